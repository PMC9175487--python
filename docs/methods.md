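# Methods

## Model

The similarity model is a Siamese network: a shared embedding MLP ("head")
applied to both fingerprints of a pair, a parameter-free cosine "body", and
a sigmoid output. For fingerprints x₁, x₂ ∈ {0,1}ᵈ,

    score(x₁, x₂) = σ( cos(H(x₁), H(x₂)) ),

so all scores lie strictly inside (σ(−1), σ(1)) ≈ (0.2689, 0.7311) and a
0.5 decision threshold is equivalent to asking whether the embedding cosine
is positive. This equivalence is asserted as an internal consistency check
in the test suite.

The head is a stack of linear layers given by `hidden_dims`; ReLU and
inverted dropout follow every hidden layer, the final layer is linear, and
dropout is not applied to the input. The default is `(2048, 2048, 2048)`
with dropout 0.5 on a 1024-bit input. The published description of this
architecture admits both a literal two-layer reading and a three-hidden-
layer reading; depth is therefore configurable (`--head-dims`), the default
covers the deeper reading, and the choice is recorded in every checkpoint.
The input dimension always follows the data's fingerprint spec rather than
being hard-coded.

Training minimizes mean binary cross-entropy (log arguments clamped at
1e-7) with Adam, default learning rate 1e-4, batch 128, up to 200 epochs
with patience 10 on validation BCE (best-validation weights restored).
Because sigmoid∘BCE collapses to a `(score − label)` gradient at the cosine,
the backward pass is short and is implemented, together with the forward
pass, dropout, and Adam, directly on NumPy arrays. A single seed drives
parameter initialization, dropout masks, and batch shuffling; bitwise
reproducibility assumes single-threaded BLAS.

Numerical conventions: cosine of an all-zero embedding is defined as 0
(warned, never NaN); computed cosines are clipped to [−1, 1] to guard
against floating-point excursions past the bounds; Tanimoto of two all-zero
fingerprints is defined as 1 (warned). Batch and single-vector embedding
may differ at float32 rounding level (different BLAS kernels), which is why
protocol oracles in the tests compare at 1e-6 while pure-float64 formula
oracles compare at 1e-9.

## Data handling

Fingerprints default to RDKit's path-based topological fingerprint
(`RDKFingerprint`, 1024 bits), the closest widely available analogue of the
CDK "standard" path fingerprint; the dialect (name, length, params) is
stored in every dataset and checkpoint, and train/predict mismatches are
rejected rather than silently scored. An optional standardization pass
keeps the largest covalent fragment (salt stripping) before
fingerprinting; it is off by default since source databases do not document
such a step.

Interaction tables use the `compound_id, smiles | fingerprint_hex,
protein_id, activity∈{A,N}` layout. Duplicated (compound, protein) rows are
deduplicated keep-first by default (overridable to an error); rows with
unparseable SMILES are dropped and counted in the ingest report.

The nested split takes `round(0.10·N)` compounds for test, then
`round(0.10·remainder)` for validation, leaving 81% for training at the
default fractions. The split unit is the compound, preventing a
multi-target compound from leaking across partitions; row-level splitting
is available behind a flag.

Pair generation samples the target protein uniformly over proteins — the
anti-dominance rule — so per-protein pair frequency is independent of data
size (verified by chi-square in the tests). Positives are two distinct
actives of the sampled protein; negatives join one active with a partner
sharing no co-active protein, drawn from the pooled eligible candidates
(inactives of that protein plus actives of other proteins). The pool
composition can be forced with `neg_mix`. Sampling is with replacement
across pairs (required to reach thousands of pairs from small pools);
rejection sampling is capped at 1,000 attempts per pair before an explicit
error. The single-label filter deletes classes: each multi-target compound
keeps one uniformly chosen active record.

## Prediction protocol

The support set holds up to 100 actives per protein, sampled without
replacement. A query's per-protein score is the maximum similarity score
over that protein's support; calls use strict `>` at the threshold (a
boundary score of exactly 0.5 is a negative call). The few-shot regime
reuses a trained model with no weight updates: per protein, 90% of the
actives (at least one, at most all but one) form the support, and held-out
actives plus all remaining compounds are queries. Truth tables are built
from the dataset's active records with unknown interactions counted as
negatives — the single-positive convention of the source databases, which
inflates apparent false positives and is why recall is the primary metric.

Metrics are computed per protein: recall TP/(TP+FN), accuracy
(TP+TN)/total, and AUROC via the midrank Mann–Whitney statistic. (A
published formula for accuracy with FP in the numerator is treated as a
typo; the standard form is implemented.) Undefined metrics (no positives,
single-class AUROC) are flagged and excluded from weighting, never
NaN-propagated. The weighted average uses per-protein truth-positive counts
by default (`weights="support"`), with equal weighting available. The
cosine baseline applies the identical max-over-support protocol to raw
fingerprint cosines without head or sigmoid.

## Synthetic data

The generator emulates the statistical structure the method relies on
directly at the fingerprint level: each protein has a random prototype bit
pattern (default density 0.1 over 1024 bits), actives are prototype copies
with independent per-bit flips (default 0.02), and inactives are fresh
background vectors. This yields within-cluster Tanimoto well above the
~0.1–0.3 background typical of diverse screening chemistry. Multi-label
compounds take the bitwise OR of two prototypes before flipping. The
three-tier scenario mirrors the descending-size study design: a base tier
(5 proteins × 1000 actives), a transfer tier (4 × 500), and a few-shot
tier (4 × 20 actives with a 5× excess of inactives, matching the inactive-
heavy composition of low-data screening sets), with disjoint protein
namespaces. The ablation dataset uses 4 proteins × 300 actives with a
multi-label rate of 0.3.

What the generator does *not* emulate: real chemistry (no synthetic SMILES
— the model consumes only bit vectors), correlated bit patterns from shared
substructures, activity cliffs, assay noise, or overlapping binding-site
pharmacophores across proteins. Passing the synthetic studies therefore
demonstrates that the pipeline recovers cluster structure under its own
assumptions, not that it reaches any particular performance on real
bioactivity data.

## Desk-scale study budgets

The synthetic three-tier and ablation studies run with a (512, 512, 512)
head, 2000+2000 pretraining pairs, 1000+1000 transfer pairs, and at most 6
epochs (patience 2). These budgets are deliberate package defaults: the
synthetic clusters are low-entropy compared to real chemistry, so a smaller
head and short schedule suffice to saturate them, and a full three-seed
study completes in a few minutes on one CPU. The model-level defaults
(2048-wide head, 200-epoch cap) remain the recommended starting point for
real fingerprint data.

## Known limitations

- CPU-only NumPy training; adequate for desk-scale studies and fine-tuning,
  not for millions of pairs.
- Exact bit-level equivalence with CDK standard fingerprints is not
  attempted; cross-toolkit fingerprints must not be mixed within a dataset
  (the stored spec enforces this).
- Scores are bounded away from 0 and 1 by construction, so calibrated
  probabilities are out of scope; the 0.5 threshold is a sign test on the
  embedding cosine, not a probability statement.
- The few-shot support/query split assigns a compound to at most one role;
  with heavily multi-label small datasets this slightly reduces the
  effective query pool.
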