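# ncminer

Siamese metric learning for discovering which target proteins a natural
compound modulates.

Public chemical–protein interaction tables (ExCAPE-DB- or LIT-PCBA-style
records of compound, target gene symbol, and an active/inactive flag) are
mostly *single-positive* — one known target per compound, with every unknown
interaction treated as a negative — and severely unbalanced across proteins.
Conventional per-protein classifiers struggle in this regime, especially for
proteins with only a handful of known actives. `ncminer` sidesteps the
problem by learning *similarity between compound pairs* instead of per-class
decision boundaries: compounds are compared with a twin weight-sharing
network, and new compounds are assigned targets by comparison against
support sets of known actives. This naturally supports multi-label
prediction, transfer learning to mid-size datasets, and few-shot prediction
for proteins with fewer than a hundred known actives.

## The model

Each compound is a 1024-bit path-based structural fingerprint computed from
its canonical SMILES (RDKit). A pair of fingerprints (X₁, X₂) is scored as

    Y = B(H(X₁), H(X₂))

where the **head** H is a shared multilayer perceptron (default
1024 → 2048 → 2048 → 2048, ReLU, dropout 0.5) mapping fingerprints to
embeddings Z₁, Z₂, and the **body** B is the parameter-free cosine

    cos(Z₁, Z₂) = Z₁·Z₂ / (‖Z₁‖‖Z₂‖)

passed through a sigmoid to give a **similarity score**
σ(cos(Z₁, Z₂)) ∈ (σ(−1), σ(1)) ≈ (0.269, 0.731). Training pairs are labeled
1 iff both compounds are active on a shared protein; the target protein of
each pair is sampled *uniformly over proteins* so data-rich targets cannot
dominate. The head is trained to minimize mean binary cross-entropy with
Adam (learning rate 10⁻⁴). The forward/backward passes, dropout, and Adam
are implemented directly on NumPy arrays, making every run bit-reproducible
from a single seed.

At prediction time a **support set** of up to 100 known actives per protein
is embedded once; a query's score for protein *p* is its maximum similarity
score over *p*'s support, called positive when it exceeds 0.5 — which, given
the score bounds, is exactly the sign of the best support cosine. Compounds
can then be ranked by how many targets they are called on and joined to
natural-source (food) annotations.

## Worked example

Train on a synthetic clustered dataset (3 proteins, 200 actives + 100
inactives each) and predict targets for its held-out test compounds:

```python
from ncminer import (SynthSpec, generate_dataset, split_dataset, generate_pairs,
                     SiameseModel, TrainConfig, train, build_support_set,
                     predict_targets, evaluate_predictions)
from ncminer.inference import truth_matrix

ds = generate_dataset(SynthSpec(n_proteins=3, actives_per_protein=200,
                                inactives_per_protein=100, seed=0))
sp = split_dataset(ds, seed=0)              # 81% / 9% / 10% nested split

model = SiameseModel.create(ds.fingerprint_spec, hidden_dims=(512, 512, 512), seed=0)
train(model,
      generate_pairs(sp.train, 1000, 1000, seed=0),
      generate_pairs(sp.validation, 200, 200, seed=1),
      TrainConfig(max_epochs=5, patience=2, seed=0))

support = build_support_set(sp.train, cap=100, seed=0)
queries = [sp.test.compounds[c] for c in sp.test.compound_ids]
pred = predict_targets(model, support, queries, threshold=0.5)
truth = truth_matrix(sp.test, pred.query_ids, pred.protein_ids)
report = evaluate_predictions(pred, truth, weights="support")

print(report.per_protein[["TP", "FP", "TN", "FN", "recall", "accuracy", "auroc"]])
print("weighted:", {k: round(v, 3) for k, v in report.weighted.items()})
```

Output:

```
            TP  FP  TN  FN  recall  accuracy  auroc
protein_id
P00         17  17  56   0     1.0  0.811111    1.0
P01         21  10  59   0     1.0  0.888889    1.0
P02         24  21  45   0     1.0  0.766667    1.0
weighted: {'recall': 1.0, 'accuracy': 0.82, 'auroc': 1.0}
```

Every known active in the test set is recovered (recall 1.0 per protein).
Accuracy is lower because the truth is single-positive: compounds whose
fingerprints resemble a second protein's actives are called on it too and
counted as false positives, the expected behavior of a multi-label
predictor evaluated against single-positive records.

The same pipeline is available from the shell:

```bash
ncminer synth --out data.csv --seed 1 --n-proteins 3 --actives 200 --inactives 100
ncminer split --input data.csv --out-dir splits --seed 1
ncminer pairs --input splits/train.csv --out pairs.csv --n-pos 7000 --n-neg 7000 --seed 1
ncminer train --pairs pairs.csv --out model.npz --head-dims 512,512,512 --max-epochs 5
ncminer predict --model model.npz --support splits/train.csv --queries splits/test.csv --out pred.csv
ncminer evaluate --pred pred.csv --truth splits/test.csv --out metrics.json
ncminer rank --pred pred.csv --out ranking.csv
```

Subcommands `transfer` (fine-tune a pretrained checkpoint) and `fewshot`
(support/query prediction on a small dataset without weight updates) cover
the low-data regimes. Every run writes an effective-config snapshot
(`<subcommand>_run.json`) next to its outputs; exit codes are 0 (success),
2 (usage), 3 (data error), 4 (numeric failure).

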