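"""Synthetic multi-protein interaction datasets for testing and benchmarking.

Real chemogenomics tables (compound-protein activity flags over structurally
clustered chemistry) are emulated directly at the fingerprint level: each
protein gets a random prototype bit pattern, its active compounds are noisy
copies of that prototype, and inactives are unstructured background vectors.
Between-cluster Tanimoto similarity then sits in the ~0.1-0.3 band typical of
diverse screening collections, while within-cluster similarity is high —
the statistical structure the similarity-learning method assumes.  No SMILES
are synthesized; the model consumes only bit vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .chem_io import CompoundRecord, FingerprintSpec, InteractionDataset
from .errors import ConfigurationError


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one synthetic interaction dataset.

    Parameters
    ----------
    n_proteins : number of target proteins.
    actives_per_protein : actives per protein; an int, or a sequence of
        length ``n_proteins`` for unbalanced designs.
    inactives_per_protein : inactive (background) compounds recorded per
        protein; same int-or-sequence convention.
    fingerprint_length : bits per fingerprint (default 1024).
    prototype_density : fraction of on-bits in each protein prototype.
    flip_rate : per-bit corruption probability applied to actives
        (must be < 0.5, otherwise actives carry no cluster signal).
    multi_label_rate : probability that an active compound is additionally
        active on a second protein (fingerprint = OR of both prototypes,
        then flipped).
    protein_prefix : namespace for generated protein ids.
    seed : generator seed; everything downstream is deterministic in it.
    """

    n_proteins: int = 3
    actives_per_protein: int | tuple = 50
    inactives_per_protein: int | tuple = 50
    fingerprint_length: int = 1024
    prototype_density: float = 0.1
    flip_rate: float = 0.02
    multi_label_rate: float = 0.0
    protein_prefix: str = "P"
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ConfigurationError("n_proteins must be >= 1")
        if not (0.0 <= self.flip_rate < 0.5):
            raise ConfigurationError("flip_rate must satisfy 0 <= rate < 0.5")
        if not (0.0 < self.prototype_density < 1.0):
            raise ConfigurationError("prototype_density must lie in (0, 1)")
        if not (0.0 <= self.multi_label_rate <= 1.0):
            raise ConfigurationError("multi_label_rate must lie in [0, 1]")
        for counts in (self.actives_per_protein, self.inactives_per_protein):
            arr = self._as_counts(counts)
            if (arr < 0).any():
                raise ConfigurationError("per-protein counts must be >= 0")

    def _as_counts(self, value) -> np.ndarray:
        if np.isscalar(value):
            return np.full(self.n_proteins, int(value))
        arr = np.asarray(value, dtype=int)
        if arr.size != self.n_proteins:
            raise ConfigurationError(
                f"per-protein count list length {arr.size} != n_proteins {self.n_proteins}"
            )
        return arr

    @property
    def active_counts(self) -> np.ndarray:
        return self._as_counts(self.actives_per_protein)

    @property
    def inactive_counts(self) -> np.ndarray:
        return self._as_counts(self.inactives_per_protein)


def _random_bits(rng: np.random.Generator, n: int, length: int, density: float) -> np.ndarray:
    return (rng.random((n, length)) < density).astype(np.uint8)


def _flip(rng: np.random.Generator, bits: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return bits.copy()
    mask = rng.random(bits.shape) < rate
    return np.where(mask, 1 - bits, bits).astype(np.uint8)


def generate_dataset(spec: SynthSpec) -> InteractionDataset:
    """Generate one clustered synthetic :class:`InteractionDataset`.

    Per protein: a prototype bit vector at ``prototype_density``; actives are
    the prototype with independent bit flips at ``flip_rate``; inactives are
    fresh background vectors at the same density.  With probability
    ``multi_label_rate`` an active is also labeled active for a second,
    randomly chosen protein and its fingerprint is built from the bitwise OR
    of the two prototypes before flipping.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    L = spec.fingerprint_length
    protein_ids = [f"{spec.protein_prefix}{i:02d}" for i in range(spec.n_proteins)]
    prototypes = _random_bits(rng, spec.n_proteins, L, spec.prototype_density)

    compounds: dict[str, CompoundRecord] = {}
    rows: list[tuple[str, str, bool]] = []
    act_counts, inact_counts = spec.active_counts, spec.inactive_counts

    for p_idx, pid in enumerate(protein_ids):
        for j in range(act_counts[p_idx]):
            cid = f"{spec.protein_prefix}{p_idx:02d}_A{j:04d}"
            proto = prototypes[p_idx]
            second = None
            if spec.n_proteins > 1 and rng.random() < spec.multi_label_rate:
                second = int(rng.choice([k for k in range(spec.n_proteins) if k != p_idx]))
                proto = np.bitwise_or(proto, prototypes[second])
            fp = _flip(rng, proto, spec.flip_rate)
            compounds[cid] = CompoundRecord(cid, fp)
            rows.append((cid, pid, True))
            if second is not None:
                rows.append((cid, protein_ids[second], True))
        for j in range(inact_counts[p_idx]):
            cid = f"{spec.protein_prefix}{p_idx:02d}_N{j:04d}"
            compounds[cid] = CompoundRecord(
                cid, _random_bits(rng, 1, L, spec.prototype_density)[0]
            )
            rows.append((cid, pid, False))

    inter = pd.DataFrame(rows, columns=["compound_id", "protein_id", "active"])
    inter = inter.drop_duplicates(subset=["compound_id", "protein_id"], keep="first")
    return InteractionDataset(
        compounds=compounds,
        interactions=inter.reset_index(drop=True),
        fingerprint_spec=FingerprintSpec.synthetic(L),
        report={"synth_spec": spec.__dict__ | {}},
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Three-tier study design: large pretraining tier, mid-size transfer
    tier, and a small few-shot tier (fewer than 100 actives per protein),
    with pairwise-disjoint protein namespaces."""

    base: SynthSpec = field(
        default_factory=lambda: SynthSpec(
            n_proteins=5, actives_per_protein=1000, inactives_per_protein=500,
            protein_prefix="BASE",
        )
    )
    transfer: SynthSpec = field(
        default_factory=lambda: SynthSpec(
            n_proteins=4, actives_per_protein=500, inactives_per_protein=250,
            protein_prefix="TL",
        )
    )
    fewshot: SynthSpec = field(
        default_factory=lambda: SynthSpec(
            n_proteins=4, actives_per_protein=20, inactives_per_protein=100,
            protein_prefix="FS",
        )
    )


def generate_fewshot_scenario(
    seed: int = 0, scenario: ScenarioSpec | None = None
) -> tuple[InteractionDataset, InteractionDataset, InteractionDataset]:
    """Generate the (pretrain, transfer, few-shot) dataset triple.

    Tier seeds are derived from ``seed`` so the triple is reproducible as a
    unit; protein id namespaces are disjoint by construction (prefixes
    BASE/TL/FS).
    """
    scenario = scenario or ScenarioSpec()
    prefixes = {scenario.base.protein_prefix, scenario.transfer.protein_prefix,
                scenario.fewshot.protein_prefix}
    if len(prefixes) != 3:
        raise ConfigurationError("scenario tiers must use distinct protein prefixes")
    tiers = []
    for offset, spec in enumerate((scenario.base, scenario.transfer, scenario.fewshot)):
        tiers.append(generate_dataset(replace(spec, seed=(seed * 3 + offset) % (2**31))))
    return tuple(tiers)
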