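"""Dataset splitting, Siamese pair construction, and the single-label filter.

Pair construction implements the anti-dominance rule: the target protein of
each pair is drawn uniformly over proteins, *not* proportionally to how much
interaction data a protein has, so data-rich proteins cannot dominate the
training pairs.  A positive pair is two distinct actives of the sampled
protein; a negative pair joins an active of the sampled protein with a
partner that shares no protein on which both are active (an inactive of that
protein, or an active of a different protein only).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import InteractionDataset, fp_to_hex, hex_to_fp
from .errors import ConfigurationError, EmptyDatasetError, SamplingExhaustedError


@dataclass
class DatasetSplit:
    """Disjoint train / validation / test views of one dataset."""

    train: InteractionDataset
    validation: InteractionDataset
    test: InteractionDataset
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


@dataclass
class PairExample:
    """One labeled compound pair: label 1 iff both are active on a shared protein."""

    fp_a: np.ndarray
    fp_b: np.ndarray
    label: int
    compound_a: str
    compound_b: str
    protein: str  # sampled protein for positives; "negative" otherwise


def split_dataset(
    ds: InteractionDataset,
    seed: int,
    test_frac: float = 0.10,
    val_frac: float = 0.10,
    unit: str = "compound",
) -> DatasetSplit:
    """Nested random split: ``test_frac`` of compounds to test, then
    ``val_frac`` of the remainder to validation (defaults give 81/9/10).

    Rounding policy: each carve-out size is ``round(frac * pool)``.  The
    split unit is the compound (default), which prevents a multi-target
    compound from leaking across partitions; ``unit="row"`` splits raw
    interaction rows instead.  Deterministic under a fixed seed.
    """
    if len(ds) == 0:
        raise EmptyDatasetError("cannot split an empty dataset")
    if unit not in ("compound", "row"):
        raise ConfigurationError(f"unknown split unit {unit!r}")
    if len(ds) < 10:
        warnings.warn(f"dataset of {len(ds)} compounds gives a degenerate split")

    rng = np.random.default_rng(seed)
    if unit == "compound":
        ids = np.array(ds.compound_ids)
        rng.shuffle(ids)
        n = ids.size
        n_test = int(round(test_frac * n))
        n_val = int(round(val_frac * (n - n_test)))
        test_ids = ids[:n_test]
        val_ids = ids[n_test : n_test + n_val]
        train_ids = ids[n_test + n_val :]
        return DatasetSplit(
            train=ds.subset(list(train_ids)),
            validation=ds.subset(list(val_ids)),
            test=ds.subset(list(test_ids)),
            seed=seed,
        )
    # row-level: partition interaction rows, then carry the referenced compounds
    idx = np.arange(len(ds.interactions))
    rng.shuffle(idx)
    n = idx.size
    n_test = int(round(test_frac * n))
    n_val = int(round(val_frac * (n - n_test)))
    parts = (idx[n_test + n_val :], idx[n_test : n_test + n_val], idx[:n_test])
    views = []
    for part in parts:
        inter = ds.interactions.iloc[np.sort(part)].reset_index(drop=True)
        cids = list(dict.fromkeys(inter["compound_id"]))
        views.append(
            InteractionDataset(
                compounds={c: ds.compounds[c] for c in cids},
                interactions=inter,
                fingerprint_spec=ds.fingerprint_spec,
            )
        )
    return DatasetSplit(train=views[0], validation=views[1], test=views[2], seed=seed)


def _protein_index(ds: InteractionDataset):
    inter = ds.interactions
    act = inter[inter["active"]]
    inact = inter[~inter["active"]]
    actives = {p: [] for p in ds.proteins}
    actives.update({p: g["compound_id"].tolist() for p, g in act.groupby("protein_id")})
    inactives = {p: [] for p in ds.proteins}
    inactives.update({p: g["compound_id"].tolist() for p, g in inact.groupby("protein_id")})
    active_sets: dict[str, set] = {c: set() for c in ds.compound_ids}
    active_sets.update({c: set(g["protein_id"]) for c, g in act.groupby("compound_id")})
    return actives, inactives, active_sets


def generate_pairs(
    ds: InteractionDataset,
    n_pos: int,
    n_neg: int,
    seed: int,
    neg_mix: float | None = None,
    max_attempts: int = 1000,
) -> list[PairExample]:
    """Generate exactly ``n_pos`` positive and ``n_neg`` negative pairs.

    Positive: sample a protein uniformly among those with >= 2 actives, then
    two distinct actives of it.  Negative: sample a protein uniformly, one
    active of it, then a partner from the pooled eligible candidates —
    inactives of that protein and actives of other proteins — rejected (up to
    ``max_attempts`` times) if the two compounds share any protein on which
    both are active.  ``neg_mix`` in [0, 1] forces the fraction of negative
    partners drawn from the sampled protein's inactives instead of the
    pooled default.  Sampling is with replacement across pairs.
    """
    rng = np.random.default_rng(seed)
    actives, inactives, active_sets = _protein_index(ds)
    pos_proteins = [p for p in ds.proteins if len(actives[p]) >= 2]
    if n_pos > 0 and not pos_proteins:
        raise SamplingExhaustedError("no protein has >= 2 actives; cannot make positives")

    pairs: list[PairExample] = []
    fps = ds.compounds

    for _ in range(n_pos):
        p = pos_proteins[rng.integers(len(pos_proteins))]
        i, j = rng.choice(len(actives[p]), size=2, replace=False)
        a, b = actives[p][i], actives[p][j]
        pairs.append(PairExample(fps[a].fingerprint, fps[b].fingerprint, 1, a, b, p))

    neg_proteins = [
        p for p in ds.proteins
        if actives[p] and (
            inactives[p]
            or any(actives[q] for q in ds.proteins if q != p)
        )
    ]
    if n_neg > 0 and not neg_proteins:
        raise SamplingExhaustedError("no protein admits a negative partner")

    other_actives = {
        p: [c for q in ds.proteins if q != p for c in actives[q]] for p in ds.proteins
    }
    for _ in range(n_neg):
        made = False
        for _attempt in range(max_attempts):
            p = neg_proteins[rng.integers(len(neg_proteins))]
            a = actives[p][rng.integers(len(actives[p]))]
            if neg_mix is None:
                pool = inactives[p] + other_actives[p]
            else:
                pool = inactives[p] if rng.random() < neg_mix else other_actives[p]
            if not pool:
                continue
            b = pool[rng.integers(len(pool))]
            if b != a and not (active_sets[a] & active_sets[b]):
                pairs.append(
                    PairExample(fps[a].fingerprint, fps[b].fingerprint, 0, a, b, "negative")
                )
                made = True
                break
        if not made:
            raise SamplingExhaustedError(
                f"could not build a negative pair within {max_attempts} attempts "
                f"(last protein tried: {p!r})"
            )
    return pairs


def filter_single_label(ds: InteractionDataset, seed: int) -> InteractionDataset:
    """Reduce a multi-label dataset to single-label by deleting classes.

    Every compound active on several proteins keeps exactly one of them,
    chosen uniformly at random (seed-deterministic); its other active records
    are removed.  Inactive records and the input dataset are untouched.
    """
    rng = np.random.default_rng(seed)
    inter = ds.interactions
    keep = np.ones(len(inter), dtype=bool)
    act = inter[inter["active"]]
    for cid, grp in act.groupby("compound_id", sort=True):
        if len(grp) > 1:
            chosen = grp.index[rng.integers(len(grp))]
            keep[[i for i in grp.index if i != chosen]] = False
    return InteractionDataset(
        compounds=dict(ds.compounds),
        interactions=inter[keep].reset_index(drop=True),
        fingerprint_spec=ds.fingerprint_spec,
    )


# ---------------------------------------------------------------------------
# pair serialization
# ---------------------------------------------------------------------------

def write_pairs(pairs: list[PairExample], path: str | Path, seed: int | None = None) -> None:
    """CSV with hex-packed fingerprints plus a JSON sidecar (seed, counts)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "fp_a_hex": [fp_to_hex(p.fp_a) for p in pairs],
            "fp_b_hex": [fp_to_hex(p.fp_b) for p in pairs],
            "label": [p.label for p in pairs],
            "compound_a": [p.compound_a for p in pairs],
            "compound_b": [p.compound_b for p in pairs],
            "protein": [p.protein for p in pairs],
        }
    )
    df.to_csv(path, index=False)
    n_bits = int(pairs[0].fp_a.size) if pairs else 0
    sidecar = {
        "seed": seed,
        "n_pairs": len(pairs),
        "n_positive": int(sum(p.label for p in pairs)),
        "n_negative": int(sum(1 - p.label for p in pairs)),
        "n_bits": n_bits,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_pairs(path: str | Path) -> list[PairExample]:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    n_bits = sidecar["n_bits"]
    df = pd.read_csv(path, dtype={"fp_a_hex": str, "fp_b_hex": str})
    return [
        PairExample(
            hex_to_fp(r.fp_a_hex, n_bits),
            hex_to_fp(r.fp_b_hex, n_bits),
            int(r.label),
            str(r.compound_a),
            str(r.compound_b),
            str(r.protein),
        )
        for r in df.itertuples()
    ]
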