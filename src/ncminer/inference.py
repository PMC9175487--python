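"""Support-set construction and multi-label target prediction.

A query compound is scored against every support compound (known actives of
each protein); the per-protein maximum similarity score drives a binary
"modulates this protein" call at a threshold (default 0.5, strict ``>``).
Because scores are sigmoid-of-cosine, the 0.5 call is exactly the sign of
the best support cosine.  The few-shot regime reuses a trained model without
any weight update: the small dataset's actives are split per protein into
support (90%) and held-out queries (10%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_io import CompoundRecord, InteractionDataset
from .errors import ConfigurationError, EmptyDatasetError
from .snn_core import SiameseModel, sigmoid

DEFAULT_SUPPORT_CAP = 100
DEFAULT_THRESHOLD = 0.5


@dataclass
class SupportSet:
    """Per-protein reference actives: protein_id -> (compound ids, fingerprints)."""

    members: dict  # protein_id -> list[str]
    fingerprints: dict  # protein_id -> (n, n_bits) uint8 array
    per_protein_cap: int = DEFAULT_SUPPORT_CAP
    seed: int = 0
    _embeddings: dict = field(default_factory=dict, repr=False)

    @property
    def proteins(self) -> list[str]:
        return sorted(self.members)

    def size(self, protein_id: str) -> int:
        return len(self.members[protein_id])

    def embeddings(self, model: SiameseModel) -> dict:
        """Eval-mode embeddings per protein, cached per model identity."""
        key = id(model)
        if key not in self._embeddings:
            self._embeddings = {
                key: {p: model.embed(self.fingerprints[p].astype(np.float32))
                      for p in self.members}
            }
        return self._embeddings[key]


@dataclass
class PredictionMatrix:
    """Query x protein score table; call[q,p] = score[q,p] > threshold."""

    query_ids: list
    protein_ids: list
    scores: np.ndarray  # (n_queries, n_proteins) float
    threshold: float = DEFAULT_THRESHOLD

    @property
    def calls(self) -> np.ndarray:
        return self.scores > self.threshold

    def to_frame(self) -> pd.DataFrame:
        """Long format: query_id, protein_id, score, call."""
        q = np.repeat(self.query_ids, len(self.protein_ids))
        p = np.tile(self.protein_ids, len(self.query_ids))
        return pd.DataFrame(
            {
                "query_id": q,
                "protein_id": p,
                "score": self.scores.ravel(),
                "call": self.calls.ravel(),
            }
        )

    def to_wide(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.query_ids, columns=self.protein_ids)


def build_support_set(
    train_ds: InteractionDataset,
    cap: int = DEFAULT_SUPPORT_CAP,
    seed: int = 0,
) -> SupportSet:
    """Sample up to ``cap`` actives per protein, without replacement.

    Proteins with zero actives are excluded with a warning.  Deterministic
    under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    members: dict[str, list[str]] = {}
    fingerprints: dict[str, np.ndarray] = {}
    for p in train_ds.proteins:
        actives = train_ds.actives_of(p)
        if not actives:
            warnings.warn(f"protein {p!r} has no actives; excluded from support set")
            continue
        if len(actives) > cap:
            idx = rng.choice(len(actives), size=cap, replace=False)
            chosen = [actives[i] for i in sorted(idx)]
        else:
            chosen = list(actives)
        members[p] = chosen
        fingerprints[p] = train_ds.fingerprint_matrix(chosen)
    if not members:
        raise EmptyDatasetError("no protein in the dataset has any active compound")
    return SupportSet(members=members, fingerprints=fingerprints,
                      per_protein_cap=cap, seed=seed)


def predict_targets(
    model: SiameseModel,
    support: SupportSet,
    queries: list[CompoundRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> PredictionMatrix:
    """score[q,p] = max over support(p) of similarity_score(q, s).

    Invariant to support ordering; adding support compounds can only raise
    scores (max monotonicity).
    """
    if not support.members:
        raise EmptyDatasetError("empty support set")
    if not queries:
        raise EmptyDatasetError("no query compounds")
    qfp = np.stack([q.fingerprint for q in queries]).astype(np.float32)
    if qfp.shape[1] != model.head.input_dim:
        # embed() raises SpecMismatchError with a clear message
        model.embed(qfp[0])
    qz = model.embed(qfp).astype(np.float64)  # (Q, E), eval mode
    qn = np.linalg.norm(qz, axis=1)
    qn = np.where(qn == 0, 1.0, qn)
    proteins = support.proteins
    sup_emb = support.embeddings(model)
    scores = np.empty((len(queries), len(proteins)))
    for j, p in enumerate(proteins):
        sz = sup_emb[p].astype(np.float64)
        sn = np.linalg.norm(sz, axis=1)
        sn = np.where(sn == 0, 1.0, sn)
        cos = (qz / qn[:, None]) @ (sz / sn[:, None]).T  # (Q, S_p)
        scores[:, j] = sigmoid(np.clip(cos.max(axis=1), -1.0, 1.0))
    return PredictionMatrix(
        query_ids=[q.compound_id for q in queries],
        protein_ids=proteins,
        scores=scores,
        threshold=threshold,
    )


def few_shot_predict(
    model: SiameseModel,
    small_ds: InteractionDataset,
    support_frac: float = 0.9,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> tuple[PredictionMatrix, pd.DataFrame]:
    """Few-shot regime: no weight updates; the small dataset supplies both
    support and queries.

    Per protein, ``support_frac`` of the actives (at least one, at most all
    but one) go to the support set; the remaining actives plus all compounds
    not used in any support form the query pool.  Returns the prediction
    matrix and a truth table (query x protein booleans from the dataset's
    active records) for evaluation; unknown interactions count as negatives.
    """
    if len(small_ds) == 0:
        raise EmptyDatasetError("few-shot dataset is empty")
    model.check_spec(small_ds.fingerprint_spec)
    rng = np.random.default_rng(seed)
    members: dict[str, list[str]] = {}
    fingerprints: dict[str, np.ndarray] = {}
    support_ids: set[str] = set()
    for p in small_ds.proteins:
        actives = small_ds.actives_of(p)
        if not actives:
            warnings.warn(f"protein {p!r} has no actives; excluded from few-shot support")
            continue
        if len(actives) < 2:
            warnings.warn(
                f"protein {p!r} has {len(actives)} active(s); all go to support, no query"
            )
            chosen = list(actives)
        else:
            n_sup = min(len(actives) - 1, max(1, int(round(support_frac * len(actives)))))
            idx = rng.choice(len(actives), size=n_sup, replace=False)
            chosen = [actives[i] for i in sorted(idx)]
        members[p] = chosen
        fingerprints[p] = small_ds.fingerprint_matrix(chosen)
        support_ids.update(chosen)
    if not members:
        raise EmptyDatasetError("no protein in the few-shot dataset has actives")
    support = SupportSet(members=members, fingerprints=fingerprints,
                         per_protein_cap=len(small_ds), seed=seed)

    query_ids = [c for c in small_ds.compound_ids if c not in support_ids]
    if not query_ids:
        raise EmptyDatasetError("all few-shot compounds were consumed by the support set")
    queries = [small_ds.compounds[c] for c in query_ids]
    before = [w.copy() for w in model.head.weights]
    pred = predict_targets(model, support, queries, threshold=threshold)
    assert all(np.array_equal(a, b) for a, b in zip(before, model.head.weights)), \
        "few-shot prediction must not update weights"

    truth = truth_matrix(small_ds, query_ids, pred.protein_ids)
    return pred, truth


def truth_matrix(
    ds: InteractionDataset, query_ids: list, protein_ids: list
) -> pd.DataFrame:
    """Boolean query x protein table of known active interactions."""
    act = ds.interactions[ds.interactions["active"]]
    known = set(zip(act["compound_id"], act["protein_id"]))
    data = [[(q, p) in known for p in protein_ids] for q in query_ids]
    return pd.DataFrame(data, index=query_ids, columns=protein_ids)


def rank_multi_target(
    pred: PredictionMatrix, threshold: float | None = None
) -> pd.DataFrame:
    """Compounds ranked by descending number of called target proteins.

    Only compounds with at least one call appear.  Ties are broken by
    lexicographic compound id.  Columns: compound_id, targets (sorted
    tuple), n_targets.
    """
    thr = pred.threshold if threshold is None else threshold
    calls = pred.scores > thr
    rows = []
    for i, q in enumerate(pred.query_ids):
        targets = tuple(p for j, p in enumerate(pred.protein_ids) if calls[i, j])
        if targets:
            rows.append({"compound_id": q, "targets": targets, "n_targets": len(targets)})
    df = pd.DataFrame(rows, columns=["compound_id", "targets", "n_targets"])
    if not df.empty:
        df = df.sort_values(
            ["n_targets", "compound_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def join_sources(ranking: pd.DataFrame, source_table) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate ranked compounds by their natural source (food) annotations.

    ``source_table``: mapping compound_id -> iterable of source names, or a
    DataFrame with columns (compound_id, source).  Returns (source report,
    unmatched compounds).  The report lists, per source, the contained
    ranked compounds and the union of their predicted targets, sorted by
    descending compound count then source name.
    """
    if isinstance(source_table, pd.DataFrame):
        if not {"compound_id", "source"} <= set(source_table.columns):
            raise ConfigurationError("source table needs compound_id and source columns")
        mapping: dict[str, list[str]] = {}
        for _, r in source_table.iterrows():
            mapping.setdefault(str(r["compound_id"]), []).append(str(r["source"]))
    else:
        mapping = {str(k): list(v) for k, v in dict(source_table).items()}

    per_source: dict[str, dict] = {}
    unmatched = []
    for _, row in ranking.iterrows():
        cid = row["compound_id"]
        sources = mapping.get(cid, [])
        if not sources:
            unmatched.append({"compound_id": cid, "n_targets": row["n_targets"]})
            continue
        for s in sources:
            entry = per_source.setdefault(s, {"compounds": [], "targets": set()})
            entry["compounds"].append(cid)
            entry["targets"].update(row["targets"])
    report = pd.DataFrame(
        [
            {
                "source": s,
                "n_compounds": len(e["compounds"]),
                "compounds": tuple(sorted(e["compounds"])),
                "n_targets": len(e["targets"]),
                "targets": tuple(sorted(e["targets"])),
            }
            for s, e in per_source.items()
        ],
        columns=["source", "n_compounds", "compounds", "n_targets", "targets"],
    )
    if not report.empty:
        report = report.sort_values(
            ["n_compounds", "source"], ascending=[False, True]
        ).reset_index(drop=True)
    return report, pd.DataFrame(unmatched, columns=["compound_id", "n_targets"])
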