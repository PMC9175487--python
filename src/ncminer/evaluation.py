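"""Per-protein classification metrics, weighted averages, and the raw
cosine-similarity baseline.

Truth tables are typically single-positive: only one known target per
compound, with unknown interactions counted as negatives.  Under that
convention a multi-label predictor necessarily shows many "false" positives
(some of which are real but unrecorded interactions), so recall is the
primary metric and accuracy/AUROC are interpreted with care.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .chem_io import CompoundRecord
from .errors import ConfigurationError, DimensionError
from .inference import DEFAULT_THRESHOLD, PredictionMatrix, SupportSet


def _as_bool_matrix(m) -> np.ndarray:
    arr = m.to_numpy() if isinstance(m, pd.DataFrame) else np.asarray(m)
    return arr.astype(bool)


def confusion_counts(calls, truth, protein_ids=None) -> pd.DataFrame:
    """Per-protein TP/FP/TN/FN from boolean (query x protein) matrices."""
    c = _as_bool_matrix(calls)
    t = _as_bool_matrix(truth)
    if c.shape != t.shape:
        raise DimensionError(f"calls {c.shape} vs truth {t.shape}")
    if protein_ids is None:
        if isinstance(truth, pd.DataFrame):
            protein_ids = list(truth.columns)
        else:
            protein_ids = [f"protein_{j}" for j in range(c.shape[1])]
    rows = []
    for j, p in enumerate(protein_ids):
        cj, tj = c[:, j], t[:, j]
        rows.append(
            {
                "protein_id": p,
                "TP": int(np.sum(cj & tj)),
                "FP": int(np.sum(cj & ~tj)),
                "TN": int(np.sum(~cj & ~tj)),
                "FN": int(np.sum(~cj & tj)),
            }
        )
    return pd.DataFrame(rows).set_index("protein_id")


def recall(tp: int, fn: int) -> float:
    """TP / (TP + FN); NaN (undefined) when there are no positives."""
    denom = tp + fn
    return tp / denom if denom > 0 else float("nan")


def accuracy(tp: int, fp: int, tn: int, fn: int) -> float:
    total = tp + fp + tn + fn
    return (tp + tn) / total if total > 0 else float("nan")


def auroc(scores, truth) -> float:
    """Area under the ROC curve via the rank-sum (Mann-Whitney) statistic.

    Midranks handle ties.  Undefined (NaN) unless both classes are present.
    """
    s = np.asarray(scores, dtype=np.float64)
    t = np.asarray(truth).astype(bool)
    if s.shape != t.shape:
        raise DimensionError("scores and truth differ in length")
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)
    return (ranks[t].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def weighted_average(values, weights) -> float:
    """Sum(w*m)/Sum(w) over entries whose metric is defined (non-NaN)."""
    v = np.asarray(values, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    ok = ~np.isnan(v)
    if not ok.any() or w[ok].sum() == 0:
        raise ConfigurationError("no defined metric values to average")
    return float(np.sum(v[ok] * w[ok]) / np.sum(w[ok]))


@dataclass
class MetricsReport:
    """Per-protein metrics plus their weighted averages."""

    per_protein: pd.DataFrame  # index protein_id; TP FP TN FN recall accuracy auroc weight
    weighting: str  # "support" (per-protein truth positives) or "equal"

    @property
    def weighted(self) -> dict:
        out = {}
        for m in ("recall", "accuracy", "auroc"):
            try:
                out[m] = weighted_average(
                    self.per_protein[m], self.per_protein["weight"]
                )
            except ConfigurationError:
                out[m] = float("nan")
        return out

    def to_json_dict(self) -> dict:
        return {
            "weighting": self.weighting,
            "weighted": self.weighted,
            "per_protein": self.per_protein.reset_index().to_dict(orient="records"),
        }


def evaluate_predictions(
    pred: PredictionMatrix, truth, weights: str = "support"
) -> MetricsReport:
    """Full metric pipeline on a prediction matrix against a truth table.

    ``weights="support"`` weighs each protein by its number of truth
    positives among the evaluated queries; ``"equal"`` weighs uniformly.
    AUROC uses the continuous per-protein max-similarity scores; recall and
    accuracy use the thresholded calls.
    """
    if weights not in ("support", "equal"):
        raise ConfigurationError(f"unknown weighting scheme {weights!r}")
    t = _as_bool_matrix(truth)
    counts = confusion_counts(pred.calls, t, protein_ids=pred.protein_ids)
    rec, acc, auc, w = [], [], [], []
    for j, p in enumerate(pred.protein_ids):
        row = counts.loc[p]
        rec.append(recall(row["TP"], row["FN"]))
        acc.append(accuracy(row["TP"], row["FP"], row["TN"], row["FN"]))
        auc.append(auroc(pred.scores[:, j], t[:, j]))
        w.append(int(t[:, j].sum()) if weights == "support" else 1)
    per = counts.copy()
    per["recall"] = rec
    per["accuracy"] = acc
    per["auroc"] = auc
    per["weight"] = w
    return MetricsReport(per_protein=per, weighting=weights)


def cosine_baseline(
    support: SupportSet,
    queries: list[CompoundRecord],
    threshold: float = DEFAULT_THRESHOLD,
) -> PredictionMatrix:
    """Structural-similarity baseline: same max-over-support protocol, but the
    score is the raw cosine between fingerprint bit vectors (no learned head,
    no sigmoid); the threshold applies to the raw cosine."""
    if not support.members:
        raise ConfigurationError("empty support set")
    qfp = np.stack([q.fingerprint for q in queries]).astype(np.float64)
    qn = np.linalg.norm(qfp, axis=1)
    qn = np.where(qn == 0, 1.0, qn)
    proteins = support.proteins
    scores = np.empty((len(queries), len(proteins)))
    for j, p in enumerate(proteins):
        sfp = support.fingerprints[p].astype(np.float64)
        sn = np.linalg.norm(sfp, axis=1)
        sn = np.where(sn == 0, 1.0, sn)
        cos = (qfp / qn[:, None]) @ (sfp / sn[:, None]).T
        scores[:, j] = cos.max(axis=1)
    return PredictionMatrix(
        query_ids=[q.compound_id for q in queries],
        protein_ids=proteins,
        scores=scores,
        threshold=threshold,
    )
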