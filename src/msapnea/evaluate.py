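"""Per-segment metrics and per-recording apnea-hypopnea-index diagnosis.

Per-segment performance is summarized by accuracy, sensitivity (recall of
the apneic class), specificity (recall of the normal class), F1 and a
rank-based AUC, all derived from the confusion matrix with AH as the
positive class. Per recording, the apnea-hypopnea index is estimated as

    AHI = 60 * n_SA_segments / T

with ``T`` the number of scored minutes — apneic minutes per hour of
recording. Recordings are binned into severity categories A (AHI > 10),
B (5 < AHI <= 10) and C (AHI <= 5); an AHI above 5 counts as sleep apnea.
An AHI of exactly 5 is assigned to C / not-SA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ecg_io import LABEL_APNEA, LABEL_NORMAL

__all__ = ["ConfusionMatrix", "SegmentMetrics", "RecordingDiagnosis",
           "confusion", "metrics_from_confusion", "compute_ahi", "diagnose",
           "per_recording_report"]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts with the apneic class (AH) positive."""

    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fp, self.fn, self.tp) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass(frozen=True)
class SegmentMetrics:
    """Percent-scale segment metrics; undefined ratios are ``None``."""

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    f1: float | None
    auc: float | None = None  # fraction in [0, 1], needs scores

    def rounded(self, ndigits: int = 1) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = None if v is None else round(v, 3 if k == "auc" else ndigits)
        return out


def _to_binary(values) -> np.ndarray:
    arr = np.asarray(values)
    if arr.dtype.kind in "iubf":
        out = arr.astype(np.int64)
        if np.any((arr != 0) & (arr != 1)):
            raise ValueError("numeric labels must be 0 (N) or 1 (AH)")
        return out
    mapping = {LABEL_NORMAL: 0, LABEL_APNEA: 1, "A": 1}
    out = np.empty(arr.shape, dtype=np.int64)
    for i, v in enumerate(arr.ravel()):
        if str(v) not in mapping:
            raise ValueError(f"unknown label {v!r}")
        out.ravel()[i] = mapping[str(v)]
    return out


def confusion(labels, predictions) -> ConfusionMatrix:
    """Confusion counts from true labels and predictions (N/AH or 0/1)."""
    y = _to_binary(labels)
    p = _to_binary(predictions)
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels vs "
                         f"{len(p)} predictions")
    return ConfusionMatrix(
        tn=int(np.sum((y == 0) & (p == 0))),
        fp=int(np.sum((y == 0) & (p == 1))),
        fn=int(np.sum((y == 1) & (p == 0))),
        tp=int(np.sum((y == 1) & (p == 1))),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def metrics_from_confusion(cm: ConfusionMatrix,
                           scores: np.ndarray | None = None,
                           labels=None) -> SegmentMetrics:
    """Percent metrics from counts; AUC (rank-based, midrank ties) needs
    per-segment AH scores plus the matching labels."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    auc = None
    if scores is not None:
        if labels is None:
            raise ValueError("AUC needs labels alongside scores")
        y = _to_binary(labels)
        if len(np.unique(y)) == 2:
            auc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return SegmentMetrics(
        accuracy=_ratio(cm.tp + cm.tn, cm.total),
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        f1=_ratio(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn),
        auc=auc,
    )


def compute_ahi(n_sa_segments: int, total_minutes: int) -> float:
    """Apneic minutes per hour: ``60 * n_sa_segments / total_minutes``."""
    if total_minutes < 1:
        raise ValueError("total_minutes must be >= 1")
    if n_sa_segments < 0 or n_sa_segments > total_minutes:
        raise ValueError("n_sa_segments must lie in [0, total_minutes]")
    return 60.0 * n_sa_segments / total_minutes


def diagnose(ahi: float) -> tuple[str, bool]:
    """Severity category and SA verdict: A iff AHI > 10, B iff 5 < AHI <= 10,
    C otherwise; SA iff AHI > 5."""
    if ahi < 0:
        raise ValueError("AHI must be nonnegative")
    if ahi > 10:
        return "A", True
    if ahi > 5:
        return "B", True
    return "C", False


@dataclass(frozen=True)
class RecordingDiagnosis:
    record_id: str
    T: int               # scored minutes
    n_sa_segments: int
    ahi: float
    category: str
    is_sa: bool


def per_recording_report(record_ids, predictions,
                         reference_ahi: dict[str, float] | None = None
                         ) -> tuple[pd.DataFrame, float | None]:
    """One diagnosis row per recording, plus the Pearson correlation between
    predicted and reference AHI when a reference mapping is supplied."""
    ids = np.asarray(record_ids)
    pred = _to_binary(predictions)
    if len(ids) != len(pred):
        raise ValueError("record_ids and predictions length mismatch")
    rows = []
    for rid in sorted(set(ids.tolist())):
        mask = ids == rid
        t = int(mask.sum())
        n_sa = int(pred[mask].sum())
        ahi = compute_ahi(n_sa, t)
        category, is_sa = diagnose(ahi)
        rows.append(RecordingDiagnosis(str(rid), t, n_sa, ahi, category,
                                       is_sa).__dict__)
    table = pd.DataFrame(rows)
    corr = None
    if reference_ahi is not None:
        unknown = set(reference_ahi) - set(table["record_id"])
        if unknown:
            raise ValueError(f"unknown record(s) in reference list: "
                             f"{sorted(unknown)}")
        sub = table[table["record_id"].isin(reference_ahi)]
        ref = np.array([reference_ahi[r] for r in sub["record_id"]])
        predicted = sub["ahi"].to_numpy()
        if len(ref) >= 2 and np.std(ref) > 0 and np.std(predicted) > 0:
            corr = float(np.corrcoef(predicted, ref)[0, 1])
        elif len(ref) >= 1 and np.allclose(predicted, ref):
            corr = 1.0
    return table, corr
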