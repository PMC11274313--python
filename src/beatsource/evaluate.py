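"""Evaluation: confusion matrix, accuracy/precision/recall/F1, ROC/AUC,
and the per-recording quality timeline.

Percentage metrics are reported to one decimal using a two-stage half-up
rounding (the proportion is first rounded to 0.01%, then to 0.1%).  This is
the convention that reproduces clinical-report figures derived from
proportions printed to four decimal places: e.g. 139/169 = 82.2485% is
reported as 82.3.

Positive-class convention: the printed worked-example metrics are
reproducible only with "from vessel" as the positive class, so that is the
default; both conventions are computable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as sk_auc
from sklearn.metrics import roc_curve as sk_roc_curve

from .config import DUS_RATE_HZ
from .signals import LABEL_FETAL, LABEL_VESSEL, Recording


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def report_percent(p: float) -> float:
    """Two-stage half-up rounding of a percentage: 0.01% then 0.1%."""
    return round_half_up(round_half_up(p, 2), 1)


# ---------------------------------------------------------------------------
# confusion matrix and Eq-style metrics


@dataclass
class ConfusionMatrix:
    """Counts over (true, predicted) pairs; f = fetal, v = vessel."""

    n_ff: int  # true fetal, predicted fetal
    n_fv: int  # true fetal, predicted vessel
    n_vf: int  # true vessel, predicted fetal
    n_vv: int  # true vessel, predicted vessel

    def __post_init__(self) -> None:
        for name in ("n_ff", "n_fv", "n_vf", "n_vv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.n_ff + self.n_fv + self.n_vf + self.n_vv

    def as_dict(self) -> Dict[str, int]:
        return {"n_ff": self.n_ff, "n_fv": self.n_fv, "n_vf": self.n_vf, "n_vv": self.n_vv}


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionMatrix:
    """Count the four (true, predicted) cells over fetal/vessel labels."""
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    if t.shape != p.shape:
        raise ValueError("label sequences differ in length")
    valid = {LABEL_FETAL, LABEL_VESSEL}
    bad = (set(t) | set(p)) - valid
    if bad:
        raise ValueError(f"labels outside the binary set: {sorted(bad)}")
    return ConfusionMatrix(
        n_ff=int(np.sum((t == LABEL_FETAL) & (p == LABEL_FETAL))),
        n_fv=int(np.sum((t == LABEL_FETAL) & (p == LABEL_VESSEL))),
        n_vf=int(np.sum((t == LABEL_VESSEL) & (p == LABEL_FETAL))),
        n_vv=int(np.sum((t == LABEL_VESSEL) & (p == LABEL_VESSEL))),
    )


@dataclass
class MetricsReport:
    """Percentages to one decimal; None where a denominator was zero."""

    accuracy: Optional[float]
    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    positive_class: str
    raw: Dict[str, Optional[float]] = field(default_factory=dict)
    undefined: List[str] = field(default_factory=list)


def classification_metrics(cm: ConfusionMatrix,
                           positive_class: str = LABEL_VESSEL) -> MetricsReport:
    """Accuracy, precision, recall and F1 as percentages.

    TP/TN/FP/FN are mapped according to ``positive_class``.  A metric whose
    denominator is zero is reported as None and listed in ``undefined``,
    never silently zero.
    """
    if cm.total <= 0:
        raise ValueError("empty confusion matrix")
    if positive_class == LABEL_VESSEL:
        tp, fn, fp, tn = cm.n_vv, cm.n_vf, cm.n_fv, cm.n_ff
    elif positive_class == LABEL_FETAL:
        tp, fn, fp, tn = cm.n_ff, cm.n_fv, cm.n_vf, cm.n_vv
    else:
        raise ValueError(f"positive_class must be fetal or vessel, got {positive_class!r}")

    undefined: List[str] = []
    raw: Dict[str, Optional[float]] = {}
    raw["accuracy"] = 100.0 * (tp + tn) / cm.total
    raw["precision"] = 100.0 * tp / (tp + fp) if tp + fp > 0 else None
    raw["recall"] = 100.0 * tp / (tp + fn) if tp + fn > 0 else None
    if raw["precision"] is None:
        undefined.append("precision")
    if raw["recall"] is None:
        undefined.append("recall")
    if raw["precision"] is not None and raw["recall"] is not None and raw["precision"] + raw["recall"] > 0:
        raw["f1"] = 2.0 * raw["precision"] * raw["recall"] / (raw["precision"] + raw["recall"])
    else:
        raw["f1"] = None
        undefined.append("f1")

    rounded = {k: (None if v is None else report_percent(v)) for k, v in raw.items()}
    return MetricsReport(
        accuracy=rounded["accuracy"],
        precision=rounded["precision"],
        recall=rounded["recall"],
        f1=rounded["f1"],
        positive_class=positive_class,
        raw=raw,
        undefined=undefined,
    )


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(labels: Sequence[str], scores: Sequence[float],
            positive_class: str = LABEL_FETAL,
            orientation: str = "higher_is_positive") -> RocResult:
    """ROC curve over all thresholds and trapezoidal AUC.

    Ties are handled so the AUC equals the Mann-Whitney statistic
    P(score_pos > score_neg) + 0.5 P(equal).  ``orientation`` states which
    direction of the score indicates the positive class.
    """
    y = np.asarray([1 if l == positive_class else 0 for l in labels])
    s = np.asarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if orientation == "lower_is_positive":
        s = -s
    elif orientation != "higher_is_positive":
        raise ValueError(f"unknown orientation {orientation!r}")
    fpr, tpr, thr = sk_roc_curve(y, s, drop_intermediate=False)
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(sk_auc(fpr, tpr)))


def discrimination_auc(labels, scores, positive_class: str = LABEL_FETAL) -> float:
    """Orientation-free separability: max(AUC, 1 - AUC)."""
    a = roc_auc(labels, scores, positive_class).auc
    return max(a, 1.0 - a)


# ---------------------------------------------------------------------------
# quality timeline


@dataclass
class QualityTimeline:
    """Per-window classifier output along a recording, for the colour bar."""

    start_s: np.ndarray
    p_fetal: np.ndarray
    p_vessel: np.ndarray
    color: List[str]           # blue iff p_fetal >= p_vessel
    stride_s: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start_s": self.start_s,
                "p_fetal": self.p_fetal,
                "p_vessel": self.p_vessel,
                "color": self.color,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def quality_timeline(rec: Recording, model, stride_s: float = 2.0,
                     window_s: float = 2.0) -> QualityTimeline:
    """Classify consecutive windows of a recording on the trace time axis."""
    if rec.duration_s < window_s:
        raise ValueError("recording shorter than one window")
    w = int(round(window_s * DUS_RATE_HZ))
    stride = int(round(stride_s * DUS_RATE_HZ))
    starts = np.arange(0, len(rec.dus.samples) - w + 1, stride)
    x = np.stack([rec.dus.samples[s:s + w] for s in starts]).astype(np.float32)
    proba = model.predict_proba(x)
    colors = ["blue" if pf >= pv else "red" for pf, pv in proba]
    return QualityTimeline(
        start_s=starts / DUS_RATE_HZ,
        p_fetal=proba[:, 0],
        p_vessel=proba[:, 1],
        color=colors,
        stride_s=stride_s,
    )


# ---------------------------------------------------------------------------
# aggregate report


@dataclass
class EvalReport:
    """Serializable summary of one end-to-end run."""

    confusion: ConfusionMatrix
    metrics_vessel_positive: MetricsReport
    metrics_fetal_positive: MetricsReport
    model_auc: float
    baseline_aucs: Dict[str, float]
    counts: Dict[str, Dict[str, int]]
    stage_log: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def metrics_d(m: MetricsReport) -> dict:
            return {
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "positive_class": m.positive_class,
                "undefined": m.undefined,
            }

        return {
            "confusion": self.confusion.as_dict(),
            "metrics_vessel_positive": metrics_d(self.metrics_vessel_positive),
            "metrics_fetal_positive": metrics_d(self.metrics_fetal_positive),
            "model_auc": self.model_auc,
            "baseline_aucs": self.baseline_aucs,
            "counts": self.counts,
            "stage_log": self.stage_log,
        }

    def to_json(self) -> str:
        import json

        return json.dumps(self.to_dict(), indent=2, sort_keys=True)
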