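"""Confusion matrix, multiclass metric battery and bootstrap CIs.

All rate metrics derive from per-class one-vs-rest TP/TN/FP/FN counts
read off the confusion matrix; macro variants are unweighted means over
classes. Cohen's kappa is (p_o - p_e) / (1 - p_e) with p_e from the
marginal distributions; MCC uses the Gorodkin multiclass
generalization; AUC is macro one-vs-rest and requires probability
scores (reported as None when only hard labels exist). Confidence
intervals are percentile bootstrap over resampled prediction/label
pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray            # rows = true class, cols = predicted
    labels: list[str]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.labels, columns=self.labels)


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    macro_specificity: float
    macro_auc: float | None
    mcc: float
    kappa: float
    per_class: pd.DataFrame       # precision / recall / specificity / f1 per class
    confusion: ConfusionMatrix
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "macro_specificity": self.macro_specificity,
            "macro_auc": self.macro_auc,
            "mcc": self.mcc,
            "kappa": self.kappa,
        }
        if self.ci:
            d["ci"] = {k: list(v) for k, v in self.ci.items()}
        return d

    def summary(self) -> str:
        lines = ["Metric                 Value   95% CI"]
        for name in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                     "macro_specificity", "macro_auc", "mcc", "kappa"):
            v = getattr(self, name)
            ci = self.ci.get(name)
            ci_s = f"[{ci[0]:.4f}, {ci[1]:.4f}]" if ci else ""
            v_s = f"{v:.4f}" if v is not None else "  n/a"
            lines.append(f"{name:<22} {v_s}  {ci_s}")
        return "\n".join(lines)


def confusion(y_true, y_pred, label_order: list[str]) -> ConfusionMatrix:
    """Exact confusion tally with a fixed label ordering."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    pos = {lab: k for k, lab in enumerate(label_order)}
    counts = np.zeros((len(label_order), len(label_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in pos or p not in pos:
            raise ValueError(f"label outside label_order: {t!r} / {p!r}")
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(counts=counts, labels=list(label_order))


def _ovr_counts(cm: np.ndarray):
    """Per-class one-vs-rest (TP, FP, FN, TN)."""
    total = cm.sum()
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = total - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros_like(num)
    np.divide(num, den, out=out, where=den > 0)
    return out


def compute_metrics(
    cm: ConfusionMatrix,
    y_true=None,
    probs: np.ndarray | None = None,
) -> MetricsReport:
    """The full metric battery from a confusion matrix.

    ``probs`` (n x n_classes scores aligned with ``y_true``) enables
    macro one-vs-rest AUC; without it AUC is None. Per-class precision
    for a class never predicted is reported as 0 with a warning.
    """
    C = cm.counts.astype(float)
    n = C.sum()
    if n <= 0:
        raise ValueError("empty confusion matrix")
    tp, fp, fn, tn = _ovr_counts(C)
    if ((tp + fp) == 0).any():
        logger.warning("some classes were never predicted; precision set to 0")
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, tn + fp)
    f1 = _safe_div(2 * precision * recall, precision + recall)

    accuracy = float(tp.sum() / n)
    # Cohen's kappa from the marginals
    p_o = accuracy
    p_e = float((C.sum(axis=1) * C.sum(axis=0)).sum() / n**2)
    kappa = (p_o - p_e) / (1 - p_e) if p_e < 1 else 1.0
    # Gorodkin multiclass MCC
    t_k = C.sum(axis=1)
    p_k = C.sum(axis=0)
    cov_xy = tp.sum() * n - float((t_k * p_k).sum())
    cov_xx = n**2 - float((p_k * p_k).sum())
    cov_yy = n**2 - float((t_k * t_k).sum())
    mcc = cov_xy / np.sqrt(cov_xx * cov_yy) if cov_xx > 0 and cov_yy > 0 else 0.0

    auc = None
    if probs is not None:
        if y_true is None:
            raise ValueError("probs given without y_true")
        present = sorted(set(y_true))
        probs = np.asarray(probs)
        if len(present) == 2:
            pos = present[1]
            score = probs[:, cm.labels.index(pos)]
            auc = float(roc_auc_score([int(v == pos) for v in y_true], score))
        elif len(present) > 2:
            cols = [cm.labels.index(lab) for lab in present]
            sub = probs[:, cols]
            # renormalize over the classes present so scores stay a
            # probability distribution when some classes have no support
            sub = sub / np.clip(sub.sum(axis=1, keepdims=True), 1e-12, None)
            auc = float(
                roc_auc_score(
                    list(y_true), sub,
                    multi_class="ovr", average="macro", labels=present,
                )
            )

    per_class = pd.DataFrame(
        {"precision": precision, "recall": recall,
         "specificity": specificity, "f1": f1, "support": C.sum(axis=1)},
        index=cm.labels,
    )
    return MetricsReport(
        accuracy=accuracy,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        macro_specificity=float(specificity.mean()),
        macro_auc=auc,
        mcc=float(mcc),
        kappa=float(kappa),
        per_class=per_class,
        confusion=cm,
    )


_METRIC_GETTERS = {
    "accuracy": lambda r: r.accuracy,
    "macro_precision": lambda r: r.macro_precision,
    "macro_recall": lambda r: r.macro_recall,
    "macro_f1": lambda r: r.macro_f1,
    "macro_specificity": lambda r: r.macro_specificity,
    "macro_auc": lambda r: r.macro_auc,
    "mcc": lambda r: r.mcc,
    "kappa": lambda r: r.kappa,
}


def bootstrap_ci(
    y_true,
    y_pred,
    label_order: list[str],
    metric_id: str = "accuracy",
    probs: np.ndarray | None = None,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> tuple[float, float]:
    """Seeded percentile bootstrap interval for one metric.

    Resamples (label, prediction[, probability]) triples with
    replacement ``B`` times and returns the (2.5%, 97.5%) percentile
    interval at the default level.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    if metric_id not in _METRIC_GETTERS:
        raise ValueError(f"unknown metric {metric_id!r}")
    y_true = np.asarray(list(y_true))
    y_pred = np.asarray(list(y_pred))
    rng = np.random.default_rng(seed)
    n = len(y_true)
    vals = []
    for _ in range(B):
        take = rng.integers(0, n, size=n)
        cm = confusion(y_true[take], y_pred[take], label_order)
        p = None if probs is None else np.asarray(probs)[take]
        rep = compute_metrics(cm, y_true=y_true[take] if p is not None else None, probs=p)
        v = _METRIC_GETTERS[metric_id](rep)
        if v is not None:
            vals.append(v)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)
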