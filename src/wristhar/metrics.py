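"""Evaluation metrics: confusion matrices, balanced accuracy, F1s, logloss.

Balanced accuracy is the mean per-class recall; F1-micro aggregates
TP/FP/FN globally (equal to plain accuracy for single-label multiclass
predictions); F1-macro averages per-class F1 scores unweighted;
F1-weighted weights them by support; logloss is the mean categorical
cross-entropy -(1/N) sum_i sum_j y_ij log p_ij with the predicted
probabilities floored at 1e-15.

Hold-out sets legitimately miss activities (not every subject recorded
every class), so classes with zero true support are by default excluded
from the BA / F1-macro averages and reported in
``MetricsReport.zero_support_classes``; set ``strict_zero_support=True``
to instead count them as recall 0, the stricter convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPS = 1e-15


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # (C, C) ints, rows = true, cols = predicted
    vocabulary: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        C = len(self.vocabulary)
        if self.counts.shape != (C, C):
            raise ValueError(f"counts must be ({C}, {C}), got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def tp(self) -> np.ndarray:
        return np.diag(self.counts)

    @property
    def fp(self) -> np.ndarray:
        return self.counts.sum(axis=0) - self.tp

    @property
    def fn(self) -> np.ndarray:
        return self.counts.sum(axis=1) - self.tp

    @property
    def support(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.vocabulary), columns=list(self.vocabulary))


@dataclass
class MetricsReport:
    balanced_accuracy: float
    f1_micro: float
    f1_macro: float
    f1_weighted: float
    logloss: float | None
    precision: dict[str, float]
    recall: dict[str, float]
    n_samples: int
    n_classes: int
    vocabulary: tuple[str, ...]
    zero_support_classes: tuple[str, ...] = ()
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "balanced_accuracy": self.balanced_accuracy,
            "f1_micro": self.f1_micro,
            "f1_macro": self.f1_macro,
            "f1_weighted": self.f1_weighted,
            "logloss": self.logloss,
            "n_samples": self.n_samples,
            "n_classes": self.n_classes,
        }


def confusion(true_labels, predicted_labels, vocabulary) -> ConfusionMatrix:
    """counts[i, j] = number of samples with true class i predicted as j."""
    vocabulary = tuple(vocabulary)
    lut = {a: i for i, a in enumerate(vocabulary)}
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    C = len(vocabulary)
    counts = np.zeros((C, C), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in lut or p not in lut:
            raise ValueError(f"label outside the vocabulary: {t!r} / {p!r}")
        counts[lut[t], lut[p]] += 1
    return ConfusionMatrix(counts, vocabulary)


def _f1(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def compute_metrics(
    cm: ConfusionMatrix,
    probabilities: np.ndarray | None = None,
    true_onehot: np.ndarray | None = None,
    strict_zero_support: bool = False,
) -> MetricsReport:
    """Metrics from a confusion matrix plus (optionally) probabilities.

    ``probabilities`` (N, C) and ``true_onehot`` (N, C) are needed only
    for logloss; rows of ``probabilities`` must sum to 1.
    """
    tp, fp, fn = cm.tp.astype(float), cm.fp.astype(float), cm.fn.astype(float)
    support = cm.support.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)

    has_support = support > 0
    zero_support = tuple(a for a, h in zip(cm.vocabulary, has_support) if not h)
    avg_mask = np.ones_like(has_support) if strict_zero_support else has_support
    if not avg_mask.any():
        ba = f1_macro = f1_weighted = 0.0
    else:
        ba = float(recall[avg_mask].mean())
        per_class_f1 = np.array([_f1(p, r) for p, r in zip(precision, recall)])
        f1_macro = float(per_class_f1[avg_mask].mean())
        w = support[avg_mask]
        f1_weighted = float((per_class_f1[avg_mask] * w).sum() / w.sum()) if w.sum() else 0.0

    micro_p = tp.sum() / max(tp.sum() + fp.sum(), EPS)
    micro_r = tp.sum() / max(tp.sum() + fn.sum(), EPS)
    f1_micro = _f1(micro_p, micro_r)

    logloss = None
    if probabilities is not None:
        probabilities = np.asarray(probabilities, dtype=float)
        if true_onehot is None:
            raise ValueError("true_onehot is required with probabilities")
        true_onehot = np.asarray(true_onehot, dtype=float)
        if probabilities.shape != true_onehot.shape:
            raise ValueError("probabilities and true_onehot shapes differ")
        if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")
        p = np.clip(probabilities, EPS, 1.0)
        logloss = float(-(true_onehot * np.log(p)).sum() / len(p))

    return MetricsReport(
        balanced_accuracy=ba,
        f1_micro=float(f1_micro),
        f1_macro=f1_macro,
        f1_weighted=f1_weighted,
        logloss=logloss,
        precision={a: float(v) for a, v in zip(cm.vocabulary, precision)},
        recall={a: float(v) for a, v in zip(cm.vocabulary, recall)},
        n_samples=cm.n,
        n_classes=len(cm.vocabulary),
        vocabulary=cm.vocabulary,
        zero_support_classes=zero_support,
    )


def evaluate_predictions(
    true_labels, probabilities: np.ndarray, vocabulary, strict_zero_support: bool = False
) -> MetricsReport:
    """Convenience wrapper: argmax-decode probabilities then score."""
    vocabulary = tuple(vocabulary)
    probabilities = np.asarray(probabilities, dtype=float)
    pred = [vocabulary[i] for i in probabilities.argmax(axis=1)]
    cm = confusion(true_labels, pred, vocabulary)
    lut = {a: i for i, a in enumerate(vocabulary)}
    onehot = np.zeros_like(probabilities)
    onehot[np.arange(len(probabilities)), [lut[t] for t in true_labels]] = 1.0
    return compute_metrics(cm, probabilities, onehot, strict_zero_support)


def gain_report(general: MetricsReport, personalized: MetricsReport) -> dict[str, float]:
    """Per-metric deltas (personalized - general) on the same hold-out set."""
    if general.vocabulary != personalized.vocabulary or general.n_samples != personalized.n_samples:
        raise ValueError("reports evaluate different sets; gains are not comparable")
    out = {}
    for name in ("balanced_accuracy", "f1_micro", "f1_macro", "f1_weighted", "logloss"):
        g, p = getattr(general, name), getattr(personalized, name)
        out[name] = None if g is None or p is None else p - g
    return out


def mean_sd(values) -> str:
    """'mean±sd' cohort-summary formatting used in the result tables."""
    values = np.asarray(list(values), dtype=float)
    return f"{values.mean():.2f}±{values.std(ddof=0):.2f}"


def summarize_reports(reports: dict, by: str = "cds") -> pd.DataFrame:
    """Cohort table: rows keyed by CDS (or fraction), mean±sd per metric.

    ``reports`` maps (subject, key) -> MetricsReport.
    """
    rows = {}
    keys = sorted({k for (_, k) in reports})
    for key in keys:
        vals = [r for (s, k), r in reports.items() if k == key]
        rows[key] = {
            "balanced_accuracy": mean_sd([v.balanced_accuracy for v in vals]),
            "f1_macro": mean_sd([v.f1_macro for v in vals]),
            "f1_micro": mean_sd([v.f1_micro for v in vals]),
            "logloss": mean_sd([v.logloss for v in vals if v.logloss is not None]),
        }
    df = pd.DataFrame(rows).T
    df.index.name = by
    return df
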