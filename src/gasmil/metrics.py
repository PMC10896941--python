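"""Evaluation statistics: ROC AUC, sensitivity/specificity at the 0.5
cutoff, Cohen's weighted kappa, and seeded percentile-bootstrap CIs.

Slide-level four-grade outputs are binarized for ROC analysis as
grade >= 2 (moderate/marked) vs < 2, scored by P(grade 2) + P(grade 3);
weighted kappa is computed on the full ordinal grades. Patient stages
binarize at stage >= III, the high-risk convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score, roc_auc_score


class MetricError(ValueError):
    pass


@dataclass
class MetricResult:
    name: str
    point: float
    ci_low: float
    ci_high: float
    n: int
    n_boot: int
    seed: int


def _check_binary(labels: np.ndarray) -> None:
    u = np.unique(labels)
    if not np.isin(u, (0, 1)).all():
        raise MetricError("labels must be binary 0/1")
    if len(u) < 2:
        raise MetricError("both classes must be present")


def _bootstrap(stat, labels, scores, n_boot: int, seed: int) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    n = len(labels)
    vals = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            vals.append(stat(labels[idx], scores[idx]))
        except MetricError:
            continue  # degenerate resample (single class); drop it
    if not vals:
        return (np.nan, np.nan)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def auc(labels, scores, n_boot: int = 1000, seed: int = 0) -> MetricResult:
    """ROC AUC = probability a positive outscores a negative (ties count 1/2)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise MetricError("labels and scores must have equal length")
    _check_binary(labels)

    def stat(l, s):
        _check_binary(l)
        return float(roc_auc_score(l, s))

    point = stat(labels, scores)
    lo, hi = _bootstrap(stat, labels, scores, n_boot, seed)
    return MetricResult("auc", point, lo, hi, len(labels), n_boot, seed)


def sens_spec_at_cutoff(labels, scores, cutoff: float = 0.5) -> tuple[float, float]:
    """Sensitivity and specificity with predicted-positive iff score >= cutoff."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_binary(labels)
    pred = scores >= cutoff
    pos, neg = labels == 1, labels == 0
    sens = float((pred & pos).sum() / pos.sum())
    spec = float((~pred & neg).sum() / neg.sum())
    return sens, spec


def weighted_kappa(ratings_a, ratings_b, k: int = 4, weights: str = "quadratic",
                   n_boot: int = 1000, seed: int = 0) -> MetricResult:
    """Cohen's weighted kappa for ordinal ratings in 0..k-1.

    Disagreement weights are |i-j|^p / (k-1)^p with p=1 (linear) or p=2
    (quadratic, the default for ordinal pathology grades).
    """
    a = np.asarray(ratings_a, dtype=int)
    b = np.asarray(ratings_b, dtype=int)
    if a.shape != b.shape:
        raise MetricError("rating vectors must have equal length")
    if weights not in ("linear", "quadratic"):
        raise MetricError("weights must be 'linear' or 'quadratic'")
    if a.min() < 0 or a.max() >= k or b.min() < 0 or b.max() >= k:
        raise MetricError(f"ratings must lie in 0..{k - 1}")
    cats = np.arange(k)

    def stat(x, y):
        return float(cohen_kappa_score(x, y, labels=cats, weights=weights))

    point = stat(a, b)
    lo, hi = _bootstrap(stat, a, b, n_boot, seed)
    return MetricResult(f"kappa_{weights}", point, lo, hi, len(a), n_boot, seed)


def binarize_grades(grades, threshold: int = 2) -> np.ndarray:
    """Ordinal grade/stage -> binary positive iff value >= threshold."""
    return (np.asarray(grades, dtype=int) >= threshold).astype(int)
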