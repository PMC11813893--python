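"""Evaluation metrics and summary statistics.

AUC is computed by the Mann-Whitney rank statistic (average ranks for ties),
with the abnormal class as positive: it equals the probability that a random
abnormal sample receives a higher anomaly score than a random normal one.
Summaries report mean, sample standard deviation (N-1) and variance = sd^2
over the fold x repeat AUC values of a configuration; report-time rounding is
half-up, full precision is kept internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy.stats import rankdata


def round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def auc(scores, labels) -> float:
    """Rank-based ROC AUC with abnormal (truthy label) as the positive class.

    ``labels`` may be boolean/0-1 or the strings "normal"/"abnormal".
    Average ranks handle ties; all scores equal gives 0.5.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.dtype.kind in "US":
        pos = labels == "abnormal"
    else:
        pos = labels.astype(bool)
    m = int(pos.sum())
    n_neg = int((~pos).sum())
    if m == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # ascending, average ties
    return float((ranks[pos].sum() - m * (m + 1) / 2.0) / (m * n_neg))


def mse(y, yhat) -> float:
    """Mean squared error ``(1/n) sum (y_i - yhat_i)^2``."""
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size < 1:
        raise ValueError("need at least one value")
    return float(np.mean((y - yhat) ** 2))


@dataclass(frozen=True)
class AUCSummary:
    """Per-configuration AUC values with their mean/sd/variance."""

    values: tuple[float, ...]
    mean: float
    sd: float
    variance: float

    def rounded(self, decimals: int = 4) -> dict[str, float]:
        return {
            "mean": round_half_up(self.mean, decimals),
            "sd": round_half_up(self.sd, decimals),
            "variance": round_half_up(self.variance, decimals),
        }


def summarize(values) -> AUCSummary:
    """Mean, sample sd (N-1 denominator) and variance = sd^2 of AUC values."""
    vals = np.asarray(list(values), dtype=np.float64)
    if vals.size < 2:
        raise ValueError("need at least 2 values to summarize")
    sd = float(np.std(vals, ddof=1))
    return AUCSummary(
        values=tuple(float(v) for v in vals),
        mean=float(np.mean(vals)),
        sd=sd,
        variance=sd * sd,
    )


def relative_change(a: float, b: float, decimals: int = 1) -> float:
    """Percent change ``(a - b)/a * 100`` rounded half-up to ``decimals``."""
    if a == 0:
        raise ValueError("reference value a must be nonzero")
    return round_half_up((a - b) / a * 100.0, decimals)
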