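"""Evaluation statistics: RMSE / MAE / R^2 / MAPE, Dice, Wilcoxon signed-rank.

The Wilcoxon test uses the exact null distribution of the positive-rank sum
for n <= 25 (computed by the generating-polynomial recursion over sign
assignments, equivalent to full enumeration of the 2^n sign vectors) and a
normal approximation with tie correction above.  Zero differences are
discarded (Wilcoxon's original policy); tied absolute differences receive
mid-ranks; the two-sided p doubles the smaller tail and is capped at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateSampleError, DomainError, ShapeError

__all__ = ["MetricReport", "regression_metrics", "dice", "wilcoxon_signed_rank"]

_EXACT_N_MAX = 25


@dataclass
class MetricReport:
    """Scalar evaluation metrics for one prediction set."""

    rmse: float
    mae: float
    r2: float
    mape_percent: float | None
    n: int
    dice: float | None = None
    accuracy: float | None = None

    def as_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mae": self.mae,
            "r2": self.r2,
            "mape_percent": self.mape_percent,
            "dice": self.dice,
            "accuracy": self.accuracy,
            "n": self.n,
        }


def regression_metrics(pred, truth, mape: bool = True) -> MetricReport:
    """RMSE, MAE, R^2 (truth-mean baseline) and MAPE on the percent scale."""
    pred = np.asarray(pred, dtype=np.float64).ravel()
    truth = np.asarray(truth, dtype=np.float64).ravel()
    if pred.shape != truth.shape:
        raise ShapeError(f"pred has {pred.size} values, truth has {truth.size}")
    if pred.size == 0:
        raise DomainError("need at least one observation")
    err = pred - truth
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    ss_res = float(np.sum(err**2))
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    mape_val: float | None = None
    if mape:
        zeros = np.flatnonzero(truth == 0)
        if zeros.size:
            raise DomainError(f"MAPE undefined: zero truth values at indices {zeros.tolist()}")
        mape_val = float(100.0 * np.mean(np.abs(err) / np.abs(truth)))
    return MetricReport(rmse=rmse, mae=mae, r2=float(r2), mape_percent=mape_val,
                        n=int(pred.size))


def dice(pred_mask, true_mask) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / denom


def _exact_rank_sum_distribution(double_ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable doubled positive-rank sum over sign vectors.

    Ranks are doubled so mid-ranks become integers; the recursion multiplies
    out prod_i (1 + x^r_i), i.e. each difference is independently positive or
    negative under the null.
    """
    total = int(double_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in double_ranks:
        r = int(r)  # doubled ranks are >= 2, so the slice below is well formed
        counts[r:] = counts[r:] + counts[:-r]
    return counts


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test.

    Returns ``(W, p)`` where W is the positive-rank sum of ``x - y``.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ShapeError("paired samples must have equal length")
    d = x - y
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise DegenerateSampleError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w_pos = float(ranks[d > 0].sum())
    if n <= _EXACT_N_MAX:
        double_ranks = np.rint(2 * ranks).astype(np.int64)
        counts = _exact_rank_sum_distribution(double_ranks)
        total = counts.sum()  # = 2**n
        w2 = int(round(2 * w_pos))
        p_low = counts[: w2 + 1].sum() / total
        p_high = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
    else:
        mean = n * (n + 1) / 4.0
        tie_term = 0.0
        _, t_counts = np.unique(np.abs(d), return_counts=True)
        tie_term = float(np.sum(t_counts**3 - t_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_pos - mean) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return w_pos, float(p)
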