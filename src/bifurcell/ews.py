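"""Classical early-warning-signal statistics and the ROC harness.

Critical slowing down ahead of a bifurcation raises the variance, lag-1
autocorrelation, and entropy of detrended fluctuations and lowers their
algorithmic (Lempel-Ziv) complexity.  Each statistic is computed over a
rolling window covering a fixed fraction of the series, right-aligned so
every value uses only past data, and its monotone trend is scored by the
Kendall rank correlation (tau-b) against time.  The ROC harness compares
these trend scores — and the classifier's bifurcation probability — as
discrimination thresholds for "a bifurcation is approaching".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau
from sklearn.metrics import roc_curve

__all__ = [
    "RollingEWS",
    "TrendScore",
    "ROCResult",
    "rolling_statistics",
    "sample_entropy",
    "lempel_ziv_complexity",
    "kolmogorov_complexity",
    "kendall_tau",
    "roc_evaluate",
]


# ----------------------------------------------------------------------
# scalar statistics

def sample_entropy(series: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """SampEn(m, r): -log(A/B) over template matches within Chebyshev r.

    B counts pairs of m-length templates (both drawn from the first
    N - m windows, self-matches excluded) within tolerance r; A counts
    the corresponding (m+1)-length pairs.  r defaults to 0.2 times the
    series standard deviation.  Returns NaN when either count is zero.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n <= m + 1:
        raise ValueError("series must be longer than m + 1")
    if r is None:
        r = 0.2 * float(np.std(x))
    tm1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n-m, m+1)
    tm = tm1[:, :m]  # m-templates restricted to the first n-m windows
    dm = np.abs(tm[:, None, :] - tm[None, :, :]).max(axis=2)
    dm1 = np.abs(tm1[:, None, :] - tm1[None, :, :]).max(axis=2)
    iu = np.triu_indices(tm.shape[0], k=1)
    B = int(np.count_nonzero(dm[iu] <= r))
    A = int(np.count_nonzero(dm1[iu] <= r))
    if A == 0 or B == 0:
        return float("nan")
    return float(-np.log(A / B))


def lempel_ziv_complexity(binary: np.ndarray) -> int:
    """LZ76 phrase count of a binary sequence (Kaspar-Schuster scheme)."""
    s = np.asarray(binary).astype(np.int8)
    n = s.shape[0]
    if n == 0:
        raise ValueError("empty sequence")
    c, l, i, k, k_max = 1, 1, 0, 1, 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def kolmogorov_complexity(series: np.ndarray) -> float:
    """Normalized LZ76 complexity of the median-binarized series.

    Binarize by the series median (strictly above -> 1), parse with LZ76,
    and normalize by n / log2(n), the expected phrase count of a random
    binary string; values near 1 indicate incompressible fluctuations.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("series must have length >= 2")
    b = (x > np.median(x)).astype(np.int8)
    return lempel_ziv_complexity(b) * np.log2(n) / n


def _lag1_ac(w: np.ndarray) -> float:
    a, b = w[:-1], w[1:]
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return float("nan")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


# ----------------------------------------------------------------------
# rolling statistics

@dataclass
class RollingEWS:
    """Per-time statistic sequences aligned to window right edges."""

    window: int
    variance: np.ndarray
    ac1: np.ndarray
    sampen: np.ndarray
    kc: np.ndarray

    def by_name(self, name: str) -> np.ndarray:
        return {"variance": self.variance, "ac1": self.ac1,
                "sampen": self.sampen, "kc": self.kc}[name]


def rolling_statistics(residuals: np.ndarray,
                       window_fraction: float = 0.25) -> RollingEWS:
    """Variance, lag-1 AC, sample entropy, and LZ76 over rolling windows.

    The window covers ``window_fraction`` of the series (rounded), slides
    one point at a time, and is right-aligned; each output series has
    length N - w + 1.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.shape[0]
    w = int(round(window_fraction * n))
    if w < 3 or w > n:
        raise ValueError("window must satisfy 3 <= w <= N")
    wins = np.lib.stride_tricks.sliding_window_view(x, w)
    var = wins.var(axis=1, ddof=1)
    ac1 = np.array([_lag1_ac(win) for win in wins])
    sampen = np.array([sample_entropy(win) for win in wins])
    kc = np.array([kolmogorov_complexity(win) for win in wins])
    return RollingEWS(window=w, variance=var, ac1=ac1, sampen=sampen, kc=kc)


# ----------------------------------------------------------------------
# trend score and ROC

@dataclass(frozen=True)
class TrendScore:
    statistic: str
    kendall_tau: float


def kendall_tau(values: np.ndarray, statistic: str = "") -> TrendScore:
    """Kendall tau-b of a statistic series against the time index.

    NaN entries (undefined windows) are dropped; an all-tied series scores
    0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.shape[0] < 2:
        raise ValueError("need at least two values")
    t = np.arange(v.shape[0])
    ok = np.isfinite(v)
    if ok.sum() < 2 or np.all(v[ok] == v[ok][0]):
        return TrendScore(statistic, 0.0)
    tau, _ = kendalltau(t[ok], v[ok])
    if not np.isfinite(tau):
        tau = 0.0
    return TrendScore(statistic, float(tau))


@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_predictions: int


def roc_evaluate(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve and trapezoidal AUC for bifurcation-vs-null scores.

    ``labels`` are 1 for bifurcation trajectories and 0 for nulls; higher
    scores should indicate bifurcation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least one positive and one negative label")
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thr, tpr=tpr, fpr=fpr, auc=auc,
                     n_predictions=len(scores))
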