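"""Applying the classifier and EWS baselines to pseudotime expression data.

The trajectory coordinate is the first principal component (PC1) of the
cells x genes matrix, ordered by pseudotime, its sign pinned so PC1
correlates positively with pseudotime.  It is smoothed with a Lowess
filter (span 0.2); the residuals around the trend carry the fluctuation
signal the classifier and the EWS statistics consume.  Long cell
sequences are down-sampled by a factor (default 100), and shifting the
down-sampling phase one cell at a time yields up to ``factor`` distinct
trajectories from one dataset.  Null trajectories resample residuals from
the first 20% of a trajectory (before any transition signature) onto the
original trend.  In-silico perturbations zero (knockout) or scale
(overexpression) the genes with the largest absolute PC1 loadings and
rebuild the trajectory from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.io import mmread
from statsmodels.nonparametric.smoothers_lowess import lowess

from .ews import kendall_tau, rolling_statistics
from .nn.training import MIN_SEGMENT, normalize_and_pad

__all__ = [
    "ExpressionInput",
    "TrajectoryBundle",
    "PredictionSweep",
    "read_expression",
    "compute_pc1",
    "detrend",
    "make_bundle",
    "downsample_phases",
    "make_null_trajectory",
    "prediction_sweep",
    "knockout",
    "overexpress",
    "preprocess",
]

LOWESS_SPAN = 0.2
BASELINE_STATS = ("variance", "ac1", "sampen", "kc")


@dataclass
class ExpressionInput:
    """Cells x genes expression with per-cell pseudotime.

    The matrix is assumed already log-normalized; see :func:`preprocess`
    for an optional normalization step.  Cells are sortable by pseudotime
    with stable tie-breaking on input order.
    """

    matrix: np.ndarray
    pseudotime: np.ndarray
    cell_labels: Optional[np.ndarray] = None
    gene_ids: Optional[np.ndarray] = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x genes)")
        if self.pseudotime.shape[0] != self.matrix.shape[0]:
            raise ValueError("pseudotime length must match cell count")
        if np.any(~np.isfinite(self.pseudotime)):
            raise ValueError("pseudotime must have no missing values")
        if self.gene_ids is None:
            self.gene_ids = np.array([f"g{i}" for i in range(self.matrix.shape[1])])

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    def order(self) -> np.ndarray:
        """Stable pseudotime ordering of cells."""
        return np.argsort(self.pseudotime, kind="stable")


def read_expression(expr_path: str | Path, meta_path: str | Path,
                    pseudotime_col: str = "pseudotime",
                    label_col: Optional[str] = "cell_label") -> ExpressionInput:
    """Read a cells x genes matrix (.mtx or dense .csv) with cell metadata."""
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        matrix = np.asarray(mmread(expr_path).todense(), dtype=float)
        gene_ids = None
    else:
        df = pd.read_csv(expr_path)
        gene_ids = df.columns.to_numpy()
        matrix = df.to_numpy(dtype=float)
    meta = pd.read_csv(meta_path)
    labels = meta[label_col].to_numpy() if (label_col and label_col in meta) else None
    return ExpressionInput(matrix=matrix,
                           pseudotime=meta[pseudotime_col].to_numpy(),
                           cell_labels=labels, gene_ids=gene_ids)


def compute_pc1(inp: ExpressionInput) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PC1 scores ordered by pseudotime, plus loadings and ordered times.

    Columns are centered; the leading principal axis comes from the SVD of
    the centered matrix; the sign is pinned so the scores correlate
    positively with pseudotime (falling back to a positive largest
    loading when the correlation is degenerate).
    """
    if inp.n_cells < 2 or inp.n_genes < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    X = inp.matrix - inp.matrix.mean(axis=0)
    if not np.any(X):
        raise ValueError("zero-variance expression matrix")
    # leading axis only; randomized solvers avoided for determinism
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[0]
    scores = X @ loadings
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(scores, inp.pseudotime)[0, 1]
    if np.isfinite(c) and c != 0.0:
        sgn = np.sign(c)
    else:
        sgn = np.sign(loadings[np.argmax(np.abs(loadings))]) or 1.0
    loadings = loadings * sgn
    scores = scores * sgn
    order = inp.order()
    return scores[order], loadings, inp.pseudotime[order]


def detrend(series: np.ndarray, times: Optional[np.ndarray] = None,
            span: float = LOWESS_SPAN) -> tuple[np.ndarray, np.ndarray]:
    """Lowess trend (local-linear, tricube, 0 robustness iterations).

    Returns (trend, residuals); trend + residuals reconstructs the series
    exactly.
    """
    y = np.asarray(series, dtype=float)
    x = np.arange(len(y), dtype=float) if times is None else np.asarray(times, dtype=float)
    trend = lowess(y, x, frac=span, it=0, return_sorted=False)
    return trend, y - trend


@dataclass
class TrajectoryBundle:
    """A trajectory coordinate with its trend, residuals and provenance."""

    times: np.ndarray
    pc1: np.ndarray
    trend: np.ndarray
    residuals: np.ndarray
    phase: int = -1
    transition_time: Optional[float] = None

    def __post_init__(self):
        n = len(self.pc1)
        if not (len(self.times) == len(self.trend) == len(self.residuals) == n):
            raise ValueError("bundle arrays must have equal length")


def make_bundle(pc1: np.ndarray, times: np.ndarray, span: float = LOWESS_SPAN,
                phase: int = -1,
                transition_time: Optional[float] = None) -> TrajectoryBundle:
    trend, resid = detrend(pc1, times, span=span)
    return TrajectoryBundle(times=np.asarray(times, dtype=float),
                            pc1=np.asarray(pc1, dtype=float),
                            trend=trend, residuals=resid, phase=phase,
                            transition_time=transition_time)


def downsample_phases(n_or_series, factor: int = 100) -> list[np.ndarray]:
    """Index sets (or series values) of all down-sampling phases.

    Phase k takes elements k, k + factor, k + 2 factor, ...; the phases
    partition the original index set.  Given an integer, returns index
    arrays; given an array, returns value arrays.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if np.isscalar(n_or_series):
        n = int(n_or_series)
        return [np.arange(k, n, factor) for k in range(min(factor, n))]
    x = np.asarray(n_or_series)
    return [x[k::factor] for k in range(min(factor, len(x)))]


def make_null_trajectory(bundle: TrajectoryBundle,
                         rng: np.random.Generator) -> np.ndarray:
    """Trend plus residuals resampled from the first 20% of the series."""
    n = len(bundle.residuals)
    if n < 5:
        raise ValueError("need at least 5 residual points")
    pool = bundle.residuals[:max(1, int(np.ceil(0.2 * n)))]
    return bundle.trend + rng.choice(pool, size=n, replace=True)


@dataclass
class PredictionSweep:
    """Predictions over a pseudotime grid; one row per prediction time."""

    table: pd.DataFrame

    @property
    def n_available(self) -> int:
        return int(self.table["available"].sum())


def _predict_at(residuals: np.ndarray, times: np.ndarray, t: float,
                ensemble, input_length: int,
                baselines: bool) -> Optional[dict]:
    mask = times < t  # strictly preceding data only
    seg = residuals[mask]
    if len(seg) < MIN_SEGMENT:
        return None
    row: dict = {}
    probs = ensemble.predict_proba(
        normalize_and_pad(seg[-input_length:], input_length)[None, :])[0]
    row.update(p_null=float(probs[0]), p_fold=float(probs[1]),
               p_tc=float(probs[2]), p_pf=float(probs[3]))
    if baselines:
        stats = rolling_statistics(seg)
        for name in BASELINE_STATS:
            row[f"tau_{name}"] = kendall_tau(stats.by_name(name), name).kendall_tau
    return row


def prediction_sweep(bundle: TrajectoryBundle, ensemble,
                     prediction_times: Sequence[float],
                     baselines: bool = True,
                     input_length: int = 500) -> PredictionSweep:
    """Classifier and baseline predictions at each grid time.

    Each prediction uses only residuals at times strictly before the
    prediction time, tail-cropped to the classifier's input length.
    Times with fewer than 50 preceding points are marked unavailable.
    """
    rows = []
    for t in prediction_times:
        base = {"time": float(t), "available": False,
                "p_null": np.nan, "p_fold": np.nan,
                "p_tc": np.nan, "p_pf": np.nan}
        if baselines:
            base.update({f"tau_{n}": np.nan for n in BASELINE_STATS})
        got = _predict_at(bundle.residuals, bundle.times, t, ensemble,
                          input_length, baselines)
        if got is not None:
            base.update(got)
            base["available"] = True
        rows.append(base)
    return PredictionSweep(table=pd.DataFrame(rows))


# ----------------------------------------------------------------------
# in-silico perturbations

def _perturb(inp: ExpressionInput, k: int, mode: str, factor: float,
             span: float) -> tuple[ExpressionInput, TrajectoryBundle]:
    if not (0 <= k <= inp.n_genes):
        raise ValueError("k must be in [0, n_genes]")
    _, loadings, _ = compute_pc1(inp)
    top = np.argsort(-np.abs(loadings))[:k]
    matrix = inp.matrix.copy()
    if mode == "knockout":
        matrix[:, top] = 0.0
    else:
        matrix[:, top] *= factor
    out = ExpressionInput(matrix=matrix, pseudotime=inp.pseudotime.copy(),
                          cell_labels=inp.cell_labels,
                          gene_ids=inp.gene_ids)
    pc1, _, times = compute_pc1(out)
    return out, make_bundle(pc1, times, span=span)


def knockout(inp: ExpressionInput, k: int,
             span: float = LOWESS_SPAN) -> tuple[ExpressionInput, TrajectoryBundle]:
    """Zero the k genes with the largest |PC1 loading|; rebuild the bundle."""
    return _perturb(inp, k, "knockout", 0.0, span)


def overexpress(inp: ExpressionInput, k: int, factor: float = 2.0,
                span: float = LOWESS_SPAN) -> tuple[ExpressionInput, TrajectoryBundle]:
    """Scale the top-k |PC1 loading| genes by ``factor``; rebuild the bundle."""
    return _perturb(inp, k, "overexpress", factor, span)


def preprocess(inp: ExpressionInput, n_top_genes: int = 3000) -> ExpressionInput:
    """Optional normalization: library-size scale, log1p, top variable genes.

    Genes are ranked by dispersion (variance / mean of the log counts).
    Off by default throughout the package — inputs are assumed already
    log-normalized.
    """
    X = np.asarray(inp.matrix, dtype=float)
    tot = X.sum(axis=1, keepdims=True)
    tot[tot == 0] = 1.0
    X = np.log1p(X / tot * np.median(tot))
    mean = X.mean(axis=0)
    var = X.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    keep = np.sort(np.argsort(-disp)[:min(n_top_genes, X.shape[1])])
    return ExpressionInput(matrix=X[:, keep], pseudotime=inp.pseudotime.copy(),
                           cell_labels=inp.cell_labels,
                           gene_ids=np.asarray(inp.gene_ids)[keep])
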