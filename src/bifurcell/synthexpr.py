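"""Synthetic single-cell expression fixture with a planted fate transition.

Emulates the shape of pseudotime-ordered scRNA-seq datasets (a branching
latent process mapped into high-dimensional noisy expression) without
modeling regulatory kinetics: a one-dimensional latent trajectory follows
a randomized normal-form map approaching its bifurcation at a configured
pseudotime, then departs toward a new state; a subset of "informative"
genes reads the latent state through random loadings while the remaining
genes carry stationary noise.  The ground truth (class, transition time,
informative genes) is emitted alongside the matrix so recovery can be
tested.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import maps
from .maps import BifurcationClass, MapModel, sample_model
from .pipeline import ExpressionInput

__all__ = ["SyntheticExpressionConfig", "generate_synthetic_expression",
           "simulate_latent"]


@dataclass(frozen=True)
class SyntheticExpressionConfig:
    """Configuration of the planted-transition expression simulator.

    Defaults emulate a modest scRNA-seq trajectory: a few thousand cells,
    a few hundred genes of which a fifth read the latent fate coordinate,
    and per-gene observation noise of about half the (standardized)
    latent amplitude.
    """

    n_cells: int = 2000
    n_genes: int = 200
    n_informative: int = 40
    transition_pseudotime: float = 0.75
    latent_class: BifurcationClass = BifurcationClass.PITCHFORK
    mu0: Optional[float] = None
    loading_scale: float = 1.0
    noise_sd: float = 0.5
    post_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.n_informative <= self.n_genes):
            raise ValueError("n_informative must be <= n_genes")
        if not (0.0 < self.transition_pseudotime <= 1.0):
            raise ValueError("transition_pseudotime must be in (0, 1]")


def simulate_latent(config: SyntheticExpressionConfig,
                    rng: np.random.Generator) -> tuple[np.ndarray, MapModel]:
    """Latent fate coordinate over n_cells pseudotime points.

    Up to the transition: a forced normal-form run with mu ramped from
    mu0 to 0 (no truncation — the fixture keeps the whole trace, states
    clipped defensively).  After the transition: a smooth saturating
    departure of amplitude ``post_amplitude`` (in units of the pre-
    transition fluctuation scale) plus matched noise, a stylized new
    branch rather than the diverging normal form.
    """
    model = sample_model(config.latent_class, rng)
    if config.mu0 is not None:
        model = MapModel(bclass=model.bclass, alpha=model.alpha,
                         sigma=model.sigma, mu0=float(config.mu0),
                         cubic_sign=model.cubic_sign, seed=model.seed)
    n = config.n_cells
    n_pre = max(2, int(round(config.transition_pseudotime * n)))
    mu_sched = model.mu0 * (1.0 - np.arange(n_pre) / (n_pre - 1))
    x = np.empty(n)
    x[0] = maps.equilibrium(model, model.mu0)
    for t in range(1, n_pre):
        xt = maps.step_map(model, x[t - 1], mu_sched[t], rng)
        x[t] = np.clip(xt, -10.0, 10.0)
    if n_pre < n:
        k = np.arange(n - n_pre, dtype=float)
        tau = max(1.0, 0.05 * n)
        direction = -1.0 if model.bclass != BifurcationClass.PITCHFORK \
            else (1.0 if rng.random() < 0.5 else -1.0)
        scale = max(np.std(x[:n_pre]), model.sigma)
        x[n_pre:] = (x[n_pre - 1]
                     + direction * config.post_amplitude * scale
                     * (1.0 - np.exp(-k / tau))
                     + model.sigma * rng.standard_normal(n - n_pre))
    return x, model


def generate_synthetic_expression(
    config: SyntheticExpressionConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ExpressionInput, dict]:
    """Emit the expression matrix, pseudotime, and a ground-truth record.

    The latent trace is standardized by the fluctuation scale of its
    *early* segment (the first 20% of the pre-transition cells, before
    critical slowing down inflates the variance), clipped at 8 units so
    escapes and the post-transition departure stay bounded.  This keeps
    the fluctuations the early-warning methods must read at unit scale
    against the observation noise instead of being crushed by the much
    larger departure amplitude.  Informative genes get
    N(0, loading_scale) loadings on the latent state; all genes receive
    independent N(0, noise_sd) observation noise around gene-specific
    baselines.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    latent, model = simulate_latent(config, rng)
    n_pre = max(2, int(round(config.transition_pseudotime * config.n_cells)))
    head = latent[:max(2, int(0.2 * n_pre))]
    sd = head.std()
    z = np.clip((latent - head.mean()) / (sd if sd > 0 else 1.0), -8.0, 8.0)
    n, g, gi = config.n_cells, config.n_genes, config.n_informative
    baseline = rng.normal(0.0, 1.0, size=g)
    matrix = baseline[None, :] + rng.normal(0.0, config.noise_sd, size=(n, g))
    informative = rng.choice(g, size=gi, replace=False)
    loadings = rng.normal(0.0, config.loading_scale, size=gi)
    matrix[:, informative] += np.outer(z, loadings)
    pseudotime = np.linspace(0.0, 1.0, n)
    inp = ExpressionInput(matrix=matrix, pseudotime=pseudotime)
    truth = {
        "latent_class": maps.CLASS_NAMES[model.bclass],
        "transition_pseudotime": config.transition_pseudotime,
        "informative_genes": np.sort(informative).tolist(),
        "latent": latent,
        "mu0": model.mu0,
        "sigma": model.sigma,
        "n_cells": n,
        "n_genes": g,
    }
    return inp, truth
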