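"""Two-gene mutual-repression model with fold and pitchfork bifurcations.

The deterministic skeleton is

    dg1/dt = m1 / (1 + g2^2)     - kD g1
    dg2/dt = m2 / (1 + c g1^2)   - kD g2

a mutual-repression motif: each gene's synthesis is Hill-repressed by the
other, and both degrade at rate kD.  With c = 1 the system is bistable
over a parameter range and loses a stable state through a fold as m1
grows; with m1 = m2 it is symmetric and undergoes a pitchfork as kD
falls; with c = 0.1 the fold disappears, giving a null (no-bifurcation)
scenario with a still time-dependent parameter.  Trajectories are
integrated with the Euler-Maruyama scheme (additive Gaussian white
noise) and down-sampled; a pseudotime series is assembled from replicate
simulations with the wrapped-diagonal construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .dataset import build_pseudotime_set

__all__ = [
    "TwoGeneConfig",
    "Equilibrium",
    "simulate_two_gene",
    "two_gene_equilibria",
    "build_grn_pseudotime",
    "transition_index",
]


@dataclass(frozen=True)
class TwoGeneConfig:
    """Scenario parameters.  Ramped parameters are (start, end) tuples."""

    m1: float | tuple[float, float] = 1.0
    m2: float | tuple[float, float] = 3.0
    kD: float | tuple[float, float] = 1.0
    c: float = 1.0
    sigma: float = 0.05
    dt: float = 0.01
    t_end: float = 600.0
    downsample_factor: int = 100
    scenario: str = "custom"

    @classmethod
    def fold(cls) -> "TwoGeneConfig":
        """m1 ramps 1 -> 4.75; m2 = 3, kD = 1, c = 1."""
        return cls(m1=(1.0, 4.75), m2=3.0, kD=1.0, c=1.0, scenario="fold")

    @classmethod
    def pitchfork(cls) -> "TwoGeneConfig":
        """m1 = m2 = 1; kD ramps 1 -> 0.25; c = 1."""
        return cls(m1=1.0, m2=1.0, kD=(1.0, 0.25), c=1.0, scenario="pitchfork")

    @classmethod
    def null(cls) -> "TwoGeneConfig":
        """Fold preset with c = 0.1, which removes the fold."""
        return cls(m1=(1.0, 4.75), m2=3.0, kD=1.0, c=0.1, scenario="null")

    def param_at(self, frac: float) -> tuple[float, float, float]:
        """(m1, m2, kD) at ramp fraction ``frac`` in [0, 1]."""
        def val(p):
            if isinstance(p, tuple):
                return p[0] + (p[1] - p[0]) * frac
            return float(p)
        return val(self.m1), val(self.m2), val(self.kD)


@dataclass(frozen=True)
class Equilibrium:
    g1: float
    g2: float
    stable: bool


def two_gene_equilibria(m1: float, m2: float, kD: float, c: float) -> list[Equilibrium]:
    """All real equilibria at fixed parameters, with linear stability.

    Substituting g2 = m2 / (kD (1 + c g1^2)) into the g1 balance gives a
    degree-5 polynomial in g1 whose real roots are the equilibria.
    Stability comes from the Jacobian eigenvalues.
    """
    # D(x) = kD (1 + c x^2); polynomial: kD x (D^2 + m2^2) - m1 D^2 = 0
    D = np.array([kD * c, 0.0, kD])  # descending coefficients
    D2 = np.polymul(D, D)
    P = np.polysub(
        np.polymul(np.array([kD, 0.0]), np.polyadd(D2, np.array([m2 ** 2]))),
        m1 * D2,
    )
    roots = np.roots(P)
    out = []
    for r in roots:
        if abs(r.imag) > 1e-8:
            continue
        g1 = float(r.real)
        g2 = m2 / (kD * (1.0 + c * g1 ** 2))
        # Jacobian of the vector field
        j11 = -kD
        j12 = -2.0 * m1 * g2 / (1.0 + g2 ** 2) ** 2
        j21 = -2.0 * m2 * c * g1 / (1.0 + c * g1 ** 2) ** 2
        j22 = -kD
        eig = np.linalg.eigvals(np.array([[j11, j12], [j21, j22]]))
        out.append(Equilibrium(g1=g1, g2=float(g2),
                               stable=bool(np.all(eig.real < 0.0))))
    # dedupe nearly-identical roots, sorted by g1
    out.sort(key=lambda e: e.g1)
    dedup: list[Equilibrium] = []
    for e in out:
        if dedup and abs(e.g1 - dedup[-1].g1) < 1e-7:
            continue
        dedup.append(e)
    return dedup


def _initial_state(config: TwoGeneConfig) -> tuple[float, float]:
    """Stable equilibrium at the ramp start (the followed branch)."""
    m1, m2, kD = config.param_at(0.0)
    stable = [e for e in two_gene_equilibria(m1, m2, kD, config.c) if e.stable]
    if not stable:
        raise RuntimeError("no stable equilibrium at ramp start")
    # follow the low-g1 branch when multiple stable states exist
    e = min(stable, key=lambda e: e.g1)
    return e.g1, e.g2


def simulate_two_gene(
    config: TwoGeneConfig,
    rng: Optional[np.random.Generator] = None,
    n_sims: int = 1,
    initial_state: Optional[tuple[float, float]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Euler-Maruyama integration of the two-gene SDE.

    Noise increments are sigma * sqrt(dt) * N(0, 1) per gene; ramped
    parameters are updated every step (piecewise-constant over dt).
    Initial conditions default to the stable equilibrium of the
    deterministic system at the ramp start.  Output is down-sampled by
    ``config.downsample_factor``; shape (n_sims, n_out) per gene.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_steps = int(round(config.t_end / config.dt))
    g1_0, g2_0 = _initial_state(config) if initial_state is None else initial_state
    g1 = np.full(n_sims, g1_0)
    g2 = np.full(n_sims, g2_0)
    ds = config.downsample_factor
    n_out = n_steps // ds
    out1 = np.empty((n_sims, n_out))
    out2 = np.empty((n_sims, n_out))
    sqdt = np.sqrt(config.dt)
    for step in range(n_steps):
        m1, m2, kD = config.param_at(step / max(n_steps - 1, 1))
        d1 = m1 / (1.0 + g2 ** 2) - kD * g1
        d2 = m2 / (1.0 + config.c * g1 ** 2) - kD * g2
        if config.sigma > 0:
            g1 = g1 + d1 * config.dt + config.sigma * sqdt * rng.standard_normal(n_sims)
            g2 = g2 + d2 * config.dt + config.sigma * sqdt * rng.standard_normal(n_sims)
        else:
            g1 = g1 + d1 * config.dt
            g2 = g2 + d2 * config.dt
        if not (np.all(np.isfinite(g1)) and np.all(np.isfinite(g2))):
            raise RuntimeError(f"state blow-up at step {step}")
        if (step + 1) % ds == 0:
            k = (step + 1) // ds - 1
            out1[:, k] = g1
            out2[:, k] = g2
    return out1, out2


def transition_index(config: TwoGeneConfig, n_grid: int = 400) -> Optional[int]:
    """Down-sampled index where the followed branch ends, or None.

    For fold-type scenarios: the ramp fraction where the low-g1 stable
    equilibrium disappears.  For the symmetric (pitchfork) scenario: where
    the symmetric equilibrium loses stability.  Returns the corresponding
    index of the down-sampled trace.
    """
    n_steps = int(round(config.t_end / config.dt))
    n_out = n_steps // config.downsample_factor
    fracs = np.linspace(0.0, 1.0, n_grid)

    if config.scenario == "pitchfork":
        # symmetric branch persists through the bifurcation but loses
        # stability there
        for f in fracs[1:]:
            m1, m2, kD = config.param_at(f)
            eqs = two_gene_equilibria(m1, m2, kD, config.c)
            sym = min(eqs, key=lambda e: abs(e.g1 - e.g2))
            if not sym.stable:
                return int(f * (n_out - 1))
        return None

    # fold-type scenarios: continue the initially-followed stable branch;
    # a jump in the nearest stable equilibrium marks its disappearance
    g1p, g2p = _initial_state(config)
    jump_tol = 0.2
    for f in fracs[1:]:
        m1, m2, kD = config.param_at(f)
        stable = [e for e in two_gene_equilibria(m1, m2, kD, config.c) if e.stable]
        if not stable:
            return int(f * (n_out - 1))
        near = min(stable, key=lambda e: (e.g1 - g1p) ** 2 + (e.g2 - g2p) ** 2)
        if np.hypot(near.g1 - g1p, near.g2 - g2p) > jump_tol:
            return int(f * (n_out - 1))
        g1p, g2p = near.g1, near.g2
    return None


def build_grn_pseudotime(
    config: TwoGeneConfig,
    n_sims: int = 20,
    rng: Optional[np.random.Generator] = None,
    observable: str = "pc1",
) -> np.ndarray:
    """Pseudotime series set from replicate GRN simulations.

    Runs ``n_sims`` simulations, applies the wrapped-diagonal
    construction to the down-sampled traces, and returns an
    (n_sims, n_out) array of pseudotime series of the chosen observable.

    ``observable`` is "pc1" (default), "g1", or "g2".  The default
    projects each assembled (g1, g2) series onto its leading principal
    axis with the sign pinned to correlate positively with the index —
    the same trajectory coordinate the expression pipeline uses, and the
    one that weights whichever gene carries the larger variance signal
    in a given scenario.
    """
    rng = np.random.default_rng() if rng is None else rng
    g1, g2 = simulate_two_gene(config, rng=rng, n_sims=n_sims)
    if observable == "g1":
        return build_pseudotime_set(g1)
    if observable == "g2":
        return build_pseudotime_set(g2)
    if observable != "pc1":
        raise ValueError("observable must be 'pc1', 'g1', or 'g2'")
    y1 = build_pseudotime_set(g1)
    y2 = build_pseudotime_set(g2)
    out = np.empty_like(y1)
    t = np.arange(y1.shape[1])
    for i in range(y1.shape[0]):
        X = np.stack([y1[i], y2[i]], axis=1)
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1 = Xc @ vt[0]
        if np.corrcoef(pc1, t)[0, 1] < 0:
            pc1 = -pc1
        out[i] = pc1
    return out
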