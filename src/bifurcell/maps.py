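"""Randomized normal-form map models of local bifurcations.

Each model is a one-dimensional discrete-time map built from the normal
form of a fold, transcritical, or pitchfork bifurcation, decorated with
higher-order polynomial terms with random coefficients and additive white
noise.  The higher-order terms diversify the dynamics while vanishing (to
second order) at the tracked equilibrium, so the local linearization — and
hence the distance to the bifurcation — is controlled exactly by the
bifurcation parameter mu.  The bifurcation occurs at mu = 0, where the
dominant eigenvalue of the map reaches 1.

Forced simulations ramp mu linearly from a sampled mu0 up to 0; null
simulations hold mu fixed at mu0.  A noise-induced transition (deviation
from the tracked equilibrium exceeding 10 times the noise amplitude) ends
a simulation early.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "BifurcationClass",
    "CLASS_NAMES",
    "MapModel",
    "SimulationTrace",
    "sample_model",
    "step_map",
    "equilibrium",
    "dominant_eigenvalue",
    "simulate_forced",
    "simulate_null",
    "MU0_RANGES",
    "SIGMA_RANGE",
]


class BifurcationClass(enum.IntEnum):
    """The four output classes.  Index order is shared with the classifier."""

    NULL = 0
    FOLD = 1
    TRANSCRITICAL = 2
    PITCHFORK = 3


CLASS_NAMES = ("null", "fold", "transcritical", "pitchfork")

#: Sampling interval for the initial bifurcation parameter mu0, per class.
#: Chosen so the dominant eigenvalue at the start of a run lies in [0, 0.8].
MU0_RANGES = {
    BifurcationClass.FOLD: (-0.25, -0.01),
    BifurcationClass.TRANSCRITICAL: (-1.0, -0.2),
    BifurcationClass.PITCHFORK: (-1.0, -0.2),
}

#: Sampling interval for the additive noise amplitude sigma.
SIGMA_RANGE = (0.005, 0.015)

#: Lowest order of the random polynomial terms, per class.  The fold and
#: transcritical forms carry alpha_i for i = 3..10, the pitchfork for
#: i = 4..10 (its cubic term is the normal-form term itself).
_MIN_ORDER = {
    BifurcationClass.FOLD: 3,
    BifurcationClass.TRANSCRITICAL: 3,
    BifurcationClass.PITCHFORK: 4,
}
_MAX_ORDER = 10

#: Noise-induced-transition threshold, in units of sigma.
TRANSITION_FACTOR = 10.0


@dataclass(frozen=True)
class MapModel:
    """One randomized normal-form map.

    Parameters
    ----------
    bclass
        Bifurcation class (fold, transcritical, or pitchfork; never null —
        null series reuse a bifurcation-class model with frozen mu).
    alpha
        Random higher-order coefficients, index i = 3..10 for fold and
        transcritical, i = 4..10 for pitchfork.
    sigma
        Additive noise amplitude.
    mu0
        Initial bifurcation parameter.
    cubic_sign
        Sign of the cubic normal-form term (pitchfork only), +1 or -1.
    seed
        Identifier of the random stream the model was drawn from.
    """

    bclass: BifurcationClass
    alpha: np.ndarray
    sigma: float
    mu0: float
    cubic_sign: int = 1
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.bclass == BifurcationClass.NULL:
            raise ValueError("null is not a model class; use a bifurcation class with frozen mu")
        n_alpha = _MAX_ORDER - _MIN_ORDER[self.bclass] + 1
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (n_alpha,):
            raise ValueError(f"expected {n_alpha} alpha coefficients, got {alpha.shape}")
        object.__setattr__(self, "alpha", alpha)
        lo, hi = SIGMA_RANGE
        if not (0.0 < self.sigma):
            raise ValueError("sigma must be positive")
        if self.cubic_sign not in (+1, -1):
            raise ValueError("cubic_sign must be +1 or -1")

    @property
    def min_order(self) -> int:
        return _MIN_ORDER[self.bclass]


@dataclass
class SimulationTrace:
    """States and parameter schedule of one simulation.

    ``states`` and ``mu_schedule`` are truncated strictly before the first
    noise-induced transition (if any).  ``kept_states`` is the trailing
    500-point window, present only when the truncated run retains at least
    500 points.
    """

    states: np.ndarray
    mu_schedule: np.ndarray
    forced: bool
    transitioned: bool
    kept_states: Optional[np.ndarray] = None

    @property
    def valid(self) -> bool:
        return self.kept_states is not None


def sample_model(
    bclass: BifurcationClass,
    rng: np.random.Generator,
    seed: Optional[int] = None,
) -> MapModel:
    """Draw one randomized model of the given bifurcation class.

    alpha_i ~ N(0, 1); sigma ~ U(0.005, 0.015); mu0 uniform over the
    class-specific interval; the pitchfork cubic sign is a fair coin.
    """
    bclass = BifurcationClass(bclass)
    if bclass == BifurcationClass.NULL:
        raise ValueError("cannot sample a model for the null class")
    n_alpha = _MAX_ORDER - _MIN_ORDER[bclass] + 1
    alpha = rng.standard_normal(n_alpha)
    sigma = rng.uniform(*SIGMA_RANGE)
    lo, hi = MU0_RANGES[bclass]
    mu0 = rng.uniform(lo, hi)
    cubic_sign = 1
    if bclass == BifurcationClass.PITCHFORK:
        cubic_sign = int(rng.choice([-1, 1]))
    return MapModel(bclass=bclass, alpha=alpha, sigma=sigma, mu0=mu0,
                    cubic_sign=cubic_sign, seed=seed)


def _poly(alpha: np.ndarray, z, min_order: int):
    """Sum_i alpha_i z^i for i = min_order..10, via Horner on the tail."""
    acc = np.zeros_like(np.asarray(z, dtype=float))
    for k in range(alpha.shape[0] - 1, -1, -1):
        acc = acc * z + alpha[k]
    return acc * z**min_order


def _drift(bclass: BifurcationClass, x, mu, alpha, cubic_sign, min_order):
    """Deterministic part of the map, broadcasting over x/mu."""
    if bclass == BifurcationClass.FOLD:
        root = np.sqrt(-mu)
        z = x - root
        return -mu + x - x**2 + _poly(alpha, z, min_order)
    if bclass == BifurcationClass.TRANSCRITICAL:
        return (1.0 + mu) * x - x**2 + _poly(alpha, x, min_order)
    # pitchfork
    return (1.0 + mu) * x + cubic_sign * x**3 + _poly(alpha, x, min_order)


def step_map(model: MapModel, x: float, mu: float, rng: Optional[np.random.Generator] = None) -> float:
    """One application of the map at state ``x`` and parameter ``mu``.

    With ``rng`` set, adds sigma * eps with eps ~ N(0, 1); otherwise the
    deterministic map (the sigma -> 0 skeleton).
    """
    if not (np.isfinite(x) and np.isfinite(mu)):
        raise ValueError("x and mu must be finite")
    if model.bclass == BifurcationClass.FOLD and mu > 0:
        raise ValueError("fold map requires mu <= 0 (sqrt(-mu) undefined)")
    out = _drift(model.bclass, float(x), float(mu), model.alpha,
                 model.cubic_sign, model.min_order)
    if rng is not None:
        out = out + model.sigma * rng.standard_normal()
    return float(out)


def equilibrium(model: MapModel, mu) -> np.ndarray | float:
    """Tracked (stable-branch) equilibrium at parameter ``mu``.

    Fold: sqrt(-mu); transcritical and pitchfork: 0.  The random
    higher-order terms vanish there and leave it exact.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu > 0):
        raise ValueError("equilibrium defined for mu <= 0")
    if model.bclass == BifurcationClass.FOLD:
        out = np.sqrt(-mu)
    else:
        out = np.zeros_like(mu)
    return out if out.ndim else float(out)


def dominant_eigenvalue(model: MapModel, mu) -> np.ndarray | float:
    """Map derivative at the tracked equilibrium; reaches 1 at mu = 0.

    Fold: 1 - 2 sqrt(-mu); transcritical/pitchfork: 1 + mu.
    """
    mu = np.asarray(mu, dtype=float)
    if np.any(mu > 0):
        raise ValueError("dominant eigenvalue defined for mu <= 0")
    if model.bclass == BifurcationClass.FOLD:
        out = 1.0 - 2.0 * np.sqrt(-mu)
    else:
        out = 1.0 + mu
    return out if out.ndim else float(out)


def _batch_equilibrium(bclass: BifurcationClass, mu: np.ndarray) -> np.ndarray:
    if bclass == BifurcationClass.FOLD:
        return np.sqrt(np.maximum(-mu, 0.0))
    return np.zeros_like(mu)


def simulate_batch(
    bclass: BifurcationClass,
    alpha: np.ndarray,
    sigma: np.ndarray,
    mu0: np.ndarray,
    cubic_sign: np.ndarray,
    *,
    forced: bool,
    n_steps: int,
    n_sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_sims`` replicates of each of M models, vectorized.

    Parameters are arrays over models: ``alpha`` (M, K), ``sigma`` (M,),
    ``mu0`` (M,), ``cubic_sign`` (M,).  Returns ``states`` of shape
    (M, n_sims, n_steps) and ``exceed`` (M, n_sims), the index of the first
    noise-induced-transition point (``n_steps`` when none occurred).  After
    a transition a replicate is frozen; its later states are unused because
    the kept window ends strictly before the transition.
    """
    alpha = np.asarray(alpha, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    mu0 = np.asarray(mu0, dtype=float)
    cubic_sign = np.asarray(cubic_sign, dtype=float)
    M = sigma.shape[0]
    min_order = _MIN_ORDER[bclass]

    t_frac = np.arange(n_steps) / (n_steps - 1)
    if forced:
        mu_sched = mu0[:, None] * (1.0 - t_frac[None, :])  # linear mu0 -> 0, inclusive
    else:
        mu_sched = np.repeat(mu0[:, None], n_steps, axis=1)

    states = np.empty((M, n_sims, n_steps), dtype=np.float64)
    exceed = np.full((M, n_sims), n_steps, dtype=np.int64)
    active = np.ones((M, n_sims), dtype=bool)

    x = np.repeat(_batch_equilibrium(bclass, mu0)[:, None], n_sims, axis=1)
    states[:, :, 0] = x
    thresh = (TRANSITION_FACTOR * sigma)[:, None]

    alpha_b = alpha[:, None, :]  # broadcast over sims
    sign_b = cubic_sign[:, None]

    for t in range(1, n_steps):
        mu = mu_sched[:, t][:, None]
        eps = rng.standard_normal((M, n_sims))
        if bclass == BifurcationClass.FOLD:
            root = np.sqrt(-np.minimum(mu, 0.0))
            z = x - root
            drift = -mu + x - x**2
        elif bclass == BifurcationClass.TRANSCRITICAL:
            z = x
            drift = (1.0 + mu) * x - x**2
        else:
            z = x
            drift = (1.0 + mu) * x + sign_b * x**3
        acc = np.zeros_like(z)
        for k in range(alpha.shape[1] - 1, -1, -1):
            acc = acc * z + alpha_b[:, :, k]
        xn = drift + acc * z**min_order + sigma[:, None] * eps
        xn = np.where(active, xn, x)
        eq = _batch_equilibrium(bclass, mu_sched[:, t])[:, None]
        newly = active & (np.abs(xn - eq) > thresh)
        exceed[newly] = t
        active &= ~newly
        x = xn
        states[:, :, t] = x

    return states, exceed


def _simulate_one(model: MapModel, n_steps: int, rng: np.random.Generator,
                  forced: bool, keep: int = 500) -> SimulationTrace:
    if n_steps < keep:
        raise ValueError(f"n_steps must be >= {keep}")
    states, exceed = simulate_batch(
        model.bclass,
        model.alpha[None, :],
        np.array([model.sigma]),
        np.array([model.mu0]),
        np.array([model.cubic_sign]),
        forced=forced,
        n_steps=n_steps,
        n_sims=1,
        rng=rng,
    )
    states = states[0, 0]
    t_ex = int(exceed[0, 0])
    t_frac = np.arange(n_steps) / (n_steps - 1)
    mu_sched = model.mu0 * (1.0 - t_frac) if forced else np.full(n_steps, model.mu0)
    transitioned = t_ex < n_steps
    end = t_ex if transitioned else n_steps  # points [0, end) kept
    kept = states[end - keep:end].copy() if end >= keep else None
    return SimulationTrace(
        states=states[:end].copy(),
        mu_schedule=mu_sched[:end].copy(),
        forced=forced,
        transitioned=transitioned,
        kept_states=kept,
    )


def simulate_forced(model: MapModel, n_steps: int = 600,
                    rng: Optional[np.random.Generator] = None) -> SimulationTrace:
    """Ramp mu linearly from mu0 to 0 over ``n_steps`` and simulate.

    The run starts at the equilibrium for mu0.  At the first step where the
    deviation from the equilibrium at the current mu exceeds 10 sigma the
    series ends (that point excluded).  The trace is valid when at least
    500 points remain; ``kept_states`` is then the trailing 500.
    """
    rng = np.random.default_rng() if rng is None else rng
    return _simulate_one(model, n_steps, rng, forced=True)


def simulate_null(model: MapModel, n_steps: int = 600,
                  rng: Optional[np.random.Generator] = None) -> SimulationTrace:
    """As :func:`simulate_forced` but with mu frozen at mu0 throughout."""
    rng = np.random.default_rng() if rng is None else rng
    return _simulate_one(model, n_steps, rng, forced=False)
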