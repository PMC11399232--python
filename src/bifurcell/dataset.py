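"""Labeled pseudotime-series corpus built from normal-form map simulations.

A pseudotime series mimics single-cell pseudotime data: consecutive points
come from *different* replicate simulations of the same model, which removes
the temporal autocorrelation a single stochastic trajectory would carry
while preserving ensemble signatures of an approaching bifurcation (rising
variance).  Given 20 replicate simulations of 500 points each, arranged as
a 20 x 500 matrix x[s, t], the i-th pseudotime series is the wrapped
diagonal

    y[i, t] = x[(i + t) mod 20, t].

The default corpus holds 1000 models per bifurcation class, 20 forced
series each (fold / transcritical / pitchfork), plus an equal number of
null series simulated with mu frozen: 80 000 series of length 500, split
0.95 / 0.025 / 0.025 into train / validation / test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .maps import (
    MU0_RANGES,
    SIGMA_RANGE,
    BifurcationClass,
    CLASS_NAMES,
    SimulationTrace,
    simulate_batch,
)

__all__ = [
    "PseudotimeSeries",
    "LabeledDataset",
    "build_pseudotime_set",
    "generate_dataset",
    "SPLIT_FRACTIONS",
    "SPLIT_NAMES",
]

SPLIT_FRACTIONS = (0.95, 0.025, 0.025)
SPLIT_NAMES = ("train", "val", "test")

_BIF_CLASSES = (
    BifurcationClass.FOLD,
    BifurcationClass.TRANSCRITICAL,
    BifurcationClass.PITCHFORK,
)


@dataclass(frozen=True)
class PseudotimeSeries:
    """One labeled 500-point pseudotime series."""

    values: np.ndarray
    label: BifurcationClass
    model_id: int = -1
    offset: int = -1


def build_pseudotime_set(traces) -> np.ndarray:
    """Wrapped-diagonal construction over equal-length replicate traces.

    Accepts a sequence of n :class:`~bifurcell.maps.SimulationTrace` (their
    ``kept_states``) or an (n, T) array.  Returns an (n, T) array ``y`` with
    ``y[i, t] = x[(i + t) mod n, t]``; the outputs jointly use every
    (simulation, time) cell exactly once, so the value multiset is
    conserved.
    """
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    rows = []
    for tr in traces:
        if isinstance(tr, SimulationTrace):
            if tr.kept_states is None:
                raise ValueError("all traces must be valid (500 kept points)")
            rows.append(np.asarray(tr.kept_states, dtype=float))
        else:
            rows.append(np.asarray(tr, dtype=float))
    lengths = {r.shape for r in rows}
    if len(lengths) != 1 or rows[0].ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    x = np.stack(rows)
    n, T = x.shape
    idx = (np.arange(n)[:, None] + np.arange(T)[None, :]) % n
    return x[idx, np.arange(T)[None, :]]


@dataclass
class LabeledDataset:
    """The shuffled, split corpus.

    ``values`` is (N, 500) float32, ``labels`` (N,) int with the
    :class:`BifurcationClass` encoding, ``split`` (N,) int with
    0 = train, 1 = val, 2 = test.  ``meta`` carries one row per series:
    id, label, split, model_seed, sigma, mu0.
    """

    values: np.ndarray
    labels: np.ndarray
    split: np.ndarray
    meta: pd.DataFrame
    seed: int

    def subset(self, part: str) -> tuple[np.ndarray, np.ndarray]:
        code = SPLIT_NAMES.index(part)
        m = self.split == code
        return self.values[m], self.labels[m]

    @property
    def n_series(self) -> int:
        return self.values.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {CLASS_NAMES[c]: int(np.sum(self.labels == c)) for c in range(4)}

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(outdir / "series.npz", values=self.values,
                            labels=self.labels, split=self.split)
        self.meta.to_csv(outdir / "meta.csv", index=False)
        (outdir / "dataset.json").write_text(json.dumps({"seed": self.seed}))

    @classmethod
    def load(cls, outdir: str | Path) -> "LabeledDataset":
        outdir = Path(outdir)
        with np.load(outdir / "series.npz") as z:
            values, labels, split = z["values"], z["labels"], z["split"]
        meta = pd.read_csv(outdir / "meta.csv")
        seed = json.loads((outdir / "dataset.json").read_text())["seed"]
        return cls(values=values, labels=labels, split=split, meta=meta, seed=seed)


def _sample_params(bclass: BifurcationClass, seeds: np.ndarray):
    """Model parameters deterministically derived from per-model seeds."""
    n = len(seeds)
    n_alpha = 8 if bclass != BifurcationClass.PITCHFORK else 7
    alpha = np.empty((n, n_alpha))
    sigma = np.empty(n)
    mu0 = np.empty(n)
    sign = np.ones(n)
    lo, hi = MU0_RANGES[bclass]
    for i, s in enumerate(seeds):
        r = np.random.default_rng(int(s))
        alpha[i] = r.standard_normal(n_alpha)
        sigma[i] = r.uniform(*SIGMA_RANGE)
        mu0[i] = r.uniform(lo, hi)
        if bclass == BifurcationClass.PITCHFORK:
            sign[i] = r.choice([-1, 1])
    return alpha, sigma, mu0, sign


def _extract_kept(states: np.ndarray, exceed: np.ndarray, keep: int) -> np.ndarray:
    """Trailing ``keep``-point window ending strictly before the transition."""
    M, S, n_steps = states.shape
    end = np.minimum(exceed, n_steps)
    start = end - keep  # caller guarantees validity (start >= 0)
    cols = start[:, :, None] + np.arange(keep)[None, None, :]
    return np.take_along_axis(states, cols, axis=2)


def _generate_class(
    bclass: BifurcationClass,
    n_models: int,
    forced: bool,
    rng: np.random.Generator,
    n_steps: int,
    sims_per_model: int,
    keep: int,
    retry_cap: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Generate n_models valid models' worth of pseudotime series.

    A model with any invalid replicate (transition leaving < ``keep``
    points) is discarded and replaced by a freshly drawn model, up to
    ``retry_cap`` attempts per slot.
    """
    seeds = rng.integers(0, 2**31, size=n_models)
    alpha, sigma, mu0, sign = _sample_params(bclass, seeds)
    states, exceed = simulate_batch(
        bclass, alpha, sigma, mu0, sign,
        forced=forced, n_steps=n_steps, n_sims=sims_per_model, rng=rng)
    valid = (exceed >= keep).all(axis=1)
    tries = 0
    while not valid.all():
        tries += 1
        if tries > retry_cap:
            raise RuntimeError(
                f"model replacement exceeded retry cap ({retry_cap}) for class "
                f"{CLASS_NAMES[bclass]}: pathological parameter region")
        bad = np.flatnonzero(~valid)
        new_seeds = rng.integers(0, 2**31, size=len(bad))
        a2, s2, m2, g2 = _sample_params(bclass, new_seeds)
        st2, ex2 = simulate_batch(
            bclass, a2, s2, m2, g2,
            forced=forced, n_steps=n_steps, n_sims=sims_per_model, rng=rng)
        ok2 = (ex2 >= keep).all(axis=1)
        seeds[bad] = new_seeds
        alpha[bad] = a2
        sigma[bad] = s2
        mu0[bad] = m2
        sign[bad] = g2
        states[bad] = st2
        exceed[bad] = ex2
        valid[bad] = ok2

    kept = _extract_kept(states, exceed, keep)  # (M, S, keep)
    # wrapped-diagonal construction, vectorized over models
    S = sims_per_model
    idx = (np.arange(S)[:, None] + np.arange(keep)[None, :]) % S
    series = kept[:, idx, np.arange(keep)[None, :]]  # (M, S, keep)
    series = series.reshape(n_models * S, keep).astype(np.float32)
    label = int(bclass) if forced else int(BifurcationClass.NULL)
    meta = pd.DataFrame({
        "label": label,
        "model_seed": np.repeat(seeds, S),
        "sigma": np.repeat(sigma, S),
        "mu0": np.repeat(mu0, S),
    })
    return series, meta


def split_counts(n: int, fractions: Sequence[float] = SPLIT_FRACTIONS) -> tuple[int, int, int]:
    n_val = int(round(n * fractions[1]))
    n_test = int(round(n * fractions[2]))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(
    n_models_per_class: int = 1000,
    sims_per_model: int = 20,
    shuffle_seed: int = 0,
    n_steps: int = 600,
    series_length: int = 500,
    retry_cap: int = 100,
) -> LabeledDataset:
    """Generate the full labeled corpus.

    For each bifurcation class, ``n_models_per_class`` models each
    contribute ``sims_per_model`` forced pseudotime series.  An equal
    number of null series comes from models with mu frozen at mu0, their
    classes assigned round-robin over the three bifurcation classes.  All
    series are shuffled and partitioned 0.95 / 0.025 / 0.025.
    """
    if n_models_per_class < 1:
        raise ValueError("n_models_per_class must be >= 1")
    if n_steps < series_length:
        raise ValueError("n_steps must be >= series_length")
    ss = np.random.SeedSequence(shuffle_seed)
    children = ss.spawn(5)
    all_values, all_meta = [], []
    for bclass, child in zip(_BIF_CLASSES, children[:3]):
        v, m = _generate_class(
            bclass, n_models_per_class, True, np.random.default_rng(child),
            n_steps, sims_per_model, series_length, retry_cap)
        all_values.append(v)
        all_meta.append(m)
    # null models: round-robin over the three bifurcation classes
    base, rem = divmod(n_models_per_class, 3)
    null_rng = np.random.default_rng(children[3])
    for j, bclass in enumerate(_BIF_CLASSES):
        n_j = base + (1 if j < rem else 0)
        if n_j == 0:
            continue
        v, m = _generate_class(
            bclass, n_j, False, null_rng,
            n_steps, sims_per_model, series_length, retry_cap)
        all_values.append(v)
        all_meta.append(m)

    values = np.concatenate(all_values)
    meta = pd.concat(all_meta, ignore_index=True)
    labels = meta["label"].to_numpy(dtype=np.int8)
    N = values.shape[0]

    shuffle_rng = np.random.default_rng(children[4])
    perm = shuffle_rng.permutation(N)
    values, labels = values[perm], labels[perm]
    meta = meta.iloc[perm].reset_index(drop=True)

    n_train, n_val, n_test = split_counts(N)
    split = np.empty(N, dtype=np.int8)
    split[:n_train] = 0
    split[n_train:n_train + n_val] = 1
    split[n_train + n_val:] = 2

    meta.insert(0, "id", np.arange(N))
    meta.insert(2, "split", [SPLIT_NAMES[s] for s in split])
    return LabeledDataset(values=values, labels=labels, split=split,
                          meta=meta, seed=shuffle_seed)
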