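"""Censoring, normalization, training loop, evaluation, and ensembling.

The input contract of the classifier: a contiguous segment of a 500-point
pseudotime series, between 50 and 500 points long, normalized by its mean
absolute value and prepended with zeros to a fixed length of 500.  During
training the segment is re-drawn every epoch as data augmentation; variant
1 censors both ends (uniform start), variant 2 censors only the beginning
(segment anchored at the series end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score

from .network import BifurcationNet, NetworkSpec, build_network

__all__ = [
    "DegenerateSegmentError",
    "censor",
    "censor_batch",
    "normalize_and_pad",
    "Adam",
    "TrainingHistory",
    "train",
    "EvalResult",
    "evaluate",
    "ProbabilityVector",
    "Ensemble",
]

MIN_SEGMENT = 50


class DegenerateSegmentError(ValueError):
    """Raised when a segment's mean absolute value is numerically zero."""


def censor(series: np.ndarray, variant: int,
           rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Draw a censored segment of a 500-point series.

    L ~ U{50..500}; variant 1: start ~ U{0..500-L}; variant 2:
    start = 500 - L (segment ends at the series end).
    """
    series = np.asarray(series)
    T = series.shape[0]
    L = int(rng.integers(MIN_SEGMENT, T + 1))
    if variant == 1:
        start = int(rng.integers(0, T - L + 1))
    else:
        start = T - L
    return series[start:start + L], start


def normalize_and_pad(segment: np.ndarray, length: int = 500) -> np.ndarray:
    """Divide by mean |value| and left-pad with zeros to ``length``."""
    segment = np.asarray(segment, dtype=np.float32)
    L = segment.shape[0]
    if not (1 <= L <= length):
        raise ValueError(f"segment length must be in [1, {length}]")
    m = float(np.mean(np.abs(segment)))
    if m < 1e-12:
        raise DegenerateSegmentError("segment mean absolute value is ~0")
    out = np.zeros(length, dtype=np.float32)
    out[length - L:] = segment / m
    return out


def censor_batch(X: np.ndarray, variant: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Vectorized censor + normalize + pad over (N, 500) series."""
    N, T = X.shape
    L = rng.integers(MIN_SEGMENT, T + 1, size=N)
    if variant == 1:
        start = rng.integers(0, T - L + 1)
    else:
        start = T - L
    pos = np.arange(T)[None, :]
    lead = (T - L)[:, None]
    src = np.clip(start[:, None] + pos - lead, 0, T - 1)
    mask = pos >= lead
    G = np.take_along_axis(X, src, axis=1) * mask
    norm = np.abs(G).sum(axis=1) / L
    norm = np.where(norm < 1e-12, 1.0, norm)
    return (G / norm[:, None]).astype(np.float32)


def _onehot(y: np.ndarray, n_classes: int = 4) -> np.ndarray:
    out = np.zeros((y.shape[0], n_classes), dtype=np.float32)
    out[np.arange(y.shape[0]), y] = 1.0
    return out


class Adam:
    """Adam optimizer over a flat list of (param, grad) pairs."""

    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self, params) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_loss(self) -> float:
        return self.val_loss[self.best_epoch]


def _xent(probs: np.ndarray, y: np.ndarray) -> float:
    p = probs[np.arange(y.shape[0]), y]
    return float(-np.mean(np.log(np.clip(p, 1e-12, None))))


def train(
    dataset,
    spec: NetworkSpec,
    seed: int = 0,
    epochs_max: int = 200,
    lr: float = 5e-4,
    batch_size: int = 1024,
    patience: int = 20,
    verbose: bool = False,
) -> tuple[BifurcationNet, TrainingHistory]:
    """Train one network; return the best-validation-loss checkpoint.

    Censoring is re-drawn for the training partition every epoch; the
    validation partition is censored once (seed-derived) so the checkpoint
    metric is stable across epochs.
    """
    Xtr, ytr = dataset.subset("train")
    Xval, yval = dataset.subset("val")
    if len(Xtr) == 0 or len(Xval) == 0:
        raise ValueError("dataset must have non-empty train and val partitions")
    ss = np.random.SeedSequence(seed)
    s_init, s_cens, s_order, s_val = ss.spawn(4)
    net = build_network(spec, seed=int(s_init.generate_state(1)[0] % 2**31))
    cens_rng = np.random.default_rng(s_cens)
    order_rng = np.random.default_rng(s_order)
    Xval_c = censor_batch(Xval, spec.variant, np.random.default_rng(s_val))
    yval_1h = _onehot(yval)

    opt = Adam(net.parameters(), lr=lr)
    hist = TrainingHistory()
    best_weights = net.get_weights()
    best_val = np.inf
    stale = 0
    for epoch in range(epochs_max):
        Xc = censor_batch(Xtr, spec.variant, cens_rng)
        order = order_rng.permutation(len(Xc))
        losses = []
        for lo in range(0, len(Xc), batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = Xc[idx], ytr[idx]
            probs = net.forward(xb, training=True)
            losses.append(_xent(probs, yb) * len(idx))
            net.backward(probs, _onehot(yb))
            opt.step(net.parameters())
        hist.train_loss.append(float(np.sum(losses) / len(Xc)))
        vprobs = net.forward(Xval_c, training=False)
        vloss = _xent(vprobs, yval)
        hist.val_loss.append(vloss)
        if vloss < best_val - 1e-6:
            best_val = vloss
            best_weights = net.get_weights()
            hist.best_epoch = epoch
            stale = 0
        else:
            stale += 1
        if verbose:
            print(f"epoch {epoch}: train {hist.train_loss[-1]:.4f} val {vloss:.4f}")
        if stale >= patience:
            break
    net.set_weights(best_weights)
    return net, hist


@dataclass
class EvalResult:
    f1_multiclass: float
    f1_binary: float
    confusion: np.ndarray  # row-normalized by true class


def evaluate(predictor, X: np.ndarray, y: np.ndarray,
             variant: int | None = None,
             rng: np.random.Generator | None = None) -> EvalResult:
    """Evaluate on a held-out partition.

    ``predictor`` maps (N, 500) inputs to (N, 4) probabilities (a network
    or an :class:`Ensemble`).  With ``variant`` set, inputs are censored
    per that variant's scheme first (``rng`` required).  Multiclass F1 is
    macro-averaged; binary F1 collapses fold/TC/PF into "bifurcation"
    (the positive class).
    """
    if variant is not None:
        if rng is None:
            rng = np.random.default_rng(0)
        X = censor_batch(np.asarray(X), variant, rng)
    probs = predictor.predict_proba(X) if hasattr(predictor, "predict_proba") else predictor(X)
    pred = probs.argmax(axis=1)
    f1_multi = f1_score(y, pred, average="macro", labels=[0, 1, 2, 3],
                        zero_division=0)
    f1_bin = f1_score((y > 0).astype(int), (pred > 0).astype(int),
                      zero_division=0)
    conf = confusion_matrix(y, pred, labels=[0, 1, 2, 3], normalize="true")
    return EvalResult(float(f1_multi), float(f1_bin), conf)


@dataclass(frozen=True)
class ProbabilityVector:
    """Class probabilities in the fixed order (null, fold, TC, PF)."""

    p_null: float
    p_fold: float
    p_tc: float
    p_pf: float

    def __post_init__(self):
        arr = self.as_array()
        if np.any(arr < -1e-9) or abs(arr.sum() - 1.0) > 1e-5:
            raise ValueError("probabilities must be in [0,1] and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_null, self.p_fold, self.p_tc, self.p_pf])

    @classmethod
    def from_array(cls, a) -> "ProbabilityVector":
        a = np.asarray(a, dtype=float)
        return cls(*a.tolist())

    @property
    def argmax(self) -> int:
        return int(self.as_array().argmax())


class Ensemble:
    """Average of trained member networks (5 of each variant at full scale)."""

    def __init__(self, members: list[BifurcationNet]):
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = members

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.mean([m.predict_proba(X) for m in self.members], axis=0)

    def predict_series(self, padded: np.ndarray) -> ProbabilityVector:
        """Prediction for one already-normalized, zero-prepended series."""
        return ProbabilityVector.from_array(self.predict_proba(padded)[0])

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, m in enumerate(self.members):
            fn = f"member_{i}.npz"
            m.save(outdir / fn)
            manifest.append({"file": fn, "variant": m.spec.variant,
                             "n_params": m.n_params})
        (outdir / "ensemble.json").write_text(json.dumps({"members": manifest}))

    @classmethod
    def load(cls, outdir) -> "Ensemble":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "ensemble.json").read_text())
        return cls([BifurcationNet.load(outdir / m["file"])
                    for m in manifest["members"]])
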