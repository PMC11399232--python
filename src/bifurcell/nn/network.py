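"""CNN-LSTM bifurcation classifier: architecture spec and network.

Two variants share the layer stack

    conv(12, same, ReLU) -> dropout(0.1) -> maxpool(2, 2)
    -> conv -> dropout -> maxpool
    -> LSTM(U1, sequences) -> LSTM(U2, final state) -> dense softmax(4)

and differ in their width and in how their training inputs are censored:
variant 1 (50 filters, 100 + 20 LSTM units) trains on series censored at
both ends, variant 2 (100 filters, 50 + 20 LSTM units) on series censored
only at the beginning, so it sees data right up to the bifurcation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import LSTM, Conv1D, Dense, Dropout, MaxPool1D

__all__ = ["NetworkSpec", "count_parameters", "BifurcationNet", "build_network"]


@dataclass(frozen=True)
class NetworkSpec:
    variant: int
    conv_filters: int
    lstm1_units: int
    lstm2_units: int = 20
    kernel_width: int = 12
    pool_size: int = 2
    pool_stride: int = 2
    dropout_fraction: float = 0.10
    n_classes: int = 4
    input_length: int = 500

    def __post_init__(self):
        if self.variant not in (1, 2):
            raise ValueError("variant must be 1 or 2")
        if self.pool_size != self.pool_stride:
            raise ValueError("only pool_size == pool_stride is supported")

    @classmethod
    def variant1(cls) -> "NetworkSpec":
        return cls(variant=1, conv_filters=50, lstm1_units=100)

    @classmethod
    def variant2(cls) -> "NetworkSpec":
        return cls(variant=2, conv_filters=100, lstm1_units=50)

    @classmethod
    def scaled(cls, variant: int) -> "NetworkSpec":
        """Reduced-width spec for desk-scale runs (same depth and shape)."""
        if variant == 1:
            return cls(variant=1, conv_filters=8, lstm1_units=16, lstm2_units=8)
        return cls(variant=2, conv_filters=16, lstm1_units=8, lstm2_units=8)


def count_parameters(spec: NetworkSpec) -> int:
    """Analytic trainable-parameter total of the layer stack.

    (K + 1) F  +  (K F + 1) F  +  4 (F + U1 + 1) U1
    + 4 (U1 + U2 + 1) U2  +  (U2 + 1) n_classes,
    with K the kernel width, F the filter count, U1/U2 the LSTM widths.
    """
    K, F = spec.kernel_width, spec.conv_filters
    U1, U2, C = spec.lstm1_units, spec.lstm2_units, spec.n_classes
    return ((K * 1 + 1) * F
            + (K * F + 1) * F
            + 4 * (F + U1 + 1) * U1
            + 4 * (U1 + U2 + 1) * U2
            + (U2 + 1) * C)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class BifurcationNet:
    """The CNN-LSTM network with forward, backward, and weight I/O."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        F, K = spec.conv_filters, spec.kernel_width
        p = spec.dropout_fraction
        self.conv1 = Conv1D(1, F, K, rng)
        self.drop1 = Dropout(p, rng)
        self.pool1 = MaxPool1D()
        self.conv2 = Conv1D(F, F, K, rng)
        self.drop2 = Dropout(p, rng)
        self.pool2 = MaxPool1D()
        self.lstm1 = LSTM(F, spec.lstm1_units, return_sequences=True, rng=rng)
        self.lstm2 = LSTM(spec.lstm1_units, spec.lstm2_units,
                          return_sequences=False, rng=rng)
        self.dense = Dense(spec.lstm2_units, spec.n_classes, rng)
        self._trainable = [self.conv1, self.conv2, self.lstm1, self.lstm2, self.dense]
        self._stack = [self.conv1, self.drop1, self.pool1,
                       self.conv2, self.drop2, self.pool2,
                       self.lstm1, self.lstm2, self.dense]

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(v.size for layer in self._trainable
                   for v in layer.params.values())

    def parameters(self):
        """Flat list of (param, grad) array pairs, in a fixed order."""
        out = []
        for layer in self._trainable:
            for k in sorted(layer.params):
                out.append((layer.params[k], layer.grads[k]))
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.parameters(), weights):
            p[...] = w

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Class probabilities for inputs of shape (B, input_length)."""
        h = np.asarray(x, dtype=np.float32)[:, :, None]
        for layer in self._stack:
            h = layer.forward(h, training=training)
        return _softmax(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.forward(np.atleast_2d(x), training=False)

    def backward(self, probs: np.ndarray, onehot: np.ndarray) -> None:
        """Backprop of the mean categorical cross-entropy loss."""
        B = probs.shape[0]
        grad = (probs - onehot).astype(np.float32) / B
        for layer in reversed(self._stack):
            grad = layer.backward(grad)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(path, *(w for w in self.get_weights()),
                            variant=self.spec.variant,
                            conv_filters=self.spec.conv_filters,
                            lstm1_units=self.spec.lstm1_units,
                            lstm2_units=self.spec.lstm2_units)

    @classmethod
    def load(cls, path) -> "BifurcationNet":
        with np.load(path) as z:
            spec = NetworkSpec(variant=int(z["variant"]),
                               conv_filters=int(z["conv_filters"]),
                               lstm1_units=int(z["lstm1_units"]),
                               lstm2_units=int(z["lstm2_units"]))
            net = cls(spec, seed=0)
            weights = [z[f"arr_{i}"] for i in range(len(net.get_weights()))]
        net.set_weights(weights)
        return net


def build_network(spec: NetworkSpec, seed: int = 0) -> BifurcationNet:
    """Build a network with seed-deterministic initial weights."""
    return BifurcationNet(spec, seed=seed)
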