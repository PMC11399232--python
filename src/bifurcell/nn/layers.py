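"""NumPy building blocks for the CNN-LSTM bifurcation classifier.

Each layer exposes ``forward(x, training)`` and ``backward(grad)``;
trainable layers hold ``params`` and ``grads`` dicts of arrays with
matching keys.  All computation is float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv1D", "Dropout", "MaxPool1D", "LSTM", "Dense"]


def _glorot(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


class Conv1D:
    """1-D convolution with 'same' zero padding and ReLU activation.

    For an even kernel width K the window at output position i covers
    input positions i - (K//2 - 1) .. i + K//2, realized by padding
    K//2 - 1 zeros on the left and K//2 on the right.
    """

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        self.c_in, self.filters, self.kernel = c_in, filters, kernel
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2
        W = _glorot(rng, (kernel, c_in, filters), kernel * c_in, filters)
        self.params = {"W": W, "b": np.zeros(filters, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    @property
    def n_params(self) -> int:
        return (self.kernel * self.c_in + 1) * self.filters

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # win: (B, T, C, K) -> columns (B*T, K*C)
        col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B * T, self.kernel * C)
        Wf = self.params["W"].reshape(self.kernel * C, self.filters)
        z = col @ Wf + self.params["b"]
        mask = z > 0
        out = np.where(mask, z, 0.0).reshape(B, T, self.filters)
        self._cache = (col, mask, (B, T, C))
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        col, mask, (B, T, C) = self._cache
        dz = grad.reshape(B * T, self.filters) * mask
        Wf = self.params["W"].reshape(self.kernel * C, self.filters)
        self.grads["W"][...] = (col.T @ dz).reshape(self.params["W"].shape)
        self.grads["b"][...] = dz.sum(axis=0)
        dcol = (dz @ Wf.T).reshape(B, T, self.kernel, C)
        dxp = np.zeros((B, T + self.pad_left + self.pad_right, C), dtype=np.float32)
        for k in range(self.kernel):
            dxp[:, k:k + T, :] += dcol[:, :, k, :]
        return dxp[:, self.pad_left:self.pad_left + T, :]


class Dropout:
    """Inverted dropout; active only when training."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class MaxPool1D:
    """Max pooling with pool size 2 and stride 2 (length must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, C = x.shape
        r = x.reshape(B, T // 2, 2, C)
        arg = r.argmax(axis=2)
        out = np.take_along_axis(r, arg[:, :, None, :], axis=2)[:, :, 0, :]
        self._cache = (arg, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        arg, (B, T, C) = self._cache
        dr = np.zeros((B, T // 2, 2, C), dtype=np.float32)
        np.put_along_axis(dr, arg[:, :, None, :], grad[:, :, None, :], axis=2)
        return dr.reshape(B, T, C)


class LSTM:
    """Standard LSTM with forget/input/output gates and tanh cell input.

    Gate pre-activations are z = x_t W + h_{t-1} U + b, split into
    (input, forget, cell, output) blocks; the forget-gate bias is
    initialized to 1.  h_0 = c_0 = 0.  ``return_sequences`` selects the
    full hidden sequence vs only the final hidden state.
    """

    def __init__(self, c_in: int, units: int, return_sequences: bool,
                 rng: np.random.Generator):
        self.c_in, self.units = c_in, units
        self.return_sequences = return_sequences
        U4 = 4 * units
        W = _glorot(rng, (c_in, U4), c_in, U4)
        Ur = _glorot(rng, (units, U4), units, U4)
        b = np.zeros(U4, dtype=np.float32)
        b[units:2 * units] = 1.0  # forget bias
        self.params = {"W": W, "U": Ur, "b": b}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    @property
    def n_params(self) -> int:
        return 4 * (self.c_in + self.units + 1) * self.units

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, T, C = x.shape
        U = self.units
        W, Ur, b = self.params["W"], self.params["U"], self.params["b"]
        h = np.zeros((B, U), dtype=np.float32)
        c = np.zeros((B, U), dtype=np.float32)
        gates = np.empty((T, B, 4 * U), dtype=np.float32)
        cs = np.empty((T, B, U), dtype=np.float32)
        cprev = np.empty((T, B, U), dtype=np.float32)
        hprev = np.empty((T, B, U), dtype=np.float32)
        hs = np.empty((T, B, U), dtype=np.float32)
        xW = x.reshape(B * T, C) @ W  # precompute input contributions
        xW = xW.reshape(B, T, 4 * U)
        for t in range(T):
            z = xW[:, t, :] + h @ Ur + b
            i = _sigmoid(z[:, :U])
            f = _sigmoid(z[:, U:2 * U])
            g = np.tanh(z[:, 2 * U:3 * U])
            o = _sigmoid(z[:, 3 * U:])
            cprev[t] = c
            hprev[t] = h
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[t] = np.concatenate([i, f, g, o], axis=1)
            cs[t] = c
            hs[t] = h
        self._cache = (x, gates, cs, cprev, hprev)
        if self.return_sequences:
            return hs.transpose(1, 0, 2)
        return h

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x, gates, cs, cprev, hprev = self._cache
        B, T, C = x.shape
        U = self.units
        W, Ur = self.params["W"], self.params["U"]
        if self.return_sequences:
            dh_seq = grad.transpose(1, 0, 2)
        else:
            dh_seq = None
        dW = np.zeros_like(W)
        dU = np.zeros_like(Ur)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh_next = grad.astype(np.float32) if dh_seq is None else np.zeros((B, U), dtype=np.float32)
        dc_next = np.zeros((B, U), dtype=np.float32)
        for t in range(T - 1, -1, -1):
            dh = dh_next + (dh_seq[t] if dh_seq is not None else 0.0)
            i = gates[t, :, :U]
            f = gates[t, :, U:2 * U]
            g = gates[t, :, 2 * U:3 * U]
            o = gates[t, :, 3 * U:]
            tc = np.tanh(cs[t])
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * cprev[t]
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dW += x[:, t, :].T @ dz
            dU += hprev[t].T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ W.T
            dh_next = dz @ Ur.T
        self.grads["W"][...] = dW
        self.grads["U"][...] = dU
        self.grads["b"][...] = db
        return dx


class Dense:
    """Fully connected layer (linear; softmax applied by the network)."""

    def __init__(self, c_in: int, units: int, rng: np.random.Generator):
        self.c_in, self.units = c_in, units
        self.params = {"W": _glorot(rng, (c_in, units), c_in, units),
                       "b": np.zeros(units, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    @property
    def n_params(self) -> int:
        return (self.c_in + 1) * self.units

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._cache = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x = self._cache
        self.grads["W"][...] = x.T @ grad
        self.grads["b"][...] = grad.sum(axis=0)
        return grad @ self.params["W"].T
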