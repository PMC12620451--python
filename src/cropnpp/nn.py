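"""Minimal 1-D convolutional network for tabular spectral regression.

A deliberately small, fully transparent numpy implementation of the FPAR
regression network: three 1-D convolutional layers (16, 32, 64 filters,
kernel size 2, 'same' padding, ReLU), each followed by max-pooling of
size 2 (ceil mode, so a 15-long feature vector survives three poolings:
15 -> 8 -> 4 -> 2), inverted dropout on the flattened activations, then
three dense layers ending in a scalar linear output. Trained with Adam
on mean squared error.

Every layer implements ``forward`` and ``backward`` with analytic
gradients; the whole network is checked against numerical gradients in
the test suite. All randomness (initialization, shuffling, dropout)
flows through a single ``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np


class Conv1D:
    """1-D convolution, stride 1, 'same' padding (pad right by kernel-1)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (kernel * in_ch + out_ch))  # Glorot uniform
        self.W = rng.uniform(-lim, lim, size=(kernel, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.kernel = kernel

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (N, L, Cin) -> (N, L, Cout)
        n, L, _ = x.shape
        k = self.kernel
        xp = np.pad(x, ((0, 0), (0, k - 1), (0, 0)))
        self._xp, self._L = xp, L
        z = np.zeros((n, L, self.b.size))
        for j in range(k):
            z += xp[:, j:j + L, :] @ self.W[j]
        return z + self.b

    def backward(self, dz: np.ndarray):
        xp, L, k = self._xp, self._L, self.kernel
        self.dW = np.empty_like(self.W)
        for j in range(k):
            self.dW[j] = np.einsum("nli,nlo->io", xp[:, j:j + L, :], dz)
        self.db = dz.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        for j in range(k):
            dxp[:, j:j + L, :] += dz @ self.W[j].T
        return dxp[:, :L, :]

    @property
    def grads(self):
        return [self.dW, self.db]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, d):
        return d * self._mask


class MaxPool1D:
    """Max pooling, size 2, stride 2, ceil mode (odd lengths padded)."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, L, c = x.shape
        self._L = L
        L2 = -(-L // 2)
        if L % 2:
            x = np.pad(x, ((0, 0), (0, 1), (0, 0)), constant_values=-np.inf)
        xr = x.reshape(n, L2, 2, c)
        self._arg = np.argmax(xr, axis=2)
        return np.max(xr, axis=2)

    def backward(self, d: np.ndarray):
        n, L2, c = d.shape
        dxr = np.zeros((n, L2, 2, c))
        np.put_along_axis(dxr, self._arg[:, :, None, :], d[:, :, None, :], axis=2)
        dx = dxr.reshape(n, L2 * 2, c)
        return dx[:, : self._L, :]


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, d):
        return d.reshape(self._shape)


class Dropout:
    """Inverted dropout; identity outside training mode."""

    params: list = []
    grads: list = []

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self.training = False

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, d):
        return d if self._mask is None else d * self._mask


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        lim = np.sqrt(6.0 / (n_in + n_out))  # Glorot uniform
        self.W = rng.uniform(-lim, lim, size=(n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, d):
        self.dW = self._x.T @ d
        self.db = d.sum(axis=0)
        return d @ self.W.T

    @property
    def grads(self):
        return [self.dW, self.db]


class Adam:
    def __init__(self, params: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Cnn1DRegressor:
    """The FPAR regression network.

    Parameters mirror the published configuration: conv filter counts
    (16, 32, 64), kernel size 2, dropout 0.3, three dense layers, Adam
    at learning rate 1e-3, MSE loss.
    """

    def __init__(self, n_features: int,
                 conv_filters: tuple[int, ...] = (16, 32, 64),
                 kernel_size: int = 2, dropout_rate: float = 0.3,
                 dense_units: tuple[int, ...] = (64, 32),
                 seed: int = 42):
        self.n_features = n_features
        self.rng = np.random.default_rng(seed)
        layers: list = []
        length, ch = n_features, 1
        for f in conv_filters:
            layers += [Conv1D(ch, f, kernel_size, self.rng), ReLU(), MaxPool1D()]
            ch = f
            length = -(-length // 2)
        self.dropout = Dropout(dropout_rate, self.rng)
        layers += [Flatten(), self.dropout]
        n_in = length * ch
        for u in dense_units:
            layers += [Dense(n_in, u, self.rng), ReLU()]
            n_in = u
        layers.append(Dense(n_in, 1, self.rng))
        self.layers = layers
        # target standardization (set during fit, inverted at predict time):
        # keeps the optimization well-scaled for targets of small variance
        self.y_loc = 0.0
        self.y_scale = 1.0

    # -- plumbing ---------------------------------------------------------
    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self.dropout.training = training
        h = x[:, :, None]
        for layer in self.layers:
            h = layer.forward(h)
        return h[:, 0]

    def _backward(self, dout: np.ndarray) -> None:
        d = dout[:, None]
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self) -> list:
        return [p for layer in self.layers for p in layer.params]

    def gradients(self) -> list:
        return [g for layer in self.layers for g in layer.grads]

    # -- training ---------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 10,
            batch_size: int = 16, lr: float = 1e-3,
            verbose: bool = False) -> list[float]:
        """Train on (X, y); returns the per-epoch mean training loss."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        if n < batch_size:
            raise ValueError(f"need at least batch_size={batch_size} samples, got {n}")
        self.y_loc = float(y.mean())
        self.y_scale = float(y.std()) or 1.0
        y = (y - self.y_loc) / self.y_scale
        opt = Adam(self.parameters(), lr=lr)
        history = []
        for epoch in range(epochs):
            order = self.rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb, yb = X[idx], y[idx]
                pred = self._forward(xb, training=True)
                resid = pred - yb
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}: {loss}")
                self._backward(2.0 * resid / resid.size)
                opt.step(self.gradients())
                losses.append(loss)
            history.append(float(np.mean(losses)))
            if verbose:
                print(f"epoch {epoch + 1}: mse={history[-1]:.6f}")
        return history

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._forward(X, training=False) * self.y_scale + self.y_loc

    # -- serialization ----------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"weight shape mismatch: {p.shape} vs {w.shape}")
            p[...] = w
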