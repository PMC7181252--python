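"""Minimal feed-forward / recurrent neural-network core.

Implements exactly the building blocks the FOG detectors need — dense,
1-D convolution (valid padding), max-pooling, dropout, a time-distributed
wrapper, and an LSTM — with manual backpropagation on NumPy arrays, plus
Adam and RMSprop optimizers with element-wise gradient clipping and an
early-stopping training loop.

Conventions
-----------
* Batch-major arrays: dense input (N, D); conv/LSTM input (N, L, C) /
  (N, T, D); time-distributed input (N, T, L, C).
* float32 by default (pass ``dtype=np.float64`` for gradient checking).
* All randomness (init, shuffling, dropout, denoising noise) flows from a
  single ``numpy.random.Generator``, so identical seeds give identical
  fits on a given platform.
* Binary cross-entropy is paired with a sigmoid output layer; the backward
  pass uses the fused, numerically stable gradient (p - y).
"""

from __future__ import annotations

import numpy as np

from ..errors import ContractError, StateError

DTYPE = np.float32


# ---------------------------------------------------------------------------
# activations


def _act_forward(name: str, z: np.ndarray) -> np.ndarray:
    if name == "linear":
        return z
    if name == "relu":
        return np.maximum(z, 0)
    if name == "tanh":
        return np.tanh(z)
    if name == "sigmoid":
        return _sigmoid(z)
    raise ContractError(f"unknown activation {name!r}")


def _act_backward(name: str, a: np.ndarray, grad: np.ndarray) -> np.ndarray:
    """d(loss)/dz given d(loss)/da and the activation output a."""
    if name == "linear":
        return grad
    if name == "relu":
        return grad * (a > 0)
    if name == "tanh":
        return grad * (1.0 - a * a)
    if name == "sigmoid":
        return grad * a * (1.0 - a)
    raise ContractError(f"unknown activation {name!r}")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape, dtype=DTYPE) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


# ---------------------------------------------------------------------------
# layers


class Layer:
    """Base class; stateless layers only override forward/backward."""

    def forward(self, x, train=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError

    def param_pairs(self):
        """[(weight array, gradient array), ...] — updated in place."""
        return []

    @property
    def n_params(self) -> int:
        return sum(int(w.size) for w, _ in self.param_pairs())


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, activation: str = "linear",
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng or np.random.default_rng()
        self.n_in, self.n_out, self.activation = n_in, n_out, activation
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out), dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        if x.shape[-1] != self.n_in:
            raise ContractError(f"Dense expects {self.n_in} inputs, got {x.shape}")
        self._x = x
        self._a = _act_forward(self.activation, x @ self.W + self.b)
        return self._a

    def backward(self, grad, from_z: bool = False):
        dz = grad if from_z else _act_backward(self.activation, self._a, grad)
        self.dW[...] = self._x.T @ dz
        self.db[...] = dz.sum(axis=0)
        return dz @ self.W.T

    def param_pairs(self):
        return [(self.W, self.dW), (self.b, self.db)]


class Conv1D(Layer):
    """Valid-padding 1-D convolution over (N, L, C) inputs, stride 1."""

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 activation: str = "relu",
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng or np.random.default_rng()
        self.in_channels, self.filters, self.kernel = in_channels, filters, kernel
        self.activation = activation
        fan_in, fan_out = kernel * in_channels, filters
        self.W = glorot_uniform(rng, fan_in, fan_out, (fan_in, fan_out), dtype)
        self.b = np.zeros(filters, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def _patches(self, x):
        # (N, L_out, C, kernel) -> (N, L_out, C * kernel)
        v = np.lib.stride_tricks.sliding_window_view(x, self.kernel, axis=1)
        n, l_out = v.shape[0], v.shape[1]
        return np.ascontiguousarray(v).reshape(n, l_out, -1)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        if x.ndim != 3 or x.shape[2] != self.in_channels:
            raise ContractError(
                f"Conv1D expects (N, L, {self.in_channels}), got {x.shape}"
            )
        if x.shape[1] < self.kernel:
            raise ContractError(
                f"input length {x.shape[1]} shorter than kernel {self.kernel}"
            )
        self._x_shape = x.shape
        self._p = self._patches(x)  # (N, L_out, C*k)
        z = self._p @ self.W + self.b
        self._a = _act_forward(self.activation, z)
        return self._a

    def backward(self, grad):
        dz = _act_backward(self.activation, self._a, grad)  # (N, L_out, F)
        n, l_out, _ = dz.shape
        dz2 = dz.reshape(-1, self.filters)
        self.dW[...] = self._p.reshape(-1, self.W.shape[0]).T @ dz2
        self.db[...] = dz2.sum(axis=0)
        dp = (dz2 @ self.W.T).reshape(n, l_out, self.in_channels, self.kernel)
        dx = np.zeros(self._x_shape, dtype=self.W.dtype)
        for j in range(self.kernel):
            dx[:, j : j + l_out, :] += dp[:, :, :, j]
        return dx

    def param_pairs(self):
        return [(self.W, self.dW), (self.b, self.db)]


class MaxPool1D(Layer):
    """Pool size 2 (default) over (N, L, C); odd trailing samples are dropped."""

    def __init__(self, pool: int = 2):
        self.pool = pool

    def forward(self, x, train=False, rng=None):
        n, l, c = x.shape
        l_out = l // self.pool
        self._in_shape = x.shape
        xr = x[:, : l_out * self.pool].reshape(n, l_out, self.pool, c)
        self._argmax = xr.argmax(axis=2)  # (N, L_out, C)
        return xr.max(axis=2)

    def backward(self, grad):
        n, l_out, c = grad.shape
        dxr = np.zeros((n, l_out, self.pool, c), dtype=grad.dtype)
        ni, li, ci = np.ogrid[:n, :l_out, :c]
        dxr[ni, li, self._argmax, ci] = grad
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        dx[:, : l_out * self.pool] = dxr.reshape(n, l_out * self.pool, c)
        return dx


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ContractError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0:
            self._mask = None
            return x
        if rng is None:
            raise StateError("training-mode dropout needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class TimeDistributed(Layer):
    """Apply a shared stack of layers independently to each time step.

    Input (N, T, ...) is folded to (N*T, ...), run through the wrapped
    layers once (hence identical weights at every step), and unfolded back
    to (N, T, D).
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train=False, rng=None):
        n, t = x.shape[0], x.shape[1]
        self._nt = (n, t)
        out = x.reshape((n * t,) + x.shape[2:])
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out.reshape((n, t) + out.shape[1:])

    def backward(self, grad):
        n, t = self._nt
        g = grad.reshape((n * t,) + grad.shape[2:])
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g.reshape((n, t) + g.shape[1:])

    def param_pairs(self):
        return [p for layer in self.layers for p in layer.param_pairs()]


class LSTM(Layer):
    """Single LSTM layer returning the last hidden state, (N, T, D) -> (N, U).

    Gate order [input, forget, cell, output]; forget-gate bias initialised
    to 1 (standard remedy for early vanishing of the cell state).
    """

    def __init__(self, n_in: int, units: int,
                 rng: np.random.Generator | None = None, dtype=DTYPE):
        rng = rng or np.random.default_rng()
        self.n_in, self.units = n_in, units
        self.W = glorot_uniform(rng, n_in, units, (n_in, 4 * units), dtype)
        self.U = glorot_uniform(rng, units, units, (units, 4 * units), dtype)
        self.b = np.zeros(4 * units, dtype=dtype)
        self.b[units : 2 * units] = 1.0
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False, rng=None):
        x = np.ascontiguousarray(x, dtype=self.W.dtype)
        if x.ndim != 3 or x.shape[2] != self.n_in:
            raise ContractError(f"LSTM expects (N, T, {self.n_in}), got {x.shape}")
        n, t, _ = x.shape
        u = self.units
        h = np.zeros((n, u), dtype=x.dtype)
        c = np.zeros((n, u), dtype=x.dtype)
        self._x = x
        self._cache = []
        for step in range(t):
            z = x[:, step] @ self.W + h @ self.U + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
        return h

    def backward(self, grad):
        n, t, _ = self._x.shape
        u = self.units
        dx = np.zeros_like(self._x)
        self.dW[...] = 0
        self.dU[...] = 0
        self.db[...] = 0
        dh = grad.astype(self._x.dtype)
        dc = np.zeros((n, u), dtype=self._x.dtype)
        for step in range(t - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[step]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di, df, dg = dc * g, dc * c_prev, dc * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1,
            )
            self.dW += self._x[:, step].T @ dz
            self.dU += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, step] = dz @ self.W.T
            dh = dz @ self.U.T
            dc = dc * f
        return dx

    def param_pairs(self):
        return [(self.W, self.dW), (self.U, self.dU), (self.b, self.db)]


# ---------------------------------------------------------------------------
# optimizers


class Optimizer:
    def __init__(self, lr: float, clipvalue: float | None = None):
        self.lr, self.clipvalue = lr, clipvalue
        self._slots: dict[int, dict] = {}

    def _clip(self, g):
        if self.clipvalue is None:
            return g
        return np.clip(g, -self.clipvalue, self.clipvalue)

    def step(self, pairs):
        raise NotImplementedError


class Adam(Optimizer):
    def __init__(self, lr=1e-4, clipvalue=1.0, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr, clipvalue)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, pairs):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for w, g in pairs:
            g = self._clip(g)
            slot = self._slots.setdefault(
                id(w), {"m": np.zeros_like(w), "v": np.zeros_like(w)}
            )
            slot["m"] = self.beta1 * slot["m"] + (1 - self.beta1) * g
            slot["v"] = self.beta2 * slot["v"] + (1 - self.beta2) * g * g
            w -= self.lr * (slot["m"] / b1t) / (np.sqrt(slot["v"] / b2t) + self.eps)


class RMSprop(Optimizer):
    def __init__(self, lr=1e-3, clipvalue=None, rho=0.9, eps=1e-7):
        super().__init__(lr, clipvalue)
        self.rho, self.eps = rho, eps

    def step(self, pairs):
        for w, g in pairs:
            g = self._clip(g)
            slot = self._slots.setdefault(id(w), {"v": np.zeros_like(w)})
            slot["v"] = self.rho * slot["v"] + (1 - self.rho) * g * g
            w -= self.lr * g / (np.sqrt(slot["v"]) + self.eps)


# ---------------------------------------------------------------------------
# model container


_LOSS_NAMES = ("bce", "mse")


class Sequential:
    """Ordered layer stack with a scalar loss and a mini-batch training loop."""

    def __init__(self, layers: list[Layer], loss: str = "bce"):
        if loss not in _LOSS_NAMES:
            raise ContractError(f"loss must be one of {_LOSS_NAMES}, got {loss!r}")
        self.layers = layers
        self.loss = loss

    # -- inference ---------------------------------------------------------

    def forward(self, x, train=False, rng=None):
        out = x
        for layer in self.layers:
            out = layer.forward(out, train=train, rng=rng)
        return out

    def predict(self, x, batch_size: int = 512) -> np.ndarray:
        """Deterministic inference (dropout off), batched to bound memory."""
        outs = [self.forward(x[i : i + batch_size])
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs) if outs else np.empty((0,))

    def param_pairs(self):
        return [p for layer in self.layers for p in layer.param_pairs()]

    @property
    def n_params(self) -> int:
        return sum(layer.n_params for layer in self.layers)

    # -- training ----------------------------------------------------------

    def _loss_and_delta(self, pred, y):
        """Scalar loss and d(loss)/d(pre-activation) of the output layer."""
        n = pred.size
        if self.loss == "bce":
            eps = 1e-7
            p = np.clip(pred, eps, 1 - eps)
            loss = float(-(y * np.log(p) + (1 - y) * np.log1p(-p)).mean())
            # fused with the sigmoid output layer: dL/dz = (p - y) / n
            delta_z = (pred - y) / n
            return loss, delta_z, True
        loss = float(((pred - y) ** 2).mean())
        return loss, 2.0 * (pred - y) / n, False

    def _backward(self, pred, y):
        loss, delta, fused = self._loss_and_delta(pred, y)
        last = self.layers[-1]
        if fused:
            if not (isinstance(last, Dense) and last.activation == "sigmoid"):
                raise ContractError("bce loss requires a sigmoid Dense output layer")
            grad = last.backward(delta.astype(pred.dtype), from_z=True)
        else:
            grad = last.backward(delta.astype(pred.dtype))
        for layer in reversed(self.layers[:-1]):
            grad = layer.backward(grad)
        return loss

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        optimizer: Optimizer,
        epochs: int,
        batch_size: int,
        rng: np.random.Generator,
        patience: int | None = 20,
        noise_sd: float = 0.0,
        verbose: bool = False,
    ) -> list[float]:
        """Mini-batch gradient training with early stopping on training loss.

        ``noise_sd`` > 0 turns the fit into a denoising objective: Gaussian
        noise is added to the inputs (clipped back to [0, 1]) while the
        clean values remain the target.
        """
        x = np.asarray(x)
        y = np.asarray(y)
        n = x.shape[0]
        if n == 0:
            raise ContractError("cannot fit on an empty dataset")
        history: list[float] = []
        best, stale = np.inf, 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                xb, yb = x[idx], y[idx]
                if noise_sd > 0:
                    noisy = xb + rng.normal(0.0, noise_sd, xb.shape)
                    xb = np.clip(noisy, 0.0, 1.0).astype(x.dtype)
                pred = self.forward(xb, train=True, rng=rng)
                losses.append(self._backward(pred, yb))
                optimizer.step(self.param_pairs())
            epoch_loss = float(np.mean(losses))
            history.append(epoch_loss)
            if verbose:
                print(f"epoch {epoch + 1}/{epochs} loss={epoch_loss:.6f}")
            if patience is not None:
                if epoch_loss < best - 1e-9:
                    best, stale = epoch_loss, 0
                else:
                    stale += 1
                    if stale >= patience:
                        break
        return history
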