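"""Compact feed-forward/convolutional network engine for spectral regression.

Implements exactly the layer types the ensemble needs -- valid (unpadded,
stride-1) 1-D convolution, dense layers, ReLU/sigmoid activations, inverted
dropout -- together with Glorot-uniform initialization, the Adam optimizer,
mean-squared-error loss, early stopping on validation RMSE with best-epoch
weight restoration, and learning-rate reduction on plateau.

Convolutions are evaluated in the frequency domain (real FFT, pointwise
batched matrix products over frequency bins, inverse FFT, valid-region
slice), which is algebraically identical to direct valid cross-correlation
but far cheaper for the wide second convolution (kernel 64 over 64
channels).  Arithmetic is float32 by default; everything is seeded and
single-threaded-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .core import NirscartError


class DivergenceError(NirscartError, RuntimeError):
    pass


def _fft_length(length: int) -> int:
    # N >= L suffices for valid correlation, input gradients and weight
    # gradients alike: the circular wrap-around only touches lags that the
    # valid-region slices discard.
    return sfft.next_fast_len(length)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int,
                   dtype=np.float32) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: holds parameter/gradient dicts for the optimizer."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, *, training=False, rng=None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class Conv1D(Layer):
    """Valid stride-1 cross-correlation: (B, L, Cin) -> (B, L-K+1, Cout)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32,
                 needs_input_grad: bool = True) -> None:
        super().__init__()
        self.kernel = kernel
        self.needs_input_grad = needs_input_grad
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.dtype = dtype
        self.params["W"] = glorot_uniform(
            rng, (kernel, in_channels, out_channels),
            kernel * in_channels, kernel * out_channels, dtype,
        )
        self.params["b"] = np.zeros(out_channels, dtype=dtype)
        self._cache = None

    def forward(self, x, *, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=self.dtype)
        B, L, Cin = x.shape
        K = self.kernel
        if L < K:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        nfft = _fft_length(L)
        X = sfft.rfft(x, n=nfft, axis=1)                       # (B, F, Cin)
        Wf = sfft.rfft(self.params["W"][::-1], n=nfft, axis=0)  # (F, Cin, Cout)
        Y = np.matmul(X.transpose(1, 0, 2), Wf)                # (F, B, Cout)
        y_full = sfft.irfft(Y.transpose(1, 0, 2), n=nfft, axis=1)
        y = y_full[:, K - 1 : L, :].astype(self.dtype) + self.params["b"]
        self._cache = (X, L, nfft)
        return y

    def backward(self, grad):
        X, L, nfft = self._cache
        K = self.kernel
        dy = np.ascontiguousarray(grad, dtype=self.dtype)
        DY = sfft.rfft(dy, n=nfft, axis=1)                     # (B, F, Cout)
        dx = None
        if self.needs_input_grad:
            # gradient w.r.t. input: full convolution of dy with W
            Wf = sfft.rfft(self.params["W"], n=nfft, axis=0)   # (F, Cin, Cout)
            DX = np.matmul(DY.transpose(1, 0, 2), Wf.transpose(0, 2, 1))
            dx_full = sfft.irfft(DX.transpose(1, 0, 2), n=nfft, axis=1)
            dx = dx_full[:, :L, :].astype(self.dtype)
        # gradient w.r.t. weights: cross-correlation of input with dy
        prod = np.matmul(X.transpose(1, 2, 0), DY.conj().transpose(1, 0, 2))
        dW_full = sfft.irfft(prod, n=nfft, axis=0)             # (nfft, Cin, Cout)
        self.grads["W"] = dW_full[:K].astype(self.dtype)
        self.grads["b"] = dy.sum(axis=(0, 1))
        return dx


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.params["W"] = glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)
        self._x = None

    def forward(self, x, *, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad):
        return grad * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x, *, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout: active only while training."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, *, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Reshape3D(Layer):
    """(B, L) -> (B, L, 1) so convolutions see a single input channel."""

    def forward(self, x, *, training=False, rng=None):
        return x[:, :, None]

    def backward(self, grad):
        return None if grad is None else grad[:, :, 0]


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x, *, training=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, training=training, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def predict(self, x, batch_size: int = 256) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        outs = [
            self.forward(x[i : i + batch_size], training=False)
            for i in range(0, x.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)[:, 0].astype(float)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_parameters(self) -> int:
        return sum(layer.params[name].size for layer, name in self.parameters())

    def get_weights(self) -> list[np.ndarray]:
        return [layer.params[name].copy() for layer, name in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (layer, name), w in zip(self.parameters(), weights):
            layer.params[name] = w.copy()


class Adam:
    def __init__(self, model: Sequential, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[n]) for layer, n in model.parameters()]
        self.v = [np.zeros_like(layer.params[n]) for layer, n in model.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.model.parameters()):
            g = layer.grads[name]
            m, v = self.m[i], self.v[i]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * np.square(g)
            upd = np.sqrt(v / b2t)
            upd += self.eps
            np.divide(m, upd, out=upd)
            upd *= self.lr / b1t
            layer.params[name] -= upd.astype(layer.params[name].dtype, copy=False)


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train(
    model: Sequential,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray,
    y_val: np.ndarray,
    *,
    max_epochs: int = 500,
    batch_size: int = 32,
    learning_rate: float = 1e-3,
    early_stop_patience: int = 25,
    lr_patience: int = 20,
    lr_factor: float = 0.5,
    min_lr: float = 1e-5,
    seed: int = 0,
    member_name: str = "",
) -> TrainingHistory:
    """Minimize MSE with Adam; monitor validation RMSE.

    Training halts once validation RMSE has not improved for
    ``early_stop_patience`` epochs, restoring the best-epoch weights; the
    learning rate is multiplied by ``lr_factor`` whenever it has not improved
    for ``lr_patience`` epochs since the last improvement or reduction.
    """
    rng = np.random.default_rng(seed)
    x_train = np.asarray(x_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float32).reshape(-1, 1)
    x_val = np.asarray(x_val, dtype=np.float32)
    y_val = np.asarray(y_val, dtype=np.float32).reshape(-1)
    opt = Adam(model, lr=learning_rate)
    hist = TrainingHistory()
    best_rmse = np.inf
    best_weights = model.get_weights()
    stagnant_for_lr = 0
    n = x_train.shape[0]
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            pred = model.forward(x_train[idx], training=True, rng=rng)
            resid = pred - y_train[idx]
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss in member {member_name or '<unnamed>'}"
                )
            losses.append(loss)
            model.backward((2.0 / resid.size) * resid.astype(np.float32))
            opt.step()
        val_pred = model.predict(x_val)
        val_rmse = float(np.sqrt(np.mean((val_pred - y_val) ** 2)))
        if not np.isfinite(val_rmse):
            raise DivergenceError(
                f"non-finite validation RMSE in member {member_name or '<unnamed>'}"
            )
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_rmse.append(val_rmse)
        hist.lr.append(opt.lr)
        if val_rmse < best_rmse:
            best_rmse = val_rmse
            hist.best_epoch = epoch
            best_weights = model.get_weights()
            stagnant_for_lr = 0
        else:
            stagnant_for_lr += 1
            if stagnant_for_lr >= lr_patience and opt.lr > min_lr:
                opt.lr = max(opt.lr * lr_factor, min_lr)
                stagnant_for_lr = 0
        if epoch - hist.best_epoch >= early_stop_patience:
            break
    hist.stopped_epoch = len(hist.val_rmse) - 1
    model.set_weights(best_weights)
    return hist
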