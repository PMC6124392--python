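"""A small, deterministic CNN engine in numpy for the verifier networks.

Architecture family: ``conv_depth`` blocks of [3x3 same-padding conv,
ReLU, 2x2 max-pool], followed by fully-connected ReLU layers and a 2-way
softmax head trained with cross-entropy (binary cross-entropy over the
two verdict classes).  Convolutions run as im2col matrix products; the
backward pass for a same-padded 3x3 convolution is itself a 3x3
convolution with the spatially flipped, channel-transposed kernel, so
training is all matmuls and stays fast on a single CPU.

Everything is float32 and driven by one seeded generator: identical seeds
give identical parameters, batch orders and final weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ConvNet", "TrainHistory"]


def _sliding_patches(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, 9*C) patches of the 3x3 neighbourhood."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    view = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # view: (N, H, W, C, 3, 3) -> (N, H, W, 3, 3, C) so weights index as
    # (ky, kx, c_in)
    view = view.transpose(0, 1, 2, 4, 5, 3)
    return np.ascontiguousarray(view).reshape(n, h, w, 9 * c)


class _Conv3x3:
    """Same-padding 3x3 convolution, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / (9 * c_in))
        self.w = rng.normal(0.0, scale, size=(9 * c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._cols = _sliding_patches(x)
        return self._cols @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        cols = self._cols.reshape(-1, 9 * self.c_in)
        dyf = dy.reshape(-1, self.c_out)
        self.dw = (cols.T @ dyf) / n
        self.db = dyf.sum(axis=0) / n
        # grad wrt input: correlate dy with the flipped kernel
        wk = self.w.reshape(3, 3, self.c_in, self.c_out)
        wk_flip = wk[::-1, ::-1].transpose(0, 1, 3, 2)  # (3,3,c_out,c_in)
        dcols = _sliding_patches(dy)
        return dcols @ wk_flip.reshape(9 * self.c_out, self.c_in)

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        xr = xr.reshape(n, h // 2, w // 2, c, 4)
        self._arg = xr.argmax(axis=4)
        self._in_shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=4)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._in_shape
        grad = np.zeros((n, h // 2, w // 2, c, 4), dtype=np.float32)
        np.put_along_axis(grad, self._arg[..., None], dy[..., None], axis=4)
        grad = grad.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(grad).reshape(n, h, w, c)


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0.0, scale, size=(n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n = dy.shape[0]
        self.dw = self._x.T @ dy / n
        self.db = dy.sum(axis=0) / n
        return dy @ self.w.T

    @property
    def params(self):
        return [("w", self.w, "dw"), ("b", self.b, "db")]


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


class ConvNet:
    """Configurable-depth binary patch classifier.

    ``input_size`` must be divisible by ``2**conv_depth``.  Channel widths
    default to 16*2^(layer-1) capped at ``max_width``; the head is
    FC(fc_widths) -> 2 logits.
    """

    def __init__(
        self,
        input_size: int,
        conv_depth: int = 5,
        in_channels: int = 3,
        base_width: int = 16,
        max_width: int = 128,
        fc_widths: Sequence[int] = (256, 64),
        seed: int = 0,
    ) -> None:
        if not 1 <= conv_depth <= 8:
            raise ValueError("conv_depth out of range")
        if input_size % (2**conv_depth) != 0:
            raise ValueError(
                f"input_size {input_size} not divisible by 2^{conv_depth}"
            )
        self.input_size = input_size
        self.conv_depth = conv_depth
        rng = np.random.default_rng(seed)
        self.layers: list = []
        c = in_channels
        size = input_size
        self.widths: list[int] = []
        for d in range(conv_depth):
            c_out = min(base_width * (2**d), max_width)
            self.layers += [_Conv3x3(c, c_out, rng), _ReLU(), _MaxPool2()]
            c = c_out
            size //= 2
            self.widths.append(c_out)
        self._flat_dim = size * size * c
        self._fc_start = len(self.layers)
        n_in = self._flat_dim
        for width in fc_widths:
            self.layers += [_Dense(n_in, width, rng), _ReLU()]
            n_in = width
        self.layers.append(_Dense(n_in, 2, rng))
        self._adam_state: dict[int, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = x
        for i, layer in enumerate(self.layers):
            if i == self._fc_start:
                h = h.reshape(h.shape[0], -1)
            h = layer.forward(h)
        return h

    def _backward(self, dlogits: np.ndarray) -> None:
        g = dlogits
        for i in reversed(range(len(self.layers))):
            g = self.layers[i].backward(g)
            if i == self._fc_start:
                # reshape gradient back to the conv feature map
                n = g.shape[0]
                size = self.input_size // (2**self.conv_depth)
                g = g.reshape(n, size, size, self.widths[-1])

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Mean cross-entropy of labels y in {0,1} (no parameter update)."""
        p = self._softmax(self._forward(self._as_input(x)))
        eps = 1e-12
        return float(-np.mean(np.log(p[np.arange(len(y)), y] + eps)))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """P(positive) per sample; inference is deterministic."""
        x = self._as_input(x)
        out = np.empty(len(x), dtype=np.float32)
        for i in range(0, len(x), batch_size):
            p = self._softmax(self._forward(x[i : i + batch_size]))
            out[i : i + batch_size] = p[:, 1]
        return out

    def _as_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.input_size or x.shape[2] != self.input_size:
            raise ValueError(
                f"expected {self.input_size}x{self.input_size} inputs, got {x.shape}"
            )
        return x

    # -- training -----------------------------------------------------------

    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 10,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        x_val: np.ndarray | None = None,
        y_val: np.ndarray | None = None,
        lr_decay: str = "cosine",
    ) -> TrainHistory:
        """Adam + cross-entropy training; returns per-epoch loss history.

        ``lr_decay='cosine'`` anneals the step size to ~0 over the epochs so
        the final weights are a settled state rather than a mid-oscillation
        snapshot; pass ``'none'`` for a constant rate.
        """
        x = self._as_input(x)
        y = np.asarray(y, dtype=np.int64)
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("labels must be 0/1")
        rng = np.random.default_rng(seed)
        history = TrainHistory()
        n = len(x)
        for _epoch in range(epochs):
            if lr_decay == "cosine":
                epoch_lr = lr * 0.5 * (1.0 + np.cos(np.pi * _epoch / epochs))
            elif lr_decay == "none":
                epoch_lr = lr
            else:
                raise ValueError(f"unknown lr_decay {lr_decay!r}")
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb, yb = x[idx], y[idx]
                logits = self._forward(xb)
                p = self._softmax(logits)
                eps = 1e-12
                loss = -np.mean(np.log(p[np.arange(len(yb)), yb] + eps))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {_epoch}"
                    )
                losses.append(float(loss))
                dlogits = p.copy()
                dlogits[np.arange(len(yb)), yb] -= 1.0
                self._backward(dlogits.astype(np.float32))
                self._adam_step(epoch_lr)
            history.train_loss.append(float(np.mean(losses)))
            if x_val is not None and y_val is not None:
                history.val_loss.append(self.loss(x_val, y_val))
                pred = self.predict_proba(x_val) >= 0.5
                history.val_accuracy.append(float(np.mean(pred == (np.asarray(y_val) == 1))))
        return history

    def _adam_step(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                   eps: float = 1e-8) -> None:
        self._adam_t += 1
        t = self._adam_t
        for i, layer in enumerate(self.layers):
            if not hasattr(layer, "params"):
                continue
            state = self._adam_state.setdefault(i, {})
            for name, param, grad_name in layer.params:
                g = getattr(layer, grad_name)
                if name not in state:
                    state[name] = (np.zeros_like(param), np.zeros_like(param))
                m, v = state[name]
                m[:] = beta1 * m + (1 - beta1) * g
                v[:] = beta2 * v + (1 - beta2) * g * g
                m_hat = m / (1 - beta1**t)
                v_hat = v / (1 - beta2**t)
                param -= lr * m_hat / (np.sqrt(v_hat) + eps)

    # -- persistence ----------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "params"):
                for name, param, _ in layer.params:
                    out[f"layer{i}_{name}"] = param
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "params"):
                for name, param, _ in layer.params:
                    key = f"layer{i}_{name}"
                    if key not in state:
                        raise KeyError(f"missing weight {key}")
                    if state[key].shape != param.shape:
                        raise ValueError(f"shape mismatch for {key}")
                    param[:] = state[key]
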