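"""Minimal neural-network primitives with explicit forward/backward passes.

Internal engine used by the backbone, GCN and head modules.  Arrays are
float64 NumPy throughout; each ``*_forward`` returns ``(out, cache)`` and
the matching ``*_backward`` consumes ``(dout, cache)``.  Convolutions use
an im2col formulation; the backward input pass scatters over the nine
kernel offsets, which is exact and fast at the small spatial sizes this
package targets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "he_init",
    "relu_forward",
    "relu_backward",
    "dropout_forward",
    "dropout_backward",
    "linear_forward",
    "linear_backward",
    "conv3x3_forward",
    "conv3x3_backward",
    "global_avg_pool_forward",
    "global_avg_pool_backward",
    "softmax",
    "softmax_cross_entropy",
    "sigmoid",
    "AdamW",
]


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """Fan-in-scaled Gaussian initialization (He et al. convention)."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# Elementwise / regularization layers
# ---------------------------------------------------------------------------

def relu_forward(x: np.ndarray):
    out = np.maximum(x, 0.0)
    return out, (x > 0.0)


def relu_backward(dout: np.ndarray, cache) -> np.ndarray:
    return dout * cache


def dropout_forward(x: np.ndarray, p: float, rng: np.random.Generator | None):
    """Inverted dropout.  ``rng=None`` or ``p=0`` means evaluation mode."""
    if rng is None or p <= 0.0:
        return x, None
    if not 0.0 <= p < 1.0:
        raise ValueError(f"dropout rate must be in [0, 1), got {p}")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask, mask


def dropout_backward(dout: np.ndarray, mask) -> np.ndarray:
    return dout if mask is None else dout * mask


# ---------------------------------------------------------------------------
# Dense layers
# ---------------------------------------------------------------------------

def linear_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """y = x @ w.T + b with x (n, d_in), w (d_out, d_in)."""
    return x @ w.T + b, (x, w)


def linear_backward(dout: np.ndarray, cache):
    x, w = cache
    dx = dout @ w
    dw = dout.T @ x
    db = dout.sum(axis=0)
    return dx, dw, db


# ---------------------------------------------------------------------------
# 3x3 stride-s convolution (pad 1), NCHW layout
# ---------------------------------------------------------------------------

def conv3x3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: int = 2):
    """x (n, c_in, h, w) -> (n, c_out, h', w') with 'same' padding then stride."""
    n, c_in, h, wd = x.shape
    c_out = w.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # n, c_in, h, w, 3, 3
    win = win[:, :, ::stride, ::stride, :, :]
    ho, wo = win.shape[2], win.shape[3]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c_in * 9)
    out = cols @ w.reshape(c_out, -1).T + b
    out = out.reshape(n, ho, wo, c_out).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, w, stride, ho, wo)


def conv3x3_backward(dout: np.ndarray, cache):
    cols, x_shape, w, stride, ho, wo = cache
    n, c_in, h, wd = x_shape
    c_out = w.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
    dw = (dflat.T @ cols).reshape(w.shape)
    db = dflat.sum(axis=0)
    dcols = (dflat @ w.reshape(c_out, -1)).reshape(n, ho, wo, c_in, 3, 3)
    dxp = np.zeros((n, c_in, h + 2, wd + 2))
    for ki in range(3):
        for kj in range(3):
            dxp[:, :, ki : ki + stride * ho : stride, kj : kj + stride * wo : stride] += (
                dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2)
            )
    return dxp[:, :, 1:-1, 1:-1], dw, db


def global_avg_pool_forward(x: np.ndarray):
    """(n, c, h, w) -> (n, c): spatial mean over the activation map."""
    return x.mean(axis=(2, 3)), x.shape


def global_avg_pool_backward(dout: np.ndarray, x_shape) -> np.ndarray:
    n, c, h, w = x_shape
    return np.broadcast_to(dout[:, :, None, None], x_shape) / (h * w)


# ---------------------------------------------------------------------------
# Output nonlinearities and losses
# ---------------------------------------------------------------------------

def batchnorm_forward(
    x: np.ndarray,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
):
    """Non-affine feature standardisation (BatchNorm without scale/shift).

    Training mode normalises by batch statistics and updates the running
    buffers in place; evaluation mode uses the running statistics, which
    keeps single-sample inference well defined.
    """
    if training:
        mu = x.mean(axis=0)
        var = x.var(axis=0)
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    y = (x - mu) * inv_std
    return y, (y, inv_std, training)


def batchnorm_backward(dout: np.ndarray, cache) -> np.ndarray:
    y, inv_std, training = cache
    if not training:
        return dout * inv_std
    n = dout.shape[0]
    return (
        inv_std
        / n
        * (n * dout - dout.sum(axis=0) - y * (dout * y).sum(axis=0))
    )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy; returns (loss, probs, dlogits)."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.log(probs[np.arange(n), labels] + eps).mean()
    dlogits = probs.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, probs, dlogits / n


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class AdamW:
    """Adam with decoupled weight decay.

    Weight decay is applied multiplicatively to the parameters before the
    adaptive gradient step, scaled by the current learning rate; bias
    vectors (1-D parameters) are not decayed, following common practice.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 5e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            if p.ndim > 1 and self.weight_decay > 0:
                p *= 1.0 - self.lr * self.weight_decay
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
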