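"""Minimal NumPy neural-network primitives used by the model core.

Forward functions return the caches their matching backward functions
need. Everything is float64 and fully deterministic given a seed.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

__all__ = [
    "uniform_fan_in",
    "softmax_rows",
    "softmax_rows_backward",
    "layernorm",
    "layernorm_backward",
    "relu",
    "leaky_relu",
    "leaky_relu_backward",
    "AdamOptimizer",
]


def uniform_fan_in(rng: np.random.Generator, shape: Tuple[int, ...]) -> np.ndarray:
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) initialization.

    fan_in is the first dimension (inputs are row vectors multiplied on
    the right by the weight matrix).
    """
    bound = 1.0 / np.sqrt(shape[0])
    return rng.uniform(-bound, bound, size=shape)


def softmax_rows(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for numerical stability."""
    shifted = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def softmax_rows_backward(a: np.ndarray, da: np.ndarray) -> np.ndarray:
    """Gradient through a row-wise softmax.

    ``a`` is the softmax output, ``da`` the gradient w.r.t. it; returns
    the gradient w.r.t. the logits.
    """
    inner = (da * a).sum(axis=1, keepdims=True)
    return a * (da - inner)


def layernorm(
    x: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float
) -> Tuple[np.ndarray, dict]:
    mu = x.mean(axis=1, keepdims=True)
    var = x.var(axis=1, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv_std
    out = gamma * xhat + beta
    return out, {"xhat": xhat, "inv_std": inv_std, "gamma": gamma}


def layernorm_backward(
    dout: np.ndarray, cache: dict
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (dx, dgamma, dbeta) for a row-wise LayerNorm."""
    xhat, inv_std, gamma = cache["xhat"], cache["inv_std"], cache["gamma"]
    n = xhat.shape[1]
    dgamma = (dout * xhat).sum(axis=0)
    dbeta = dout.sum(axis=0)
    dxhat = dout * gamma
    dx = (
        inv_std
        / n
        * (
            n * dxhat
            - dxhat.sum(axis=1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=1, keepdims=True)
        )
    )
    return dx, dgamma, dbeta


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def leaky_relu(x: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, x, slope * x)


def leaky_relu_backward(x: np.ndarray, dout: np.ndarray, slope: float) -> np.ndarray:
    return np.where(x > 0, dout, slope * dout)


class AdamOptimizer:
    """Plain Adam (Kingma & Ba) over a dict of named parameter arrays.

    Only parameters whose names appear in ``trainable`` are updated;
    everything else is left bitwise untouched, which is what the
    freeze-and-finetune transfer protocol relies on.
    """

    def __init__(
        self,
        params: Dict[str, np.ndarray],
        trainable: set,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.trainable = set(trainable)
        self.m = {k: np.zeros_like(v) for k, v in params.items() if k in self.trainable}
        self.v = {k: np.zeros_like(v) for k, v in params.items() if k in self.trainable}
        self.t = 0

    def step(
        self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray], lr: float
    ) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k in self.trainable:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + self.eps)
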