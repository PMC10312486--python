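"""The three-module attention network.

The core maps a raw count matrix ``X`` (cells x genes) to class logits
through three serial modules:

1. **Additive attention** — a learned affine map ``L: R^N -> R^N`` of
   each cell's expression row, softmax-normalized per cell into
   attention weights ``A`` (rows sum to 1). Gene scores are the
   elementwise product ``G = A * X``; they have the same shape as ``X``
   and are the model's interpretable representation.
2. **Branching projection blocks** — ``k`` serial blocks. Each block
   applies ``h`` parallel linear branches to its input, concatenates the
   branch outputs back to width ``N``, passes them through a narrow
   two-layer subnetwork (``N -> bottleneck -> N`` with a ReLU in
   between), adds a residual connection from the gene scores ``G``, and
   applies a row-wise LayerNorm.
3. **Configuration head** — a single linear map from gene-space width
   ``N`` to the number of classes ``T``, followed by a Leaky ReLU. This
   is the only module retrained during transfer learning.

Everything is plain NumPy; forward passes are deterministic functions of
the parameter state, and the backward pass is written out explicitly so
the whole network trains with Adam without an autograd framework.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import _nn
from .containers import CountMatrix

__all__ = [
    "ArchitectureConfig",
    "ModelState",
    "init_state",
    "attention_forward",
    "projection_forward",
    "configuration_forward",
    "model_forward",
    "cross_entropy",
    "MODULES",
]

MODULES = ("attention", "projection", "head")


@dataclass(frozen=True)
class ArchitectureConfig:
    """Hyperparameters fixing all parameter shapes.

    ``n_branches`` linear branches per block each map ``N`` to roughly
    ``N / h`` outputs (the last branch absorbs the remainder) so the
    concatenation has width exactly ``N`` before the
    ``N -> bottleneck -> N`` subnetwork.
    """

    n_genes: int
    n_classes: int
    n_blocks: int = 2
    n_branches: int = 4
    bottleneck: int = 128
    leaky_slope: float = 0.01
    layernorm_eps: float = 1e-5
    seed: int = 0
    attention_rank: Optional[int] = None  # None = full-rank N x N map
    log1p_input: bool = False
    attention_init_scale: float = 0.01

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_classes < 1:
            raise ValueError("n_genes and n_classes must be >= 1")
        if self.n_blocks < 1 or self.n_branches < 1 or self.bottleneck < 1:
            raise ValueError("n_blocks, n_branches and bottleneck must be >= 1")
        if self.n_branches > self.n_genes:
            raise ValueError(
                f"n_branches={self.n_branches} exceeds n_genes={self.n_genes}"
            )
        if self.attention_rank is not None and self.attention_rank < 1:
            raise ValueError("attention_rank must be >= 1 when set")

    def branch_widths(self) -> List[int]:
        base = self.n_genes // self.n_branches
        widths = [base] * (self.n_branches - 1)
        widths.append(self.n_genes - base * (self.n_branches - 1))
        return widths

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(**d)


@dataclass
class ModelState:
    """Parameters of the three modules plus per-module trainable flags.

    ``gene_names`` records the gene order the model was trained on, so
    a query dataset can be aligned to it during transfer.
    """

    arch: ArchitectureConfig
    params: Dict[str, np.ndarray]
    trainable: Dict[str, bool] = field(
        default_factory=lambda: {m: True for m in MODULES}
    )
    gene_names: Optional[np.ndarray] = None

    def copy(self) -> "ModelState":
        return ModelState(
            arch=self.arch,
            params={k: v.copy() for k, v in self.params.items()},
            trainable=dict(self.trainable),
            gene_names=None if self.gene_names is None else self.gene_names.copy(),
        )

    def module_of(self, param_name: str) -> str:
        head = param_name.split(".", 1)[0]
        if head == "attention":
            return "attention"
        if head == "head":
            return "head"
        if head.startswith("block"):
            return "projection"
        raise KeyError(f"unknown parameter {param_name!r}")

    def trainable_param_names(self) -> List[str]:
        return [k for k in self.params if self.trainable[self.module_of(k)]]

    def module_params(self, module: str) -> Dict[str, np.ndarray]:
        return {k: v for k, v in self.params.items() if self.module_of(k) == module}


def expected_shapes(arch: ArchitectureConfig) -> Dict[str, Tuple[int, ...]]:
    """Parameter name -> shape table implied by the architecture."""
    n, t = arch.n_genes, arch.n_classes
    shapes: Dict[str, Tuple[int, ...]] = {}
    if arch.attention_rank is None:
        shapes["attention.W"] = (n, n)
    else:
        r = arch.attention_rank
        shapes["attention.W1"] = (n, r)
        shapes["attention.W2"] = (r, n)
    shapes["attention.b"] = (n,)
    widths = arch.branch_widths()
    for b in range(arch.n_blocks):
        for j, w in enumerate(widths):
            shapes[f"block{b}.branch{j}.W"] = (n, w)
            shapes[f"block{b}.branch{j}.b"] = (w,)
        shapes[f"block{b}.sub.W1"] = (n, arch.bottleneck)
        shapes[f"block{b}.sub.b1"] = (arch.bottleneck,)
        shapes[f"block{b}.sub.W2"] = (arch.bottleneck, n)
        shapes[f"block{b}.sub.b2"] = (n,)
        shapes[f"block{b}.ln.gamma"] = (n,)
        shapes[f"block{b}.ln.beta"] = (n,)
    shapes["head.W"] = (n, t)
    shapes["head.b"] = (t,)
    return shapes


def init_state(arch: ArchitectureConfig, seed: Optional[int] = None) -> ModelState:
    """Seeded initialization: uniform fan-in weights, zero biases,
    LayerNorm gain 1 / shift 0.

    Attention weights are additionally shrunk by
    ``attention_init_scale`` so the softmax starts near-uniform: any
    departure of the attention tensor from uniformity is then learned
    salience rather than initialization noise, which is what the
    post-hoc marker rankings interpret.
    """
    rng = np.random.default_rng(arch.seed if seed is None else seed)
    params: Dict[str, np.ndarray] = {}
    for name, shape in expected_shapes(arch).items():
        leaf = name.rsplit(".", 1)[1]
        if leaf in ("b", "b1", "b2", "beta"):
            params[name] = np.zeros(shape)
        elif leaf == "gamma":
            params[name] = np.ones(shape)
        else:
            params[name] = _nn.uniform_fan_in(rng, shape)
            if name.startswith("attention."):
                params[name] = params[name] * arch.attention_init_scale
    return ModelState(arch=arch, params=params)


def _as_counts(x) -> np.ndarray:
    if isinstance(x, CountMatrix):
        return x.counts
    return np.asarray(x, dtype=np.float64)


def _check_width(x: np.ndarray, state: ModelState) -> None:
    if x.shape[1] != state.arch.n_genes:
        raise ValueError(
            f"input has {x.shape[1]} genes but the model was built for "
            f"{state.arch.n_genes} genes"
        )


# ---------------------------------------------------------------------------
# Attention module
# ---------------------------------------------------------------------------


def _attention_with_cache(x: np.ndarray, state: ModelState) -> Tuple[np.ndarray, np.ndarray, dict]:
    p = state.params
    if state.arch.log1p_input:
        x = np.log1p(x)
    if state.arch.attention_rank is None:
        logits = x @ p["attention.W"] + p["attention.b"]
        cache = {"x": x, "low_rank": False}
    else:
        hidden = x @ p["attention.W1"]
        logits = hidden @ p["attention.W2"] + p["attention.b"]
        cache = {"x": x, "hidden": hidden, "low_rank": True}
    a = _nn.softmax_rows(logits)
    gene_scores = a * x
    cache["a"] = a
    return a, gene_scores, cache


def attention_forward(x, state: ModelState) -> Tuple[np.ndarray, np.ndarray]:
    """Attention weights ``A`` (rows softmax-normalized) and gene scores
    ``G = A * X`` for input counts ``x`` (cells x genes)."""
    x = _as_counts(x)
    _check_width(x, state)
    a, g, _ = _attention_with_cache(x, state)
    return a, g


def _attention_backward(
    dgene_scores: np.ndarray, cache: dict, state: ModelState, grads: Dict[str, np.ndarray]
) -> None:
    x, a = cache["x"], cache["a"]
    da = dgene_scores * x
    dlogits = _nn.softmax_rows_backward(a, da)
    grads["attention.b"] = dlogits.sum(axis=0)
    if cache["low_rank"]:
        p = state.params
        grads["attention.W2"] = cache["hidden"].T @ dlogits
        grads["attention.W1"] = x.T @ (dlogits @ p["attention.W2"].T)
    else:
        grads["attention.W"] = x.T @ dlogits


# ---------------------------------------------------------------------------
# Projection blocks
# ---------------------------------------------------------------------------


def _block_forward(
    z: np.ndarray, gene_scores: np.ndarray, state: ModelState, b: int
) -> Tuple[np.ndarray, dict]:
    p = state.params
    arch = state.arch
    branch_outs = []
    for j in range(arch.n_branches):
        branch_outs.append(z @ p[f"block{b}.branch{j}.W"] + p[f"block{b}.branch{j}.b"])
    u = np.concatenate(branch_outs, axis=1)
    h_pre = u @ p[f"block{b}.sub.W1"] + p[f"block{b}.sub.b1"]
    h = _nn.relu(h_pre)
    v = h @ p[f"block{b}.sub.W2"] + p[f"block{b}.sub.b2"]
    r = v + gene_scores
    out, ln_cache = _nn.layernorm(
        r, p[f"block{b}.ln.gamma"], p[f"block{b}.ln.beta"], arch.layernorm_eps
    )
    cache = {"z": z, "u": u, "h_pre": h_pre, "h": h, "ln": ln_cache}
    return out, cache


def _block_backward(
    dout: np.ndarray, cache: dict, state: ModelState, b: int, grads: Dict[str, np.ndarray]
) -> Tuple[np.ndarray, np.ndarray]:
    """Returns (dz, dgene_scores_residual) for block ``b``."""
    p = state.params
    arch = state.arch
    dr, dgamma, dbeta = _nn.layernorm_backward(dout, cache["ln"])
    grads[f"block{b}.ln.gamma"] = dgamma
    grads[f"block{b}.ln.beta"] = dbeta
    dgs = dr  # residual branch
    dv = dr
    grads[f"block{b}.sub.W2"] = cache["h"].T @ dv
    grads[f"block{b}.sub.b2"] = dv.sum(axis=0)
    dh = dv @ p[f"block{b}.sub.W2"].T
    dh_pre = dh * (cache["h_pre"] > 0)
    grads[f"block{b}.sub.W1"] = cache["u"].T @ dh_pre
    grads[f"block{b}.sub.b1"] = dh_pre.sum(axis=0)
    du = dh_pre @ p[f"block{b}.sub.W1"].T
    widths = arch.branch_widths()
    dz = np.zeros_like(cache["z"])
    start = 0
    for j, w in enumerate(widths):
        duj = du[:, start : start + w]
        grads[f"block{b}.branch{j}.W"] = cache["z"].T @ duj
        grads[f"block{b}.branch{j}.b"] = duj.sum(axis=0)
        dz += duj @ p[f"block{b}.branch{j}.W"].T
        start += w
    return dz, dgs


def projection_forward(gene_scores: np.ndarray, state: ModelState) -> np.ndarray:
    """Run the ``k`` projection blocks serially on the gene scores.

    The output keeps the input shape (cells x genes): each block's
    residual connection from the gene scores pins the width at ``N``.
    """
    gene_scores = np.asarray(gene_scores, dtype=np.float64)
    _check_width(gene_scores, state)
    z = gene_scores
    for b in range(state.arch.n_blocks):
        z, _ = _block_forward(z, gene_scores, state, b)
    return z


# ---------------------------------------------------------------------------
# Configuration head
# ---------------------------------------------------------------------------


def configuration_forward(rep: np.ndarray, state: ModelState) -> np.ndarray:
    """Class logits: LeakyReLU(rep @ W + b), shape (cells, n_classes)."""
    rep = np.asarray(rep, dtype=np.float64)
    _check_width(rep, state)
    pre = rep @ state.params["head.W"] + state.params["head.b"]
    return _nn.leaky_relu(pre, state.arch.leaky_slope)


# ---------------------------------------------------------------------------
# Full forward / backward
# ---------------------------------------------------------------------------


def _forward_full(x: np.ndarray, state: ModelState) -> Tuple[np.ndarray, np.ndarray, dict]:
    a, gene_scores, att_cache = _attention_with_cache(x, state)
    z = gene_scores
    block_caches = []
    for b in range(state.arch.n_blocks):
        z, cache = _block_forward(z, gene_scores, state, b)
        block_caches.append(cache)
    head_pre = z @ state.params["head.W"] + state.params["head.b"]
    logits = _nn.leaky_relu(head_pre, state.arch.leaky_slope)
    caches = {
        "att": att_cache,
        "blocks": block_caches,
        "head_pre": head_pre,
        "rep": z,
    }
    return logits, a, caches


def model_forward(x, state: ModelState) -> Tuple[np.ndarray, np.ndarray]:
    """Full forward pass: (class logits, attention tensor)."""
    x = _as_counts(x)
    _check_width(x, state)
    logits, a, _ = _forward_full(x, state)
    return logits, a


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.
    """
    p = _nn.softmax_rows(logits)
    c = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(c), y] + eps))
    dlogits = p.copy()
    dlogits[np.arange(c), y] -= 1.0
    dlogits /= c
    return float(loss), dlogits


def _backward_full(
    dlogits: np.ndarray, caches: dict, state: ModelState
) -> Dict[str, np.ndarray]:
    grads: Dict[str, np.ndarray] = {}
    slope = state.arch.leaky_slope
    dhead_pre = _nn.leaky_relu_backward(caches["head_pre"], dlogits, slope)
    grads["head.W"] = caches["rep"].T @ dhead_pre
    grads["head.b"] = dhead_pre.sum(axis=0)
    dz = dhead_pre @ state.params["head.W"].T
    dgene_scores = np.zeros_like(caches["att"]["a"])
    for b in reversed(range(state.arch.n_blocks)):
        dz, dgs = _block_backward(dz, caches["blocks"][b], state, b, grads)
        dgene_scores += dgs
    dgene_scores += dz  # gene scores are also the first block's input
    _attention_backward(dgene_scores, caches["att"], state, grads)
    return grads


def loss_and_grads(
    x: np.ndarray, y: np.ndarray, state: ModelState
) -> Tuple[float, Dict[str, np.ndarray]]:
    """Cross-entropy loss and gradients for a minibatch."""
    logits, _, caches = _forward_full(x, state)
    loss, dlogits = cross_entropy(logits, y)
    grads = _backward_full(dlogits, caches, state)
    return loss, grads
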