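"""Training loop, learning-rate schedule, and pseudo-labelling.

The network is trained with minibatch Adam on a softmax cross-entropy
objective for a fixed number of epochs, with an exponential
learning-rate schedule: the base rate holds until the first decay at
``schedule_start_epoch`` and is multiplied by ``gamma`` there and at
every ``schedule_interval`` epochs after (decays at epochs 10, 15, 20,
... under the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import accuracy_score, f1_score
from sklearn.model_selection import train_test_split

from . import _nn, model as M
from .containers import CountMatrix

__all__ = ["TrainConfig", "TrainHistory", "schedule_lr", "train", "pseudo_label"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 50
    schedule_start_epoch: int = 10
    schedule_interval: int = 5
    gamma: float = 0.95
    batch_size: int = 128
    train_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainHistory:
    loss: List[float] = field(default_factory=list)
    val_accuracy: List[Optional[float]] = field(default_factory=list)
    val_weighted_f1: List[Optional[float]] = field(default_factory=list)
    lr: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def to_dict(self) -> dict:
        return asdict(self)


def schedule_lr(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate in effect during 0-based ``epoch``.

    Closed form ``lr * gamma ** d`` where ``d`` counts decay events at
    or before this epoch; the first decay is applied AT
    ``schedule_start_epoch``.
    """
    if epoch < cfg.schedule_start_epoch:
        d = 0
    else:
        d = (epoch - cfg.schedule_start_epoch) // cfg.schedule_interval + 1
    return cfg.lr * cfg.gamma**d


def run_epochs(
    state: M.ModelState,
    x_train: np.ndarray,
    y_train: np.ndarray,
    cfg: TrainConfig,
    x_val: Optional[np.ndarray] = None,
    y_val: Optional[np.ndarray] = None,
    epochs: Optional[int] = None,
) -> TrainHistory:
    """Run Adam epochs in place on ``state``; returns the per-epoch history.

    ``y_train``/``y_val`` are integer class indices. Only parameters of
    modules whose trainable flag is set are updated.
    """
    epochs = cfg.epochs if epochs is None else epochs
    rng = np.random.default_rng(cfg.seed)
    trainable = set(state.trainable_param_names())
    opt = _nn.AdamOptimizer(state.params, trainable)
    history = TrainHistory()
    n = x_train.shape[0]
    for epoch in range(epochs):
        lr = schedule_lr(epoch, cfg)
        order = rng.permutation(n)
        total_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            loss, grads = M.loss_and_grads(x_train[idx], y_train[idx], state)
            opt.step(state.params, grads, lr)
            total_loss += loss * len(idx)
        history.loss.append(total_loss / n)
        history.lr.append(lr)
        if x_val is not None and len(x_val) > 0:
            logits, _ = M.model_forward(x_val, state)
            pred = logits.argmax(axis=1)
            history.val_accuracy.append(float(accuracy_score(y_val, pred)))
            history.val_weighted_f1.append(
                float(f1_score(y_val, pred, average="weighted", zero_division=0))
            )
        else:
            history.val_accuracy.append(None)
            history.val_weighted_f1.append(None)
    return history


def encode_labels(labels: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Map labels to integer codes; classes in sorted order."""
    classes, y = np.unique(np.asarray(labels, dtype=object).astype(str), return_inverse=True)
    return classes, y


def stratified_split(
    x: np.ndarray, y: np.ndarray, train_fraction: float, seed: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train")
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ValueError(
            f"class {bad!r} has {counts.min()} cell(s); stratified splitting "
            "requires at least 2 per class"
        )
    x_tr, x_va, y_tr, y_va = train_test_split(
        x,
        y,
        train_size=train_fraction,
        stratify=y,
        random_state=seed % (2**32 - 1),
    )
    if len(np.unique(y_tr)) < len(classes):
        raise ValueError("a class is absent from the training split")
    return x_tr, x_va, y_tr, y_va


def train(
    mat: CountMatrix,
    arch: M.ArchitectureConfig,
    cfg: TrainConfig = TrainConfig(),
) -> Tuple[M.ModelState, TrainHistory]:
    """Train the three-module network on a labelled count matrix.

    A stratified ``train_fraction`` / ``1 - train_fraction`` split
    provides held-out monitoring (accuracy and weighted F1 per epoch);
    the split does not feed back into optimization. Fully reproducible
    given ``cfg.seed``.
    """
    if mat.labels is None:
        raise ValueError("training requires labels (true or pseudo)")
    if mat.n_genes != arch.n_genes:
        raise ValueError(
            f"matrix has {mat.n_genes} genes but architecture expects {arch.n_genes}"
        )
    classes, y = encode_labels(mat.labels)
    if len(classes) != arch.n_classes:
        raise ValueError(
            f"labels have {len(classes)} classes but architecture expects "
            f"{arch.n_classes}"
        )
    x_tr, x_va, y_tr, y_va = stratified_split(mat.counts, y, cfg.train_fraction, cfg.seed)
    state = M.init_state(arch)
    state.gene_names = mat.gene_names.copy()
    history = run_epochs(state, x_tr, y_tr, cfg, x_va, y_va)
    return state, history


def pseudo_label(mat: CountMatrix, n_clusters: int, seed: int = 0) -> np.ndarray:
    """K-means cluster ids on a log1p-PCA embedding, as fallback
    pseudo-labels so the pipeline runs without an external clustering
    tool. Deterministic given ``seed``."""
    c = mat.n_cells
    if n_clusters > c:
        raise ValueError(f"n_clusters={n_clusters} exceeds n_cells={c}")
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if n_clusters == c:
        # one cluster per cell; k-means on duplicated points is ill-posed
        return np.arange(c)
    x = np.log1p(mat.counts)
    n_comp = min(50, c - 1, mat.n_genes)
    emb = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed % (2**32 - 1))
    return km.fit_predict(emb)
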