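"""Scikit-learn-style estimator wrapping the attention network.

``AttentionClassifier`` is the package's main entry point: it trains the
three-module core on counts plus labels and then exposes both the
classifier surface (``predict``, ``predict_proba``) and the
interpretability surface (``attention``, ``gene_scores``) that all
downstream analyses consume.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn, model as M, training as T

__all__ = ["AttentionClassifier"]


class AttentionClassifier(BaseEstimator, ClassifierMixin):
    """Additive-attention classifier for count data.

    Parameters mirror the architecture and optimizer defaults: ``k``
    projection blocks of ``h`` branches with a ``N -> bottleneck -> N``
    subnetwork, trained with Adam at ``lr`` for ``epochs`` epochs under
    an exponential schedule (decay ``gamma`` starting at
    ``schedule_start_epoch``, every ``schedule_interval`` epochs after).

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels.
    state_ : ModelState
        All learned parameters plus per-module trainable flags.
    history_ : TrainHistory
        Per-epoch loss, held-out accuracy / weighted F1, and the
        learning rate in effect.
    """

    def __init__(
        self,
        n_blocks: int = 2,
        n_branches: int = 4,
        bottleneck: int = 128,
        leaky_slope: float = 0.01,
        layernorm_eps: float = 1e-5,
        attention_rank: Optional[int] = None,
        log1p_input: bool = False,
        lr: float = 1e-4,
        epochs: int = 50,
        schedule_start_epoch: int = 10,
        schedule_interval: int = 5,
        gamma: float = 0.95,
        batch_size: int = 128,
        validation_fraction: float = 0.2,
        random_state: int = 0,
    ):
        self.n_blocks = n_blocks
        self.n_branches = n_branches
        self.bottleneck = bottleneck
        self.leaky_slope = leaky_slope
        self.layernorm_eps = layernorm_eps
        self.attention_rank = attention_rank
        self.log1p_input = log1p_input
        self.lr = lr
        self.epochs = epochs
        self.schedule_start_epoch = schedule_start_epoch
        self.schedule_interval = schedule_interval
        self.gamma = gamma
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _train_config(self) -> T.TrainConfig:
        return T.TrainConfig(
            lr=self.lr,
            epochs=self.epochs,
            schedule_start_epoch=self.schedule_start_epoch,
            schedule_interval=self.schedule_interval,
            gamma=self.gamma,
            batch_size=self.batch_size,
            train_fraction=1.0 - self.validation_fraction,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (cells x genes)")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("X and y have different numbers of cells")
        self.classes_, y_int = T.encode_labels(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        arch = M.ArchitectureConfig(
            n_genes=X.shape[1],
            n_classes=len(self.classes_),
            n_blocks=self.n_blocks,
            n_branches=self.n_branches,
            bottleneck=self.bottleneck,
            leaky_slope=self.leaky_slope,
            layernorm_eps=self.layernorm_eps,
            seed=self.random_state,
            attention_rank=self.attention_rank,
            log1p_input=self.log1p_input,
        )
        cfg = self._train_config()
        if self.validation_fraction > 0:
            x_tr, x_va, y_tr, y_va = T.stratified_split(
                X, y_int, 1.0 - self.validation_fraction, self.random_state
            )
        else:
            x_tr, y_tr, x_va, y_va = X, y_int, None, None
        self.state_ = M.init_state(arch)
        self.history_ = T.run_epochs(self.state_, x_tr, y_tr, cfg, x_va, y_va)
        self.n_features_in_ = X.shape[1]
        return self

    # ------------------------------------------------------------------
    def decision_function(self, X):
        check_is_fitted(self, "state_")
        logits, _ = M.model_forward(np.asarray(X, dtype=np.float64), self.state_)
        return logits

    def predict_proba(self, X):
        return _nn.softmax_rows(self.decision_function(X))

    def predict(self, X):
        check_is_fitted(self, "state_")
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def attention(self, X):
        """Per-cell attention tensor ``A`` (rows sum to 1)."""
        check_is_fitted(self, "state_")
        a, _ = M.attention_forward(np.asarray(X, dtype=np.float64), self.state_)
        return a

    def gene_scores(self, X):
        """Interpretable gene scores ``G = A * X``."""
        check_is_fitted(self, "state_")
        _, g = M.attention_forward(np.asarray(X, dtype=np.float64), self.state_)
        return g
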