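"""Freeze-and-finetune transfer learning.

A model pretrained on a reference dataset keeps its attention and
projection modules bitwise frozen; only the configuration head is
replaced (when the query has a different number of cell populations) or
warm-started, and fine-tuned on a small fraction of the query cells
(20% by default, with the remaining 80% held out for testing). Query
counts are first aligned to the reference gene order, with reference
genes missing from the query zero-filled so the attention softmax keeps
its meaning over the reference gene space.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Optional, Tuple

import numpy as np
from sklearn.model_selection import train_test_split

from . import _nn, model as M
from .containers import CountMatrix
from .training import TrainConfig, TrainHistory, encode_labels, run_epochs

__all__ = [
    "freeze_feature_modules",
    "replace_head",
    "align_genes",
    "AlignmentReport",
    "fine_tune",
]


def freeze_feature_modules(state: M.ModelState) -> M.ModelState:
    """Mark the attention and projection modules non-trainable.

    Fine-tuning a frozen state leaves those parameters bitwise
    unchanged; only the configuration head can move. Idempotent.
    """
    out = state.copy()
    out.trainable["attention"] = False
    out.trainable["projection"] = False
    out.trainable["head"] = True
    return out


def replace_head(state: M.ModelState, n_classes_query: int, seed: int = 0) -> M.ModelState:
    """Fresh configuration head sized for the query's class count.

    Feature modules are untouched; the head is re-initialized with the
    given seed (uniform fan-in weights, zero bias).
    """
    if n_classes_query < 2:
        raise ValueError("n_classes_query must be >= 2")
    out = state.copy()
    out.arch = dc_replace(state.arch, n_classes=n_classes_query)
    rng = np.random.default_rng(seed)
    n = state.arch.n_genes
    out.params["head.W"] = _nn.uniform_fan_in(rng, (n, n_classes_query))
    out.params["head.b"] = np.zeros(n_classes_query)
    return out


@dataclass
class AlignmentReport:
    n_matched: int
    n_zero_filled: int
    n_dropped: int


def align_genes(
    query: CountMatrix,
    reference_gene_names,
    min_overlap: float = 0.5,
) -> Tuple[CountMatrix, AlignmentReport]:
    """Reorder query columns to the reference gene order.

    Reference genes absent from the query become zero columns; query
    genes outside the reference are dropped. Errors out when the
    overlap with the reference falls below ``min_overlap`` (attention
    weights over a mostly-missing gene space would be meaningless).
    """
    ref = [str(g) for g in reference_gene_names]
    q_idx = {str(g): i for i, g in enumerate(query.gene_names)}
    matched = [g for g in ref if g in q_idx]
    if len(matched) == 0:
        raise ValueError("no overlap between query and reference gene names")
    overlap = len(matched) / len(ref)
    if overlap < min_overlap:
        raise ValueError(
            f"gene overlap {overlap:.1%} below the {min_overlap:.0%} floor; "
            "transfer would be meaningless"
        )
    counts = np.zeros((query.n_cells, len(ref)))
    for j, g in enumerate(ref):
        if g in q_idx:
            counts[:, j] = query.counts[:, q_idx[g]]
    report = AlignmentReport(
        n_matched=len(matched),
        n_zero_filled=len(ref) - len(matched),
        n_dropped=query.n_genes - len(matched),
    )
    aligned = CountMatrix(
        counts=counts,
        gene_names=np.array(ref, dtype=object),
        cell_ids=query.cell_ids,
        labels=query.labels,
    )
    return aligned, report


def fine_tune(
    state: M.ModelState,
    query: CountMatrix,
    epochs: int = 10,
    cfg: TrainConfig = TrainConfig(),
    finetune_fraction: float = 0.2,
) -> Tuple[M.ModelState, TrainHistory]:
    """Fine-tune the configuration head on a fraction of the query.

    ``finetune_fraction`` of the query cells (stratified) train the
    head; the remaining cells are the held-out test set whose accuracy
    and weighted F1 are recorded per epoch. The state must have been
    frozen explicitly with :func:`freeze_feature_modules`; the same
    optimizer and learning-rate schedule as pre-training apply.
    ``epochs=0`` returns the state unchanged.
    """
    if state.trainable["attention"] or state.trainable["projection"]:
        raise ValueError(
            "fine_tune requires feature modules frozen; call "
            "freeze_feature_modules first"
        )
    if query.labels is None:
        raise ValueError("fine-tuning requires query labels")
    if query.n_genes != state.arch.n_genes:
        raise ValueError(
            f"query has {query.n_genes} genes but the model expects "
            f"{state.arch.n_genes}; align_genes first"
        )
    classes, y = encode_labels(query.labels)
    if len(classes) != state.arch.n_classes:
        raise ValueError(
            f"query has {len(classes)} classes but the head outputs "
            f"{state.arch.n_classes}; use replace_head"
        )
    out = state.copy()
    if epochs == 0:
        return out, TrainHistory()
    x_ft, x_te, y_ft, y_te = train_test_split(
        query.counts,
        y,
        train_size=finetune_fraction,
        stratify=y,
        random_state=cfg.seed % (2**32 - 1),
    )
    history = run_epochs(out, x_ft, y_ft, cfg, x_te, y_te, epochs=epochs)
    return out, history


def evaluate_state(
    state: M.ModelState, mat: CountMatrix, labels: Optional[np.ndarray] = None
) -> Tuple[float, float]:
    """(accuracy, weighted F1) of a model state on labelled counts."""
    from sklearn.metrics import accuracy_score, f1_score

    y_raw = labels if labels is not None else mat.labels
    if y_raw is None:
        raise ValueError("labels required for evaluation")
    classes, y = encode_labels(np.asarray(y_raw))
    logits, _ = M.model_forward(mat.counts, state)
    pred = logits.argmax(axis=1)
    return (
        float(accuracy_score(y, pred)),
        float(f1_score(y, pred, average="weighted", zero_division=0)),
    )
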