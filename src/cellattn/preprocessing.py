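"""Quality-control filtering and highly-variable-gene selection.

The filter order is cells -> genes -> classes: cell filters (minimum
expressed genes, mitochondrial fraction) run first, the gene prevalence
filter is evaluated on the post-cell-filter matrix, and the small-class
filter runs last when labels are present. Boundary semantics are strict
readings of the rules: a cell expressing exactly ``min_genes_per_cell``
genes is kept ("fewer than" removes), a cell at exactly the
mitochondrial cutoff is removed ("less than" keeps), and a class with
exactly ``min_cells_per_class`` members is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import List, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountMatrix

__all__ = [
    "QCConfig",
    "FilterReport",
    "filter_counts",
    "select_hvg",
    "hvg_scores",
    "HighlyVariableGenes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCConfig:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.10
    min_cells_per_class: int = 100
    n_hvg: int = 5000
    mito_prefixes: Tuple[str, ...] = ("MT-", "mt-")

    def __post_init__(self) -> None:
        if min(self.min_genes_per_cell, self.min_cells_per_gene, self.min_cells_per_class) < 0:
            raise ValueError("count thresholds must be >= 0")
        if not 0.0 <= self.max_mito_fraction <= 1.0:
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be >= 1")


@dataclass
class FilterReport:
    """Per-rule removal counts; each count equals the size change along
    the corresponding axis caused by that rule."""

    cells_removed_low_genes: int = 0
    cells_removed_mito: int = 0
    genes_removed: int = 0
    classes_removed: int = 0
    cells_removed_small_class: int = 0
    dropped_classes: List[str] = field(default_factory=list)

    @property
    def cells_removed(self) -> int:
        return (
            self.cells_removed_low_genes
            + self.cells_removed_mito
            + self.cells_removed_small_class
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cells_removed"] = self.cells_removed
        return d


def _mito_mask(gene_names: np.ndarray, prefixes: Tuple[str, ...]) -> np.ndarray:
    return np.array(
        [any(str(g).startswith(p) for p in prefixes) for g in gene_names], dtype=bool
    )


def filter_counts(mat: CountMatrix, cfg: QCConfig = QCConfig()) -> Tuple[CountMatrix, FilterReport]:
    """Apply the QC filters and report what each rule removed.

    Raises ``ValueError`` if no cells or no genes survive, rather than
    returning an empty matrix.
    """
    report = FilterReport()

    # --- cell filters -----------------------------------------------------
    genes_per_cell = (mat.counts > 0).sum(axis=1)
    keep_genes_rule = genes_per_cell >= cfg.min_genes_per_cell
    report.cells_removed_low_genes = int((~keep_genes_rule).sum())

    mito = _mito_mask(mat.gene_names, cfg.mito_prefixes)
    total = mat.counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mat.counts[:, mito].sum(axis=1) / total, 0.0)
    keep_mito_rule = mito_frac < cfg.max_mito_fraction
    report.cells_removed_mito = int((keep_genes_rule & ~keep_mito_rule).sum())

    keep_cells = keep_genes_rule & keep_mito_rule
    if not keep_cells.any():
        raise ValueError("no cells survive QC filtering")
    out = mat.subset_cells(keep_cells)

    # --- gene filter (on the post-cell-filter matrix) ---------------------
    cells_per_gene = (out.counts > 0).sum(axis=0)
    keep_gene = cells_per_gene >= cfg.min_cells_per_gene
    report.genes_removed = int((~keep_gene).sum())
    if not keep_gene.any():
        raise ValueError("no genes survive QC filtering")
    out = out.subset_genes(keep_gene)

    # --- class filter ------------------------------------------------------
    if out.labels is not None:
        labels = out.labels
        classes, counts = np.unique(labels, return_counts=True)
        small = counts < cfg.min_cells_per_class
        report.classes_removed = int(small.sum())
        report.dropped_classes = [str(c) for c in classes[small]]
        if small.any():
            keep_class = ~np.isin(labels, classes[small])
            report.cells_removed_small_class = int((~keep_class).sum())
            if not keep_class.any():
                raise ValueError("no cells survive the small-class filter")
            out = out.subset_cells(keep_class)
            logger.info(
                "dropped %d classes (<%d cells): %s",
                report.classes_removed,
                cfg.min_cells_per_class,
                report.dropped_classes,
            )

    return out, report


def hvg_scores(mat: CountMatrix, method: str = "vst") -> np.ndarray:
    """Per-gene variability score under the chosen scheme.

    ``"vst"`` computes the variance-stabilized standardized variance: a
    quadratic trend of log10 variance against log10 mean is fit across
    genes, each gene's counts are standardized by its mean and the
    trend-predicted standard deviation with values clipped at
    ``sqrt(n_cells)``, and the variance of the clipped standardized
    values is the score. ``"logvar"`` is a plain variance of log1p
    counts.
    """
    x = mat.counts
    c = x.shape[0]
    if method == "logvar":
        return np.log1p(x).var(axis=0)
    if method != "vst":
        raise ValueError(f"unknown HVG method {method!r}")

    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1) if c > 1 else np.zeros_like(mean)
    score = np.zeros_like(mean)
    positive = (mean > 0) & (var > 0)
    if positive.sum() >= 3:
        lm = np.log10(mean[positive])
        lv = np.log10(var[positive])
        coef = np.polyfit(lm, lv, deg=2)
        pred_sd = np.sqrt(10 ** np.polyval(coef, np.log10(mean[positive])))
        clip = np.sqrt(c)
        z = (x[:, positive] - mean[positive]) / pred_sd
        z = np.clip(z, -clip, clip)
        # variance of clipped standardized values around the standardized mean
        score[positive] = (z**2).sum(axis=0) / (c - 1) - (z.sum(axis=0) ** 2) / (
            c * (c - 1)
        )
    elif positive.any():
        score[positive] = var[positive]
    return score


def select_hvg(
    mat: CountMatrix, n_hvg: int, method: str = "vst"
) -> Tuple[CountMatrix, List[str]]:
    """Restrict the matrix to the ``n_hvg`` most variable genes.

    Returns the reduced matrix (genes in original column order) and the
    ranked HVG list (most variable first). Ties break by gene index.
    """
    if n_hvg > mat.n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds the {mat.n_genes} available genes")
    scores = hvg_scores(mat, method=method)
    order = np.lexsort((np.arange(len(scores)), -scores))
    top = order[:n_hvg]
    ranked = [str(mat.gene_names[i]) for i in top]
    keep = np.zeros(mat.n_genes, dtype=bool)
    keep[top] = True
    return mat.subset_genes(keep), ranked


class HighlyVariableGenes(BaseEstimator, TransformerMixin):
    """Sklearn-style column selector keeping the top ``n_hvg`` genes.

    ``fit`` expects a raw count array (cells x genes); ``transform``
    subsets columns. Gene names are optional and only used to expose the
    ranked list.
    """

    def __init__(self, n_hvg: int = 5000, method: str = "vst"):
        self.n_hvg = n_hvg
        self.method = method

    def fit(self, X, y=None, gene_names=None):
        X = np.asarray(X, dtype=np.float64)
        names = (
            np.asarray(gene_names, dtype=object)
            if gene_names is not None
            else np.array([f"g{i}" for i in range(X.shape[1])], dtype=object)
        )
        mat = CountMatrix(X, names, np.array([f"c{i}" for i in range(X.shape[0])], dtype=object))
        _, ranked = select_hvg(mat, self.n_hvg, method=self.method)
        name_to_idx = {str(g): i for i, g in enumerate(names)}
        top = sorted(name_to_idx[g] for g in ranked)
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[top] = True
        self.ranked_genes_ = ranked
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("transform input width differs from fit input")
        return X[:, self.support_]
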