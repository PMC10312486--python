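"""Feature-selection evaluation: classification quality and variance
explained for top-n gene subsets.

A selected gene set is scored two ways: the weighted F1 of a
k-nearest-neighbour classifier restricted to those genes on a held-out
stratified split, and the fraction of total per-gene variance the set
captures on the original gene space. Both are computed across a grid of
subset sizes to produce the feature curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import f1_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .containers import CountMatrix
from .interpretation import MarkerRanking

__all__ = ["FeatureEvalReport", "fraction_variance", "knn_f1", "feature_curve"]

DEFAULT_N_LIST = (10, 25, 50, 100, 200, 300)


@dataclass
class FeatureEvalReport:
    n_list: List[int]
    weighted_f1: List[float]
    variance_fraction: List[float]
    baseline_f1: float  # full gene space
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.n_list,
                "weighted_f1": self.weighted_f1,
                "variance_fraction": self.variance_fraction,
            }
        )


def _gene_variances(mat: CountMatrix, log1p: bool) -> np.ndarray:
    x = np.log1p(mat.counts) if log1p else mat.counts
    return x.var(axis=0)


def fraction_variance(
    mat: CountMatrix, selected_genes: Sequence[str], log1p: bool = False
) -> float:
    """Sum of per-gene variances over the selection divided by the sum
    over all genes. Additive over disjoint selections by construction."""
    selected = set(map(str, selected_genes))
    unknown = selected - set(map(str, mat.gene_names))
    if unknown:
        raise ValueError(f"selected genes not in the matrix: {sorted(unknown)[:5]}")
    if not selected:
        warnings.warn("empty gene selection; variance fraction is 0", stacklevel=2)
        return 0.0
    variances = _gene_variances(mat, log1p)
    mask = np.array([str(g) in selected for g in mat.gene_names])
    total = variances.sum()
    if total == 0:
        return 0.0
    return float(variances[mask].sum() / total)


def knn_f1(
    mat: CountMatrix,
    labels: Sequence,
    selected_genes: Sequence[str],
    split_seed: int = 0,
    n_neighbors: int = 15,
    test_fraction: float = 0.2,
) -> float:
    """Weighted F1 of a KNN classifier on the selected genes, evaluated
    on a held-out stratified split. Deterministic given ``split_seed``."""
    labels = np.asarray(labels, dtype=object).astype(str)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 members for stratification")
    selected = [str(g) for g in selected_genes]
    name_to_idx = {str(g): i for i, g in enumerate(mat.gene_names)}
    try:
        idx = [name_to_idx[g] for g in selected]
    except KeyError as e:
        raise ValueError(f"selected gene not in the matrix: {e.args[0]!r}") from None
    x = mat.counts[:, idx]
    x_tr, x_te, y_tr, y_te = train_test_split(
        x,
        labels,
        test_size=test_fraction,
        stratify=labels,
        random_state=split_seed % (2**32 - 1),
    )
    k = min(n_neighbors, len(x_tr))
    clf = KNeighborsClassifier(n_neighbors=k).fit(x_tr, y_tr)
    return float(f1_score(y_te, clf.predict(x_te), average="weighted", zero_division=0))


def feature_curve(
    mat: CountMatrix,
    labels: Sequence,
    ranking: MarkerRanking,
    n_list: Sequence[int] = DEFAULT_N_LIST,
    split_seed: int = 0,
    log1p_variance: bool = False,
) -> FeatureEvalReport:
    """Evaluate nested top-n prefixes of a marker ranking.

    The variance-fraction column is monotone non-decreasing because the
    prefixes are nested. The baseline row uses the full gene space.
    """
    n_list = sorted(int(n) for n in n_list)
    if n_list[0] < 1:
        raise ValueError("subset sizes must be >= 1")
    if n_list[-1] > len(ranking):
        raise ValueError(
            f"n={n_list[-1]} exceeds the ranking length {len(ranking)}"
        )
    f1s, fracs = [], []
    for n in n_list:
        top = ranking.top(n)
        f1s.append(knn_f1(mat, labels, top, split_seed=split_seed))
        fracs.append(fraction_variance(mat, top, log1p=log1p_variance))
    baseline = knn_f1(mat, labels, list(map(str, mat.gene_names)), split_seed=split_seed)
    return FeatureEvalReport(
        n_list=list(n_list),
        weighted_f1=f1s,
        variance_fraction=fracs,
        baseline_f1=baseline,
        metadata={"log1p_variance": log1p_variance, "split_seed": split_seed},
    )
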