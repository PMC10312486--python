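"""Downstream interpretation of the learned attention tensor.

After a single training run the attention weights alone drive marker
selection, cluster characterization, and enrichment-based annotation:

* **global markers** — genes ranked by mean attention over all cells;
* **cluster markers** — the same ranking restricted to each cluster's
  cells, the input to unsupervised annotation;
* **attention correlation** — Pearson correlation between per-cluster
  mean attention vectors, a compact view of which populations the model
  considers transcriptionally similar;
* **enrichment** — one-sided hypergeometric tests of a marker list
  against a GMT gene-set library with Benjamini-Hochberg adjustment,
  replacing web-service enrichment queries with a local, reproducible
  computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerRanking",
    "EnrichmentResult",
    "ClusterAnnotation",
    "global_markers",
    "cluster_markers",
    "attention_correlation",
    "enrich",
    "annotate_clusters",
]

logger = logging.getLogger(__name__)


@dataclass
class MarkerRanking:
    """Ordered gene list with aggregated attention scores.

    ``scope`` is ``"global"`` or the cluster id the ranking belongs to.
    Scores are non-increasing; ties break by original gene index.
    """

    genes: List[str]
    scores: np.ndarray
    scope: str = "global"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)

    def top(self, n: int) -> List[str]:
        return self.genes[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene": self.genes, "score": self.scores, "scope": self.scope})


@dataclass
class EnrichmentResult:
    term: str
    overlap: int  # k: query genes in the term
    query_size: int  # n
    term_size: int  # K (restricted to the background)
    background_size: int  # M
    p_value: float
    adjusted_p: float
    overlap_genes: List[str] = field(default_factory=list)


@dataclass
class ClusterAnnotation:
    cluster: str
    call: Optional[str]  # None when nothing is enriched ("unassigned")
    tied_calls: List[str]
    results: List[EnrichmentResult]


def _rank(mean_attention: np.ndarray, gene_names: Sequence[str], scope: str) -> MarkerRanking:
    order = np.lexsort((np.arange(len(mean_attention)), -mean_attention))
    return MarkerRanking(
        genes=[str(gene_names[i]) for i in order],
        scores=mean_attention[order],
        scope=scope,
    )


def global_markers(attention: np.ndarray, gene_names: Sequence[str]) -> MarkerRanking:
    """Rank genes by mean attention weight over all cells."""
    attention = np.asarray(attention, dtype=np.float64)
    return _rank(attention.mean(axis=0), gene_names, "global")


def cluster_markers(
    attention: np.ndarray,
    labels: Sequence,
    gene_names: Sequence[str],
    top_n: int = 50,
    counts: Optional[np.ndarray] = None,
    statistic: str = "auto",
) -> Dict[str, MarkerRanking]:
    """Top ``top_n`` genes per cluster ranked by a within-cluster statistic.

    ``statistic`` picks the aggregator:

    * ``"gene_score"`` — mean gene score (attention * counts) over the
      cluster's cells; requires ``counts``. This is the default whenever
      counts are supplied: attention alone measures *global* salience,
      so a cluster's plain attention mean also elevates genes that are
      salient for other populations, while the gene score ties salience
      to the cluster's own expression.
    * ``"attention"`` — mean attention weight over the cluster's cells.
    * ``"differential"`` — cluster mean attention minus the global mean
      attention.
    * ``"auto"`` — ``"gene_score"`` if counts are given, else
      ``"attention"``.
    """
    attention = np.asarray(attention, dtype=np.float64)
    if top_n > attention.shape[1]:
        raise ValueError(f"top_n={top_n} exceeds the {attention.shape[1]} genes")
    labels = np.asarray(labels, dtype=object)
    if len(labels) != attention.shape[0]:
        raise ValueError("labels must cover all cells")
    if statistic == "auto":
        statistic = "gene_score" if counts is not None else "attention"
    if statistic == "gene_score":
        if counts is None:
            raise ValueError("statistic='gene_score' requires counts")
        values = attention * np.asarray(counts, dtype=np.float64)
    elif statistic == "attention":
        values = attention
    elif statistic == "differential":
        values = attention - attention.mean(axis=0)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    out: Dict[str, MarkerRanking] = {}
    for cls in np.unique(labels.astype(str)):
        mask = labels.astype(str) == cls
        mean = values[mask].mean(axis=0)
        ranking = _rank(mean, gene_names, scope=str(cls))
        out[str(cls)] = MarkerRanking(
            genes=ranking.genes[:top_n], scores=ranking.scores[:top_n], scope=str(cls)
        )
    return out


def attention_correlation(
    attention: np.ndarray, labels: Sequence
) -> pd.DataFrame:
    """Pearson correlation between per-cluster mean attention vectors.

    Symmetric with unit diagonal; a cluster whose mean vector has zero
    variance yields NaN against every other cluster (correlation is
    undefined, not zero).
    """
    attention = np.asarray(attention, dtype=np.float64)
    labels = np.asarray(labels, dtype=object).astype(str)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes for a correlation matrix")
    means = np.vstack([attention[labels == c].mean(axis=0) for c in classes])
    t = len(classes)
    corr = np.eye(t)
    sd = means.std(axis=1)
    for i in range(t):
        for j in range(i + 1, t):
            if sd[i] == 0 or sd[j] == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(means[i], means[j])[0, 1])
            corr[i, j] = corr[j, i] = r
    return pd.DataFrame(corr, index=classes, columns=classes)


def enrich(
    query_genes: Sequence[str],
    library: Dict[str, Sequence[str]],
    background: Sequence[str],
) -> List[EnrichmentResult]:
    """One-sided hypergeometric enrichment of a gene list.

    For each term with ``K`` genes in the size-``M`` background and an
    overlap of ``k`` with the size-``n`` query, the raw p-value is
    ``P(X >= k)`` for ``X ~ Hypergeom(M, K, n)``; Benjamini-Hochberg
    adjustment runs across all terms in the library. Matching is
    case-insensitive; query genes outside the background are dropped
    with a logged count. Results are sorted by adjusted then raw
    p-value, with the term name breaking ties deterministically.
    """
    if not library:
        raise ValueError("empty gene-set library")
    if len(query_genes) == 0:
        raise ValueError("empty query gene list")
    bg = {str(g).upper() for g in background}
    m = len(bg)
    query = {str(g).upper() for g in query_genes}
    dropped = len(query - bg)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    query &= bg
    n = len(query)
    results: List[EnrichmentResult] = []
    for term in library:
        term_genes = {str(g).upper() for g in library[term]} & bg
        k_cap = len(term_genes)
        overlap = sorted(query & term_genes)
        k = len(overlap)
        # upper tail P(X >= k); k = 0 gives exactly 1
        p = float(hypergeom.sf(k - 1, m, k_cap, n)) if n > 0 else 1.0
        p = min(p, 1.0)
        results.append(
            EnrichmentResult(
                term=str(term),
                overlap=k,
                query_size=n,
                term_size=k_cap,
                background_size=m,
                p_value=p,
                adjusted_p=np.nan,
                overlap_genes=overlap,
            )
        )
    raw = np.array([r.p_value for r in results])
    adj = multipletests(raw, method="fdr_bh")[1]
    for r, a in zip(results, adj):
        r.adjusted_p = float(max(a, r.p_value))
    results.sort(key=lambda r: (r.adjusted_p, r.p_value, r.term))
    return results


def annotate_clusters(
    attention: np.ndarray,
    labels: Sequence,
    gene_names: Sequence[str],
    library: Dict[str, Sequence[str]],
    top_n: int = 50,
    background: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    counts: Optional[np.ndarray] = None,
    statistic: str = "auto",
) -> Dict[str, ClusterAnnotation]:
    """Enrichment-based cell-type calls per cluster.

    Each cluster's top ``top_n`` attentive genes are tested against the
    library; the term with the smallest adjusted p-value below ``alpha``
    is the primary call. Ties on the minimal p-value are reported, not
    silently broken; a cluster with no term below ``alpha`` is
    unassigned (``call=None``). The full result table is retained per
    cluster for disambiguation of broad or mixed populations.
    """
    if background is None:
        background = list(gene_names)
    markers = cluster_markers(
        attention, labels, gene_names, top_n=top_n, counts=counts, statistic=statistic
    )
    out: Dict[str, ClusterAnnotation] = {}
    for cluster, ranking in markers.items():
        results = enrich(ranking.genes, library, background)
        best_p = results[0].adjusted_p
        if best_p < alpha:
            tied = [r.term for r in results if r.adjusted_p == best_p]
            call = tied[0] if len(tied) == 1 else None
        else:
            tied, call = [], None
        out[cluster] = ClusterAnnotation(
            cluster=cluster, call=call, tied_calls=tied, results=results
        )
    return out
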