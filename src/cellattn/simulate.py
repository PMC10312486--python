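"""Negative-binomial count simulation with planted marker genes.

The generator draws cells from a gamma-Poisson (negative binomial)
model: gene ``j`` in cell ``i`` has mean
``base_mean * libsize_i * fold_ij`` where ``libsize_i`` is log-normal
and ``fold_ij = marker_fold`` when ``j`` is a planted marker of cell
``i``'s type, else 1. Inverse-dispersion ``theta`` controls
overdispersion (variance ``mu + mu^2 / theta``). Each type gets a
disjoint block of marker genes, and a small fraction of background
genes carry a mitochondrial name prefix so QC filters are exercised
end to end. A matching demo GMT library (one term per type holding
exactly its planted markers) makes annotation testable without any
external gene-set resource.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .containers import CountMatrix

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "make_transfer_pair"]


@dataclass(frozen=True)
class SimulationConfig:
    n_cells: int = 2000
    n_genes: int = 200
    n_types: int = 5
    markers_per_type: int = 10
    marker_fold: float = 8.0
    base_mean: float = 1.0
    dispersion: float = 2.0  # NB inverse-dispersion theta
    libsize_sigma: float = 0.3
    mito_fraction_genes: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1 or self.n_genes < 1 or self.n_types < 1:
            raise ValueError("n_cells, n_genes and n_types must be >= 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                f"markers_per_type * n_types = "
                f"{self.markers_per_type * self.n_types} exceeds n_genes = "
                f"{self.n_genes}"
            )
        for name in ("marker_fold", "base_mean", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.libsize_sigma < 0:
            raise ValueError("libsize_sigma must be >= 0")
        if not 0.0 <= self.mito_fraction_genes < 1.0:
            raise ValueError("mito_fraction_genes must lie in [0, 1)")


@dataclass
class SimulatedDataset:
    matrix: CountMatrix
    markers: Dict[str, List[str]]  # type label -> planted marker genes
    library: Dict[str, List[str]]  # demo GMT: one term per type

    @property
    def labels(self) -> np.ndarray:
        return self.matrix.labels


def _gene_names(cfg: SimulationConfig) -> List[str]:
    """Deterministic gene naming; mito-prefixed decoys are placed at the
    end of the background block, never among planted markers."""
    n_marker_genes = cfg.markers_per_type * cfg.n_types
    n_mito = int(round(cfg.mito_fraction_genes * cfg.n_genes))
    n_mito = min(n_mito, cfg.n_genes - n_marker_genes)
    names = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    for i in range(n_mito):
        idx = cfg.n_genes - 1 - i
        names[idx] = f"MT-GENE{idx:04d}"
    return names


def _marker_blocks(cfg: SimulationConfig) -> Dict[int, np.ndarray]:
    """Type t -> indices of its planted markers (disjoint blocks)."""
    return {
        t: np.arange(t * cfg.markers_per_type, (t + 1) * cfg.markers_per_type)
        for t in range(cfg.n_types)
    }


def _draw_counts(
    cfg: SimulationConfig, types: np.ndarray, blocks: Dict[int, np.ndarray], seed: int
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    lib = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=cfg.n_cells))
    mean = np.full((cfg.n_cells, cfg.n_genes), cfg.base_mean)
    for t, idx in blocks.items():
        mean[np.ix_(types == t, idx)] *= cfg.marker_fold
    mean *= lib[:, None]
    lam = rng.gamma(shape=cfg.dispersion, scale=mean / cfg.dispersion)
    return rng.poisson(lam).astype(np.float64)


def simulate(cfg: SimulationConfig) -> SimulatedDataset:
    """Draw a planted-marker NB dataset; bitwise deterministic per seed.

    Type labels are assigned round-robin, so classes are balanced up to
    rounding.
    """
    types = np.arange(cfg.n_cells) % cfg.n_types
    blocks = _marker_blocks(cfg)
    counts = _draw_counts(cfg, types, blocks, cfg.seed)
    names = np.array(_gene_names(cfg), dtype=object)
    labels = np.array([f"type_{t}" for t in types], dtype=object)
    mat = CountMatrix(
        counts=counts,
        gene_names=names,
        cell_ids=np.array([f"cell_{i:05d}" for i in range(cfg.n_cells)], dtype=object),
        labels=labels,
    )
    markers = {f"type_{t}": [str(names[j]) for j in blocks[t]] for t in blocks}
    library = {k: list(v) for k, v in markers.items()}
    return SimulatedDataset(matrix=mat, markers=markers, library=library)


def make_transfer_pair(
    cfg_ref: SimulationConfig, cfg_query: SimulationConfig, novel_types: int = 0
) -> Tuple[SimulatedDataset, SimulatedDataset]:
    """Reference/query pair sharing generative marker structure.

    The query has ``cfg_ref.n_types + novel_types`` types over the same
    gene space: shared types reuse the reference marker blocks and fold
    exactly; novel types get fresh disjoint marker blocks. ``cfg_query``
    supplies the query's cell count, seed and noise parameters; its
    ``n_types`` field is overridden to the combined type count.
    """
    if novel_types < 0:
        raise ValueError("novel_types must be >= 0")
    if cfg_query.n_genes != cfg_ref.n_genes:
        raise ValueError("reference and query must share the gene space")
    n_types_q = cfg_ref.n_types + novel_types
    cfg_q = SimulationConfig(
        n_cells=cfg_query.n_cells,
        n_genes=cfg_query.n_genes,
        n_types=n_types_q,
        markers_per_type=cfg_ref.markers_per_type,
        marker_fold=cfg_ref.marker_fold,
        base_mean=cfg_query.base_mean,
        dispersion=cfg_query.dispersion,
        libsize_sigma=cfg_query.libsize_sigma,
        mito_fraction_genes=cfg_ref.mito_fraction_genes,
        seed=cfg_query.seed,
    )
    reference = simulate(cfg_ref)
    query = simulate(cfg_q)
    return reference, query
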