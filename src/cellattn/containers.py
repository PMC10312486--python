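"""In-memory container for cells x genes count data.

The convention throughout the package is cells as rows and genes as
columns (``X`` with shape ``(n_cells, n_genes)``), matching how the
model consumes the data. On-disk MatrixMarket files follow the 10x
genes-x-cells convention; :mod:`cellattn.io` transposes at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = ["CountMatrix"]


def _check_unique(names: Sequence[str], what: str) -> None:
    if len(set(names)) != len(names):
        seen: set = set()
        dup = next(n for n in names if n in seen or seen.add(n))
        raise ValueError(f"duplicate {what}: {dup!r}")


@dataclass
class CountMatrix:
    """Raw counts for ``n_cells`` cells by ``n_genes`` genes.

    Parameters
    ----------
    counts
        Non-negative count matrix, shape ``(n_cells, n_genes)``. Stored
        as float64 internally so it can be fed to the model directly.
    gene_names
        Unique gene symbols, length ``n_genes``.
    cell_ids
        Unique cell barcodes/ids, length ``n_cells``.
    labels
        Optional per-cell categorical labels (true annotations or
        cluster pseudo-labels), length ``n_cells``.
    """

    counts: np.ndarray
    gene_names: np.ndarray
    cell_ids: np.ndarray
    labels: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError(f"counts must be 2-D, got shape {self.counts.shape}")
        if not np.all(np.isfinite(self.counts)):
            raise ValueError("counts contain non-finite values")
        if np.any(self.counts < 0):
            raise ValueError("counts contain negative values")
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        c, n = self.counts.shape
        if len(self.gene_names) != n:
            raise ValueError(
                f"{len(self.gene_names)} gene names for {n} count columns"
            )
        if len(self.cell_ids) != c:
            raise ValueError(f"{len(self.cell_ids)} cell ids for {c} count rows")
        _check_unique(list(self.gene_names), "gene name")
        _check_unique(list(self.cell_ids), "cell id")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != c:
                raise ValueError(
                    f"{len(self.labels)} labels for {c} cells"
                )

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask_or_idx: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given cells."""
        labels = self.labels[mask_or_idx] if self.labels is not None else None
        return replace(
            self,
            counts=self.counts[mask_or_idx],
            cell_ids=self.cell_ids[mask_or_idx],
            labels=labels,
        )

    def subset_genes(self, mask_or_idx: np.ndarray) -> "CountMatrix":
        """Return a new matrix restricted to the given genes."""
        return replace(
            self,
            counts=self.counts[:, mask_or_idx],
            gene_names=self.gene_names[mask_or_idx],
        )

    def with_labels(self, labels: Sequence) -> "CountMatrix":
        return replace(self, labels=np.asarray(labels, dtype=object))

    def __eq__(self, other: object) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CountMatrix):
            return NotImplemented
        same = (
            np.array_equal(self.counts, other.counts)
            and np.array_equal(self.gene_names, other.gene_names)
            and np.array_equal(self.cell_ids, other.cell_ids)
        )
        if self.labels is None or other.labels is None:
            return same and (self.labels is None) == (other.labels is None)
        return same and np.array_equal(self.labels, other.labels)
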