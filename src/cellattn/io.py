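"""Readers and writers for the formats the pipeline touches.

Counts travel as MatrixMarket ``.mtx`` with ``genes.tsv`` /
``barcodes.tsv`` sidecars (stored genes x cells per the 10x convention
and transposed at this boundary; in memory everything is cells x
genes), or as a dense CSV with cells as rows and a gene-name header.
Labels are 2-column CSV (cell_id,label). Gene-set libraries use the
standard GMT layout (term, description, tab-separated genes). Model
checkpoints are a single ``.npz`` holding a JSON header (format
version + architecture + trainable flags) alongside the parameter
arrays; loading reproduces forward outputs bitwise.
"""

from __future__ import annotations

import json
import logging
import zipfile
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .containers import CountMatrix
from .model import ArchitectureConfig, ModelState, expected_shapes

__all__ = [
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "read_gmt",
    "write_gmt",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


def _read_tsv_column(path: Path) -> List[str]:
    # genes.tsv may carry one or two columns (id, symbol); use the last
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, -1].tolist()


def read_counts(
    path: str | Path,
    fmt: str = "mtx",
    genes: Optional[str | Path] = None,
    barcodes: Optional[str | Path] = None,
) -> CountMatrix:
    """Load counts from MatrixMarket + sidecars or a dense CSV.

    For ``fmt="mtx"``, ``path`` is either the ``.mtx`` file itself (the
    sidecars default to ``genes.tsv`` / ``barcodes.tsv`` next to it) or
    a directory holding ``matrix.mtx``, ``genes.tsv``, ``barcodes.tsv``.
    """
    path = Path(path)
    if fmt == "mtx":
        if path.is_dir():
            mtx, genes_p, barcodes_p = (
                path / "matrix.mtx",
                path / "genes.tsv",
                path / "barcodes.tsv",
            )
        else:
            mtx = path
            genes_p = Path(genes) if genes else path.parent / "genes.tsv"
            barcodes_p = Path(barcodes) if barcodes else path.parent / "barcodes.tsv"
        m = spio.mmread(mtx)  # genes x cells on disk
        counts = np.asarray(m.todense() if sparse.issparse(m) else m, dtype=np.float64).T
        gene_names = _read_tsv_column(genes_p)
        cell_ids = _read_tsv_column(barcodes_p)
        if counts.shape[1] != len(gene_names):
            raise ValueError(
                f"{mtx} has {counts.shape[1]} genes but {genes_p} lists "
                f"{len(gene_names)}"
            )
        if counts.shape[0] != len(cell_ids):
            raise ValueError(
                f"{mtx} has {counts.shape[0]} cells but {barcodes_p} lists "
                f"{len(cell_ids)}"
            )
        return CountMatrix(counts, np.array(gene_names, dtype=object), np.array(cell_ids, dtype=object))
    if fmt == "csv":
        # pandas mangles repeated column names (ACTB -> ACTB.1), so check
        # the raw header line before parsing.
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(",")[1:]
        seen: set = set()
        for name in header:
            if name in seen:
                raise ValueError(f"duplicate gene column in {path}: {name!r}")
            seen.add(name)
        df = pd.read_csv(path, index_col=0)
        return CountMatrix(
            df.to_numpy(dtype=np.float64),
            np.array(df.columns, dtype=object),
            np.array(df.index.astype(str), dtype=object),
        )
    raise ValueError(f"unknown counts format {fmt!r}")


def write_counts(mat: CountMatrix, path: str | Path, fmt: str = "mtx") -> None:
    """Write counts in the same layout :func:`read_counts` expects."""
    path = Path(path)
    if fmt == "mtx":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(
            path / "matrix.mtx",
            sparse.csr_matrix(mat.counts.T),  # genes x cells on disk
            field="integer" if np.allclose(mat.counts, np.round(mat.counts)) else "real",
        )
        pd.Series(list(mat.gene_names)).to_csv(
            path / "genes.tsv", sep="\t", header=False, index=False
        )
        pd.Series(list(mat.cell_ids)).to_csv(
            path / "barcodes.tsv", sep="\t", header=False, index=False
        )
        if mat.labels is not None:
            write_labels(mat, path / "labels.csv")
        return
    if fmt == "csv":
        pd.DataFrame(
            mat.counts, index=list(mat.cell_ids), columns=list(mat.gene_names)
        ).to_csv(path)
        return
    raise ValueError(f"unknown counts format {fmt!r}")


def read_labels(path: str | Path, mat: Optional[CountMatrix] = None) -> pd.Series:
    """2-column (cell_id,label) CSV -> Series indexed by cell id.

    When a matrix is supplied, the labels are re-ordered to its cells
    and an error names any cell without a label.
    """
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path} must have 2 columns (cell_id,label)")
    s = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    if mat is not None:
        missing = [c for c in mat.cell_ids if c not in s.index]
        if missing:
            raise ValueError(f"no label for cells: {missing[:5]}")
        s = s.loc[list(mat.cell_ids)]
    return s


def write_labels(mat: CountMatrix, path: str | Path) -> None:
    if mat.labels is None:
        raise ValueError("matrix has no labels")
    pd.DataFrame({"cell_id": list(mat.cell_ids), "label": list(mat.labels)}).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# GMT gene-set libraries
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> Dict[str, List[str]]:
    """Standard GMT: ``term<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a term are de-duplicated (order preserved)
    with a logged count; a line without at least one gene is an error
    naming the line number.
    """
    library: Dict[str, List[str]] = {}
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not parts[0]:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line (need term, "
                    "description, and at least one gene)"
                )
            term = parts[0]
            if term in library:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            genes: List[str] = []
            seen = set()
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    n_dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
            library[term] = genes
    if n_dup:
        logger.info("de-duplicated %d repeated genes within GMT terms", n_dup)
    if not library:
        raise ValueError(f"{path}: empty GMT file")
    return library


def write_gmt(library: Dict[str, Sequence[str]], path: str | Path, description: str = "") -> None:
    with open(path, "w") as fh:
        for term, genes in library.items():
            fh.write("\t".join([str(term), description, *map(str, genes)]) + "\n")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(state: ModelState, path: str | Path) -> None:
    header = {
        "format_version": CHECKPOINT_VERSION,
        "architecture": state.arch.to_dict(),
        "trainable": state.trainable,
        "gene_names": None
        if state.gene_names is None
        else [str(g) for g in state.gene_names],
    }
    arrays = {f"param:{k}": v for k, v in state.params.items()}
    np.savez(path, __header__=np.array(json.dumps(header)), **arrays)


def load_checkpoint(path: str | Path) -> ModelState:
    try:
        with np.load(path, allow_pickle=False) as data:
            if "__header__" not in data:
                raise ValueError(f"{path}: not a model checkpoint (missing header)")
            header = json.loads(str(data["__header__"]))
            version = header.get("format_version")
            if version != CHECKPOINT_VERSION:
                raise ValueError(
                    f"{path}: checkpoint format version {version} is not "
                    f"supported (expected {CHECKPOINT_VERSION})"
                )
            arch = ArchitectureConfig.from_dict(header["architecture"])
            params = {
                k[len("param:") :]: np.array(data[k])
                for k in data.files
                if k.startswith("param:")
            }
    except (zipfile.BadZipFile, OSError, EOFError) as e:
        raise ValueError(f"{path}: corrupt or truncated checkpoint ({e})") from e
    expected = expected_shapes(arch)
    if set(params) != set(expected):
        missing = sorted(set(expected) - set(params))
        extra = sorted(set(params) - set(expected))
        raise ValueError(
            f"{path}: parameters inconsistent with the architecture header "
            f"(missing {missing}, unexpected {extra})"
        )
    for k, shape in expected.items():
        if params[k].shape != shape:
            raise ValueError(
                f"{path}: parameter {k} has shape {params[k].shape}, "
                f"architecture implies {shape}"
            )
    genes = header.get("gene_names")
    return ModelState(
        arch=arch,
        params=params,
        trainable=dict(header["trainable"]),
        gene_names=None if genes is None else np.array(genes, dtype=object),
    )
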