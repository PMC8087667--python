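"""Count-matrix containers, file I/O, gene filtering and cell subsampling.

Counts are always held cells x genes in memory.  On disk, MatrixMarket files
default to the 10x convention of genes as rows and are transposed on load;
CSV/TSV files carry gene names in the header and cell ids in the first
column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "CountMatrix",
    "LabeledCells",
    "read_counts",
    "write_counts",
    "read_labels",
    "write_labels",
    "select_hvg",
    "train_test_split",
    "subsample_plates",
]


@dataclass(frozen=True)
class CountMatrix:
    """Integer cell x gene UMI count table with cell and gene identifiers."""

    counts: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise ValueError(f"non-integer count at cell {bad[0]}, gene {bad[1]}")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at cell {bad[0]}, gene {bad[1]}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "cell_ids", list(map(str, self.cell_ids)))
        object.__setattr__(self, "gene_ids", list(map(str, self.gene_ids)))
        if len(self.cell_ids) != counts.shape[0]:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids for {counts.shape[0]} rows"
            )
        if len(self.gene_ids) != counts.shape[1]:
            raise ValueError(
                f"{len(self.gene_ids)} gene ids for {counts.shape[1]} columns"
            )
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[idx], [self.cell_ids[i] for i in idx], self.gene_ids
        )

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[:, idx], self.cell_ids, [self.gene_ids[i] for i in idx]
        )


@dataclass(frozen=True)
class LabeledCells:
    """Cluster assignment for a set of cells; labels are 0..K-1, no gaps."""

    cell_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "cell_ids", list(map(str, self.cell_ids)))
        if len(self.cell_ids) != labels.shape[0]:
            raise ValueError("cell_ids and labels length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell ids")
        if labels.size:
            uniq = np.unique(labels)
            if uniq[0] != 0 or not np.array_equal(uniq, np.arange(len(uniq))):
                raise ValueError("labels must be contiguous 0-based integers")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def _mtx_sidecars(path: Path) -> tuple[Path, Path]:
    return path.with_name("barcodes.tsv"), path.with_name("genes.tsv")


def read_counts(path, format: str | None = None, cells_as_rows: bool = False) -> CountMatrix:
    """Read a count matrix from MTX (+ sidecars) or CSV/TSV.

    MTX defaults to genes as rows on disk (10x dialect) and is transposed;
    pass ``cells_as_rows=True`` if the file already stores cells as rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix, "csv")
    if format == "mtx":
        barcodes, genes = _mtx_sidecars(path)
        for side in (barcodes, genes):
            if not side.exists():
                raise ValueError(f"missing MTX sidecar file: {side}")
        mat = spio.mmread(path)
        cell_ids = barcodes.read_text().split()
        gene_ids = genes.read_text().split()
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
        if not cells_as_rows:
            dense = dense.T
        if dense.shape != (len(cell_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {dense.shape} does not match sidecars "
                f"({len(cell_ids)} barcodes, {len(gene_ids)} genes)"
            )
        return CountMatrix(dense, cell_ids, gene_ids)
    if format in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        return CountMatrix(df.to_numpy(), [str(i) for i in df.index], [str(c) for c in df.columns])
    raise ValueError(f"unknown format {format!r}")


def write_counts(cm: CountMatrix, path, format: str | None = None, cells_as_rows: bool = False) -> None:
    """Write ``cm`` so that :func:`read_counts` restores it bit-identically."""
    path = Path(path)
    if format is None:
        format = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix, "csv")
    try:
        if format == "mtx":
            mat = sparse.coo_matrix(cm.counts if cells_as_rows else cm.counts.T)
            spio.mmwrite(str(path), mat, field="integer")
            barcodes, genes = _mtx_sidecars(path)
            barcodes.write_text("\n".join(cm.cell_ids) + ("\n" if cm.cell_ids else ""))
            genes.write_text("\n".join(cm.gene_ids) + ("\n" if cm.gene_ids else ""))
        elif format in ("csv", "tsv"):
            df = pd.DataFrame(cm.counts, index=cm.cell_ids, columns=cm.gene_ids)
            df.to_csv(path, sep="," if format == "csv" else "\t")
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as err:
        raise OSError(f"failed writing counts to {path}: {err}") from err


def read_labels(path) -> LabeledCells:
    """Read a two-column TSV (cell_id, integer label)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "label"])
    return LabeledCells([str(c) for c in df["cell_id"]], df["label"].to_numpy())


def write_labels(lc: LabeledCells, path) -> None:
    pd.DataFrame({"cell_id": lc.cell_ids, "label": lc.labels}).to_csv(
        path, sep="\t", header=False, index=False
    )


def select_hvg(cm: CountMatrix, n_genes: int) -> CountMatrix:
    """Keep the ``n_genes`` most variable genes.

    Variance is computed on log1p counts after scaling each cell to the
    median library size; the original gene order is preserved among the
    selected genes.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if n_genes > cm.n_genes:
        raise ValueError(f"n_genes={n_genes} exceeds {cm.n_genes} genes")
    lib = cm.counts.sum(axis=1).astype(float)
    lib[lib == 0] = 1.0
    scaled = cm.counts / lib[:, None] * np.median(lib)
    var = np.log1p(scaled).var(axis=0)
    # stable partial sort: ties resolved toward earlier genes
    order = np.argsort(-var, kind="stable")[:n_genes]
    return cm.subset_genes(np.sort(order))


def train_test_split(cm: CountMatrix, train_frac: float = 0.7, seed: int = 0):
    """Random disjoint cell partition; |train| = round(train_frac * n)."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie in (0, 1)")
    if cm.n_cells < 2:
        raise ValueError("need at least 2 cells to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cm.n_cells)
    n_train = int(round(train_frac * cm.n_cells))
    return cm.subset_cells(np.sort(perm[:n_train])), cm.subset_cells(np.sort(perm[n_train:]))


def subsample_plates(cm: CountMatrix, n_plates: int, plate_size: int = 384, seed: int = 0) -> CountMatrix:
    """Uniform without-replacement sample of ``n_plates * plate_size`` cells."""
    if n_plates <= 0:
        raise ValueError("n_plates must be positive")
    n_req = n_plates * plate_size
    if n_req > cm.n_cells:
        raise ValueError(
            f"requested {n_req} cells but only {cm.n_cells} available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(cm.n_cells, size=n_req, replace=False)
    return cm.subset_cells(np.sort(idx))
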