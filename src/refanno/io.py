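"""Input/output and core data containers.

All expression matrices are gene-major: rows are genes, columns are cells
(or cell types for aggregated profiles).  Supported on-disk encodings are
MatrixMarket triplets with ``genes.tsv``/``barcodes.tsv`` sidecars, dense
TSV/CSV tables with gene rows, and the AnnData HDF5 container (``.h5ad``,
which stores cells x genes and is transposed on load).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "CellAnnotation",
    "ProfileMatrix",
    "OrthologMap",
    "AnnotationResult",
    "FormatError",
    "ValidationError",
    "read_count_matrix",
    "read_annotation",
    "map_orthologs",
    "write_annotation",
]


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared format."""


class ValidationError(ValueError):
    """Raised when parsed data violates a container invariant."""


def _collapse_duplicate_genes(genes, counts):
    """Sum rows sharing a gene symbol; keep first-occurrence order."""
    genes = [g.strip() for g in genes]
    if len(set(genes)) == len(genes):
        return list(genes), counts
    order: dict[str, int] = {}
    for g in genes:
        if g not in order:
            order[g] = len(order)
    idx = np.array([order[g] for g in genes])
    n_unique = len(order)
    if sp.issparse(counts):
        indicator = sp.csr_matrix(
            (np.ones(len(genes)), (idx, np.arange(len(genes)))),
            shape=(n_unique, len(genes)),
        )
        collapsed = indicator @ counts
    else:
        collapsed = np.zeros((n_unique, counts.shape[1]), dtype=counts.dtype)
        np.add.at(collapsed, idx, counts)
    return list(order), collapsed


@dataclass
class CountMatrix:
    """Integer gene-by-cell expression counts.

    Attributes
    ----------
    genes : list of str
        Unique gene symbols (row labels).
    cells : list of str
        Cell barcodes (column labels).
    counts : ndarray or sparse matrix, genes x cells
        Non-negative integer counts.
    """

    genes: list[str]
    cells: list[str]
    counts: object  # ndarray or scipy sparse, genes x cells

    def __post_init__(self):
        if len(self.genes) == 0 or len(self.cells) == 0:
            raise ValidationError("count matrix has an empty dimension")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("gene symbols not unique")
        if self.shape != (len(self.genes), len(self.cells)):
            raise ValidationError(
                f"counts shape {self.shape} does not match labels "
                f"({len(self.genes)} genes, {len(self.cells)} cells)"
            )
        self._validate_entries()

    def _validate_entries(self):
        data = self.counts.data if sp.issparse(self.counts) else self.counts
        data = np.asarray(data)
        bad = (data < 0) | (data != np.floor(data))
        if bad.any():
            if sp.issparse(self.counts):
                coo = self.counts.tocoo()
                mask = (coo.data < 0) | (coo.data != np.floor(coo.data))
                where = list(zip(coo.row[mask][:5], coo.col[mask][:5]))
            else:
                rows, cols = np.nonzero(bad)
                where = list(zip(rows[:5], cols[:5]))
            raise ValidationError(
                f"negative or non-integer counts at (gene, cell) coordinates {where}"
            )

    @property
    def shape(self):
        return self.counts.shape

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense())
        return np.asarray(self.counts)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def cell_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.cells)}

    def subset_cells(self, barcodes) -> "CountMatrix":
        ci = self.cell_index()
        cols = [ci[b] for b in barcodes]
        return CountMatrix(list(self.genes), list(barcodes), self.counts[:, cols])

    def subset_genes(self, genes) -> "CountMatrix":
        gi = self.gene_index()
        rows = [gi[g] for g in genes]
        return CountMatrix(list(genes), list(self.cells), self.counts[rows, :])

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes == other.genes
            and self.cells == other.cells
            and np.array_equal(self.dense(), other.dense())
        )


@dataclass
class CellAnnotation:
    """Per-cell cell-type labels (barcode -> label)."""

    labels: dict[str, str]

    def __post_init__(self):
        if not self.labels:
            raise ValidationError("annotation is empty")
        for b, l in self.labels.items():
            if not str(l).strip():
                raise ValidationError(f"empty label for barcode {b!r}")

    @property
    def barcodes(self) -> list[str]:
        return list(self.labels)

    @property
    def label_set(self) -> list[str]:
        return sorted(set(self.labels.values()))

    def vector(self, barcodes) -> np.ndarray:
        return np.array([self.labels[b] for b in barcodes])


@dataclass
class ProfileMatrix:
    """Gene-by-cell-type aggregated expression profiles.

    ``depth`` holds per-column aggregate library sizes (column sums by
    construction when aggregating counts).
    """

    genes: list[str]
    cell_types: list[str]
    values: np.ndarray
    depth: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.cell_types)) != len(self.cell_types):
            raise ValidationError("cell-type names not unique")
        if self.values.shape != (len(self.genes), len(self.cell_types)):
            raise ValidationError("profile shape does not match labels")
        if (self.values < 0).any():
            raise ValidationError("profile values must be non-negative")
        if self.depth is None:
            self.depth = self.values.sum(axis=0)
        self.depth = np.asarray(self.depth, dtype=float)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def column(self, cell_type: str) -> np.ndarray:
        return self.values[:, self.cell_types.index(cell_type)]

    def subset_genes(self, genes) -> "ProfileMatrix":
        gi = self.gene_index()
        rows = [gi[g] for g in genes]
        return ProfileMatrix(
            list(genes), list(self.cell_types), self.values[rows, :], self.depth
        )


@dataclass
class OrthologMap:
    """Partial source-gene -> target-gene mapping for cross-species runs."""

    mapping: dict[str, str]

    def __post_init__(self):
        if not self.mapping:
            raise ValidationError("ortholog map is empty")

    @classmethod
    def from_table(cls, path: str, sep: str = "\t") -> "OrthologMap":
        df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise FormatError("ortholog table needs two columns")
        return cls(dict(zip(df.iloc[:, 0].str.strip(), df.iloc[:, 1].str.strip())))


@dataclass
class AnnotationResult:
    """Final annotation with per-stage provenance, one row per query cell."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: barcode, final_label, round1_candidate, confidence_score,
    #          validated, recaptured  (+ merged_cell_id when speed-up used)

    REQUIRED = [
        "barcode",
        "final_label",
        "round1_candidate",
        "confidence_score",
        "validated",
        "recaptured",
    ]

    def __post_init__(self):
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValidationError(f"annotation result missing column {col!r}")
        if self.table["barcode"].duplicated().any():
            raise ValidationError("duplicate barcodes in annotation result")

    def labels(self) -> dict[str, str]:
        return dict(zip(self.table["barcode"], self.table["final_label"]))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_dense_table(path: str) -> tuple[list, list, np.ndarray]:
    sep = "," if os.path.splitext(path)[1].lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse dense table {path}: {exc}") from exc
    return [str(g) for g in df.index], [str(c) for c in df.columns], df.to_numpy()


def _read_mtx_triplet(path: str) -> tuple[list, list, object]:
    """Read MatrixMarket ``matrix.mtx`` with genes.tsv/barcodes.tsv sidecars.

    ``path`` may be the directory or the .mtx file itself.
    """
    if os.path.isdir(path):
        base = path
        mtx = os.path.join(base, "matrix.mtx")
    else:
        base = os.path.dirname(path)
        mtx = path
    try:
        mat = scipy.io.mmread(mtx).tocsr()
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse MatrixMarket file {mtx}: {exc}") from exc
    genes = pd.read_csv(os.path.join(base, "genes.tsv"), sep="\t", header=None)
    barcodes = pd.read_csv(os.path.join(base, "barcodes.tsv"), sep="\t", header=None)
    return (
        [str(g) for g in genes.iloc[:, 0]],
        [str(b) for b in barcodes.iloc[:, 0]],
        mat,
    )


def _read_h5ad(path: str) -> tuple[list, list, object]:
    import anndata

    try:
        adata = anndata.read_h5ad(path)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"cannot parse h5ad container {path}: {exc}") from exc
    x = adata.X
    counts = x.T.tocsr() if sp.issparse(x) else np.asarray(x).T
    return list(map(str, adata.var_names)), list(map(str, adata.obs_names)), counts


_READERS = {
    "mtx-triplet": _read_mtx_triplet,
    "dense-table": _read_dense_table,
    "hdf5-container": _read_h5ad,
}


def infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if os.path.isdir(path) or ext == ".mtx":
        return "mtx-triplet"
    if ext in {".h5ad", ".h5", ".hdf5"}:
        return "hdf5-container"
    return "dense-table"


def read_count_matrix(path: str, format: str | None = None) -> CountMatrix:
    """Load a gene-by-cell count matrix.

    Duplicate gene rows are collapsed by summation; genes with zero total
    counts are retained.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    fmt = format or infer_format(path)
    if fmt not in _READERS:
        raise FormatError(f"unknown format {fmt!r}")
    genes, cells, counts = _READERS[fmt](path)
    genes, counts = _collapse_duplicate_genes(genes, counts)
    return CountMatrix(genes, cells, counts)


def read_annotation(path: str, sep: str = "\t") -> CellAnnotation:
    """Read a two-column (barcode, label) table; header row optional."""
    df = pd.read_csv(path, sep=sep, header=None, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("annotation table needs two columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"barcode", "cell", "cell_id", "barcodes"}:
        df = df.iloc[1:]
    labels: dict[str, str] = {}
    for b, l in zip(df.iloc[:, 0], df.iloc[:, 1]):
        b, l = str(b).strip(), str(l).strip()
        if not l:
            raise ValidationError(f"empty label for barcode {b!r}")
        if b in labels and labels[b] != l:
            raise ValidationError(
                f"conflicting labels for barcode {b!r}: {labels[b]!r} vs {l!r}"
            )
        labels[b] = l
    return CellAnnotation(labels)


def map_orthologs(counts: CountMatrix, omap: OrthologMap) -> tuple[CountMatrix, float]:
    """Rename genes via an ortholog table.

    Unmapped source genes are dropped; many-to-one targets are collapsed by
    summation.  Returns the mapped matrix and the fraction of genes retained.
    """
    kept_rows = [i for i, g in enumerate(counts.genes) if g in omap.mapping]
    if not kept_rows:
        raise ValidationError("no gene in the matrix is covered by the ortholog map")
    targets = [omap.mapping[counts.genes[i]] for i in kept_rows]
    sub = counts.counts[kept_rows, :]
    genes, collapsed = _collapse_duplicate_genes(targets, sub)
    frac = len(kept_rows) / len(counts.genes)
    return CountMatrix(genes, list(counts.cells), collapsed), frac


def write_annotation(result: AnnotationResult, path: str, sep: str = "\t") -> None:
    """Write the annotation result as a delimited table with a header row."""
    cols = [c for c in result.table.columns]
    ordered = AnnotationResult.REQUIRED + [
        c for c in cols if c not in AnnotationResult.REQUIRED
    ]
    try:
        result.table[ordered].to_csv(path, sep=sep, index=False)
    except OSError as exc:
        raise OSError(f"cannot write annotation to {path}: {exc}") from exc
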