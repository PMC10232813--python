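"""Count-matrix and cell-metadata containers plus 10x-style disk formats.

Everything downstream consumes the two in-memory types defined here:

* :class:`CountMatrix` — genes x cells raw UMI counts (sparse CSR) with unique
  gene symbols and cell barcodes.  Genes are rows and cells are columns,
  matching 10x Genomics output orientation.
* a *cell table* — a :class:`pandas.DataFrame` with one row per barcode holding
  condition labels, QC statistics, cluster/phase assignments, per-cell scores
  and (for simulated data) ground-truth annotations.

On disk a :class:`CountMatrix` is the classic 10x triplet: ``matrix.mtx`` in
Matrix Market coordinate format (1-based indices) next to ``features.tsv`` and
``barcodes.tsv``.  Cell tables are plain TSV with a header row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CONDITIONS",
    "CountMatrix",
    "FormatError",
    "read_mtx",
    "write_mtx",
    "read_cell_table",
    "write_cell_table",
    "validate_cell_table",
]

#: The experimental arms: vehicle control, immune-stimulatory dsDNA alone,
#: dsDNA with an IFNAR-neutralizing antibody (secondary amplification blocked),
#: and dsDNA in IFNAR-knockout cells.
CONDITIONS = ("control", "dsDNA", "dsDNA_IFNARAb", "dsDNA_IFNARKO")

#: Cell-table columns always present after validation.
REQUIRED_CELL_COLUMNS = ("barcode", "condition")


class FormatError(ValueError):
    """Raised when an on-disk file or in-memory container violates the format."""


@dataclass
class CountMatrix:
    """Raw UMI counts, genes x cells.

    Parameters
    ----------
    counts
        Non-negative integer matrix, shape ``(n_genes, n_cells)``.  Stored as
        CSR; dense input is converted.
    gene_names
        Unique gene symbols, one per row.
    barcodes
        Unique cell barcodes, one per column.
    """

    counts: sp.csr_matrix
    gene_names: list[str] = field(default_factory=list)
    barcodes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.gene_names = [str(g) for g in self.gene_names]
        self.barcodes = [str(b) for b in self.barcodes]
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_names) != n_genes:
            raise FormatError(
                f"gene_names length {len(self.gene_names)} != {n_genes} rows"
            )
        if len(self.barcodes) != n_cells:
            raise FormatError(
                f"barcodes length {len(self.barcodes)} != {n_cells} columns"
            )
        dup = _duplicates(self.gene_names)
        if dup:
            raise FormatError(f"duplicate gene symbols: {sorted(dup)}")
        dup = _duplicates(self.barcodes)
        if dup:
            raise FormatError(f"duplicate barcodes: {sorted(dup)}")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("negative counts")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer counts")
        self.counts.data = np.asarray(np.round(data), dtype=np.int64)

    # -- conveniences -----------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_names)}

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return CountMatrix(
            self.counts[:, idx],
            self.gene_names,
            [self.barcodes[i] for i in idx],
        )

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense(), dtype=np.int64)


def _duplicates(items) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# Matrix Market triplet I/O
# ---------------------------------------------------------------------------

def read_mtx(matrix_path, features_path, barcodes_path) -> CountMatrix:
    """Read a 10x-style triplet (``matrix.mtx`` + features + barcodes).

    The features file may be 1-column (symbol only) or 3-column
    (id, symbol, type); symbols are taken from the second column when present
    and are the join key everywhere in the package.
    """
    matrix_path, features_path, barcodes_path = (
        Path(matrix_path), Path(features_path), Path(barcodes_path))
    for p in (matrix_path, features_path, barcodes_path):
        if not p.exists():
            raise FileNotFoundError(p)
    try:
        m = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # pragma: no cover - scipy message passthrough
        raise FormatError(f"invalid MTX file {matrix_path}: {exc}") from exc
    feats = pd.read_csv(features_path, sep="\t", header=None, dtype=str)
    symbols = feats.iloc[:, 1] if feats.shape[1] >= 2 else feats.iloc[:, 0]
    symbols = symbols.tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    barcodes = barcodes.iloc[:, 0].tolist()
    if m.shape[0] != len(symbols):
        raise FormatError(
            f"MTX rows {m.shape[0]} != features lines {len(symbols)}")
    if m.shape[1] != len(barcodes):
        raise FormatError(
            f"MTX columns {m.shape[1]} != barcodes lines {len(barcodes)}")
    dense_data = m.tocoo().data
    if dense_data.size and not np.allclose(dense_data, np.round(dense_data)):
        raise FormatError("MTX contains non-integer entries")
    return CountMatrix(sp.csr_matrix(m), symbols, barcodes)


def write_mtx(cm: CountMatrix, out_dir) -> dict[str, Path]:
    """Write the 10x triplet; returns the three paths.

    The coordinate file is emitted with 1-based indices in column-major sorted
    order so output is bit-stable for a fixed matrix.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    coo = cm.counts.tocoo()
    order = np.lexsort((coo.row, coo.col))  # column-major
    rows, cols, data = coo.row[order], coo.col[order], coo.data[order]
    with open(paths["matrix"], "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"{cm.n_genes} {cm.n_cells} {len(data)}\n")
        for r, c, v in zip(rows, cols, data):
            fh.write(f"{r + 1} {c + 1} {int(v)}\n")
    with open(paths["features"], "w") as fh:
        for g in cm.gene_names:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(paths["barcodes"], "w") as fh:
        fh.write("".join(b + "\n" for b in cm.barcodes))
    return paths


# ---------------------------------------------------------------------------
# Cell table I/O
# ---------------------------------------------------------------------------

_NUMERIC_COLS = ("n_genes_detected", "total_counts", "pct_mito",
                 "isg_score", "direct_score")


def validate_cell_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate required columns, the condition enum and value ranges."""
    for col in REQUIRED_CELL_COLUMNS:
        if col not in table.columns:
            raise FormatError(f"cell table missing required column '{col}'")
    bad = set(table["condition"].astype(str)) - set(CONDITIONS)
    if bad:
        raise FormatError(
            f"unknown condition label(s) {sorted(bad)!r}; "
            f"expected one of {CONDITIONS}")
    if "pct_mito" in table.columns:
        pm = pd.to_numeric(table["pct_mito"], errors="coerce")
        if ((pm < 0) | (pm > 100)).any():
            raise FormatError("pct_mito outside [0, 100]")
    for col in ("isg_score", "direct_score"):
        if col in table.columns:
            v = pd.to_numeric(table[col], errors="coerce").dropna()
            if len(v) and ((v < 0) | (v > 10_000)).any():
                raise FormatError(f"{col} outside [0, 10000]")
    if table["barcode"].duplicated().any():
        raise FormatError("duplicate barcodes in cell table")
    return table


def read_cell_table(path) -> pd.DataFrame:
    """Read a TSV cell table; condition labels are validated strictly.

    No whitespace trimming is applied: a label like ``"dsDNA "`` is rejected
    rather than silently repaired, so provenance errors surface early.
    """
    table = pd.read_csv(path, sep="\t", dtype={"barcode": str,
                                               "condition": str},
                        keep_default_na=True)
    for col in _NUMERIC_COLS:
        if col in table.columns:
            table[col] = pd.to_numeric(table[col])
    return validate_cell_table(table)


def write_cell_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    validate_cell_table(pd.DataFrame(table))
    table.to_csv(path, sep="\t", index=False)
    return path


@dataclass
class Dataset:
    """A count matrix paired with its cell table (rows aligned to columns)."""

    counts: CountMatrix
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.cells) != self.counts.n_cells:
            raise FormatError(
                f"cell table rows {len(self.cells)} != matrix columns "
                f"{self.counts.n_cells}")
        if list(self.cells["barcode"]) != list(self.counts.barcodes):
            raise FormatError("cell table barcodes do not match matrix columns")

    @property
    def condition(self) -> str:
        conds = self.cells["condition"].unique()
        if len(conds) != 1:
            warnings.warn("dataset mixes conditions")
        return str(conds[0])

    def subset(self, mask_or_idx) -> "Dataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return Dataset(self.counts.subset_cells(idx),
                       self.cells.iloc[idx].reset_index(drop=True))
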