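"""Readers, writers and validated containers for the formats the pipeline touches.

The containers here are deliberately thin: a spatial slide is a validated
:class:`pandas.DataFrame` plus a declared cell-type universe; genomic peaks
and TSS records are small frozen dataclasses in standard 0-based half-open
BED coordinates; an expression matrix is a named sparse matrix read from
MatrixMarket triplets with feature/barcode lists. All readers validate
eagerly and raise :class:`FormatError` rather than silently coercing
malformed rows.
"""

from __future__ import annotations

import dataclasses
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from ._exceptions import FormatError, ValidationError

__all__ = [
    "SpatialSlide",
    "GenomicInterval",
    "TssRecord",
    "DegTable",
    "NamedMatrix",
    "read_cell_table",
    "write_cell_table",
    "read_sparse_matrix",
    "write_sparse_matrix",
    "read_bed_intervals",
    "write_bed_intervals",
    "read_tss_bed",
    "write_tss_bed",
    "read_deg_table",
    "write_deg_table",
]

#: Columns every cell table must provide.
REQUIRED_CELL_COLUMNS = ("cell_id", "x", "y", "cell_type")


@dataclass
class SpatialSlide:
    """A spatial slide: one row per cell with coordinates and a type label.

    Parameters
    ----------
    cells
        DataFrame with at least ``cell_id``, ``x``, ``y`` and ``cell_type``
        columns. Any additional numeric columns are treated as per-cell
        expression values; an optional boolean ``positive`` column flags
        marker-positive cells.
    type_universe
        The declared set of admissible cell-type labels. Defaults to the
        labels observed in ``cells``.
    """

    cells: pd.DataFrame
    type_universe: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        df = self.cells
        for col in REQUIRED_CELL_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"cell table lacks required column {col!r}")
        dup = df["cell_id"].loc[df["cell_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate cell_id {dup.iloc[0]!r}")
        xy = df[["x", "y"]].to_numpy(dtype=float)
        if not np.all(np.isfinite(xy)):
            bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
            raise ValidationError(f"non-finite coordinate at row {bad}")
        labels = df["cell_type"].astype(str)
        if not self.type_universe:
            self.type_universe = tuple(sorted(labels.unique()))
        else:
            self.type_universe = tuple(self.type_universe)
            unknown = set(labels.unique()) - set(self.type_universe)
            if unknown:
                raise ValidationError(
                    f"cell_type {sorted(unknown)[0]!r} outside the declared type universe"
                )
        self.cells = df.reset_index(drop=True)

    # ---- convenience accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def coords(self) -> np.ndarray:
        """(n_cells, 2) float array of x/y coordinates."""
        return self.cells[["x", "y"]].to_numpy(dtype=float)

    @property
    def cell_types(self) -> np.ndarray:
        return self.cells["cell_type"].astype(str).to_numpy()

    def type_codes(self) -> np.ndarray:
        """Integer label codes aligned with :attr:`type_universe`."""
        mapping = {t: i for i, t in enumerate(self.type_universe)}
        return np.array([mapping[t] for t in self.cell_types], dtype=np.intp)

    @property
    def positive_indices(self) -> np.ndarray | None:
        """Indices flagged positive, or None when the slide carries no flag."""
        if "positive" not in self.cells.columns:
            return None
        flags = self.cells["positive"].astype(bool).to_numpy()
        return np.flatnonzero(flags)

    def expression(self, column: str) -> np.ndarray:
        if column not in self.cells.columns:
            raise ValidationError(f"expression column {column!r} not present")
        return self.cells[column].to_numpy(dtype=float)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval carrying a score (log fold change)."""

    chrom: str
    start: int
    end: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )


@dataclass(frozen=True)
class TssRecord:
    """A strand-aware single-base transcription start site (0-based)."""

    chrom: str
    tss: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValidationError(f"negative TSS position for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r} for {self.gene_id}")


class DegTable:
    """A differential-expression table: gene_id, logFC, p-value and FDR."""

    COLUMNS = ("gene_id", "logFC", "pvalue", "fdr")

    def __init__(self, frame: pd.DataFrame):
        for col in self.COLUMNS:
            if col not in frame.columns:
                raise ValidationError(f"DEG table lacks required column {col!r}")
        dup = frame["gene_id"].loc[frame["gene_id"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene_id {dup.iloc[0]!r} in DEG table")
        for col in ("pvalue", "fdr"):
            vals = frame[col].to_numpy(dtype=float)
            if np.any(~np.isfinite(vals)) or np.any(vals <= 0) or np.any(vals > 1):
                raise ValidationError(f"{col} values must lie in (0, 1]")
        self.frame = frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class NamedMatrix:
    """A (features x barcodes) sparse matrix with named axes."""

    matrix: scipy.sparse.csr_matrix
    features: list[str]
    barcodes: list[str]

    def lookup(self, feature: str, barcode: str) -> float:
        i = self.features.index(feature)
        j = self.barcodes.index(barcode)
        return float(self.matrix[i, j])

    def to_dense(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix.toarray(), index=self.features, columns=self.barcodes
        )


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------

def read_cell_table(
    path: str | Path,
    required_columns: Sequence[str] = REQUIRED_CELL_COLUMNS,
    type_universe: Sequence[str] | None = None,
) -> SpatialSlide:
    """Read a TSV/CSV cell table into a validated :class:`SpatialSlide`.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    otherwise tab). Missing required columns, duplicate cell ids and
    non-numeric coordinates raise :class:`FormatError` naming the offender.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str}, float_precision="round_trip")
    for col in required_columns:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    dup = df["cell_id"].loc[df["cell_id"].duplicated()]
    if len(dup):
        raise FormatError(f"{path.name}: duplicate cell_id {dup.iloc[0]!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int((coerced.isna()).idxmax())
            raise FormatError(f"{path.name}: non-numeric coordinate {col!r} at row {row}")
        df[col] = coerced
    if "positive" in df.columns:
        df["positive"] = df["positive"].astype(bool)
    try:
        return SpatialSlide(df, tuple(type_universe) if type_universe else ())
    except ValidationError as exc:  # surface as a file-format problem
        raise FormatError(f"{path.name}: {exc}") from exc


def write_cell_table(slide: SpatialSlide, path: str | Path) -> None:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    slide.cells.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# MatrixMarket expression matrices
# ---------------------------------------------------------------------------

def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def read_sparse_matrix(
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> NamedMatrix:
    """Read a MatrixMarket coordinate matrix with feature/barcode lists."""
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot parse MatrixMarket file {matrix_path}: {exc}") from exc
    features = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)
    mat = scipy.sparse.csr_matrix(mat)
    if mat.shape != (len(features), len(barcodes)):
        raise FormatError(
            f"matrix shape {mat.shape} does not match {len(features)} features x "
            f"{len(barcodes)} barcodes"
        )
    return NamedMatrix(mat, features, barcodes)


def write_sparse_matrix(
    named: NamedMatrix,
    matrix_path: str | Path,
    features_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    # mmwrite appends .mtx when missing; write through a buffer to keep the
    # exact path the caller asked for.
    buf = _io.BytesIO()
    scipy.io.mmwrite(buf, scipy.sparse.coo_matrix(named.matrix))
    Path(matrix_path).write_bytes(buf.getvalue())
    Path(features_path).write_text("".join(f"{f}\n" for f in named.features))
    Path(barcodes_path).write_text("".join(f"{b}\n" for b in named.barcodes))


# ---------------------------------------------------------------------------
# BED intervals and TSS records
# ---------------------------------------------------------------------------

def read_bed_intervals(path: str | Path, score_column: int = 4) -> list[GenomicInterval]:
    """Read BED3+ peak intervals; ``score_column`` is the 0-based column index
    holding the per-peak score (log fold change), defaulting to BED column 5.
    Peaks without that column get score 0.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise FormatError(
                    f"{path}: line {lineno}: invalid interval {start}-{end}"
                )
            score = 0.0
            if len(fields) > score_column:
                try:
                    score = float(fields[score_column])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: non-numeric score column"
                    ) from exc
            name = fields[3] if len(fields) > 3 else "."
            out.append(GenomicInterval(chrom, start, end, score, name))
    return out


def write_bed_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\n")


def read_tss_bed(path: str | Path) -> list[TssRecord]:
    """Read gene intervals from BED6 and derive strand-aware TSS points.

    Plus-strand genes start transcription at ``start``; minus-strand genes at
    ``end - 1`` (the last covered base of the half-open interval) — the
    standard genome-browser convention.
    """
    out: list[TssRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: BED6 requires 6 columns")
            chrom, name, strand = fields[0], fields[3], fields[5]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                raise FormatError(f"{path}: line {lineno}: invalid interval {start}-{end}")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}: line {lineno}: invalid strand {strand!r}")
            tss = start if strand == "+" else end - 1
            out.append(TssRecord(chrom, tss, strand, name))
    return out


def write_tss_bed(records: Sequence[TssRecord], path: str | Path) -> None:
    """Write TSS records as single-base BED6 intervals (round-trip inverse of
    :func:`read_tss_bed` for 1-bp features)."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.chrom}\t{r.tss}\t{r.tss + 1}\t{r.gene_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# DEG tables
# ---------------------------------------------------------------------------

def read_deg_table(path: str | Path) -> DegTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str}, float_precision="round_trip")
    try:
        return DegTable(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_deg_table(table: DegTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)
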