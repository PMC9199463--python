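"""Readers and writers for the formats the pipeline touches.

Count matrices travel as Matrix Market coordinate bundles (matrix.mtx +
features.tsv + barcodes.tsv, the droplet convention: genes as rows, 1-based
indices on disk). Gene sets arrive as GMT. All result tables leave as TSV
with fixed column order and deterministic row order so runs are diffable.

Malformed input raises :class:`FormatError` naming the offending file and,
where meaningful, the line — readers never silently coerce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger("perimark")

MTX_HEADER = "%%MatrixMarket matrix coordinate integer general"

__all__ = [
    "CountMatrix",
    "GeneSetCollection",
    "FormatError",
    "read_mtx_bundle",
    "write_mtx_bundle",
    "read_gmt",
    "write_marker_table",
    "write_gate_summary",
    "write_gsea_table",
    "write_venn_table",
]


class FormatError(ValueError):
    """Malformed input file; message names the file and line."""


@dataclass
class CountMatrix:
    """Sparse nonnegative-integer gene x cell count matrix.

    ``values`` is genes-by-cells CSR; ``gene_ids`` and ``barcodes`` are the
    unique row/column labels; ``tissue`` tags the bundle's origin.
    """

    values: sparse.csr_matrix
    gene_ids: list[str]
    barcodes: list[str]
    tissue: str = ""

    def __post_init__(self) -> None:
        self.values = sparse.csr_matrix(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.barcodes)} barcodes"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene IDs are not unique")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes are not unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(self.values.dtype, np.integer):
            data = self.values.data
            if data.size and np.any(data != np.round(data)):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(sorted(self.sets))

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


# ---------------------------------------------------------------------------
# Matrix Market bundles
# ---------------------------------------------------------------------------

def _read_id_column(path: Path) -> list[str]:
    """First tab-separated column of a features/barcodes TSV."""
    ids: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                raise FormatError(f"{path}:{lineno}: empty line")
            ids.append(line.split("\t")[0])
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate IDs")
    return ids


def read_mtx_bundle(directory: str | Path, tissue: str = "") -> CountMatrix:
    """Read a matrix.mtx + features.tsv + barcodes.tsv bundle.

    File indices are 1-based and mapped to 0-based internally; genes are
    rows. Header/dimension mismatches, non-integer values and duplicate IDs
    raise :class:`FormatError` naming the file and line.
    """
    directory = Path(directory)
    mtx = directory / "matrix.mtx"
    for required in (mtx, directory / "features.tsv", directory / "barcodes.tsv"):
        if not required.exists():
            raise FormatError(f"{required}: missing from bundle")

    gene_ids = _read_id_column(directory / "features.tsv")
    barcodes = _read_id_column(directory / "barcodes.tsv")

    with open(mtx) as fh:
        header = fh.readline().rstrip("\n")
        if header.strip() != MTX_HEADER:
            raise FormatError(f"{mtx}:1: expected header {MTX_HEADER!r}, got {header!r}")
        lineno = 1
        size_line = None
        for line in fh:
            lineno += 1
            if line.startswith("%"):
                continue
            size_line = line
            break
        if size_line is None:
            raise FormatError(f"{mtx}: missing size line")
        parts = size_line.split()
        if len(parts) != 3:
            raise FormatError(f"{mtx}:{lineno}: size line needs 3 fields")
        try:
            n_rows, n_cols, nnz = (int(p) for p in parts)
        except ValueError:
            raise FormatError(f"{mtx}:{lineno}: non-integer size line") from None
        if n_rows != len(gene_ids):
            raise FormatError(
                f"{mtx}:{lineno}: declares {n_rows} rows but features.tsv "
                f"has {len(gene_ids)} lines"
            )
        if n_cols != len(barcodes):
            raise FormatError(
                f"{mtx}:{lineno}: declares {n_cols} columns but barcodes.tsv "
                f"has {len(barcodes)} lines"
            )
        rows = np.empty(nnz, dtype=np.int64)
        cols = np.empty(nnz, dtype=np.int64)
        vals = np.empty(nnz, dtype=np.int64)
        k = 0
        for line in fh:
            lineno += 1
            if not line.strip():
                continue
            if k >= nnz:
                raise FormatError(f"{mtx}:{lineno}: more entries than declared nnz={nnz}")
            parts = line.split()
            if len(parts) != 3:
                raise FormatError(f"{mtx}:{lineno}: entry needs 3 fields")
            try:
                i, j, v = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"{mtx}:{lineno}: non-integer entry {line.strip()!r}") from None
            if not (1 <= i <= n_rows and 1 <= j <= n_cols):
                raise FormatError(f"{mtx}:{lineno}: index ({i},{j}) out of range")
            if v < 0:
                raise FormatError(f"{mtx}:{lineno}: negative count {v}")
            rows[k], cols[k], vals[k] = i - 1, j - 1, v
            k += 1
        if k != nnz:
            raise FormatError(f"{mtx}: declared nnz={nnz} but found {k} entries")

    values = sparse.coo_matrix(
        (vals, (rows, cols)), shape=(n_rows, n_cols), dtype=np.int64
    ).tocsr()
    return CountMatrix(values, gene_ids, barcodes, tissue=tissue)


def write_mtx_bundle(counts: CountMatrix, directory: str | Path) -> None:
    """Write a bundle readable by :func:`read_mtx_bundle`.

    Coordinate entries are sorted by (column, row), the cellranger
    convention. Labels containing tabs or newlines are rejected.
    """
    for label in (*counts.gene_ids, *counts.barcodes):
        if "\t" in label or "\n" in label:
            raise ValueError(f"label {label!r} contains a delimiter character")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = counts.values.tocoo()
    order = np.lexsort((coo.row, coo.col))
    with open(directory / "matrix.mtx", "w") as fh:
        fh.write(MTX_HEADER + "\n")
        fh.write(f"{counts.n_genes} {counts.n_cells} {coo.nnz}\n")
        for i, j, v in zip(coo.row[order], coo.col[order], coo.data[order]):
            fh.write(f"{i + 1} {j + 1} {v}\n")
    (directory / "features.tsv").write_text(
        "".join(g + "\n" for g in counts.gene_ids)
    )
    (directory / "barcodes.tsv").write_text(
        "".join(b + "\n" for b in counts.barcodes)
    )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    members. Duplicate members within a set are deduplicated with a logged
    warning; a duplicated set name or a line with fewer than 3 fields is an
    error."""
    path = Path(path)
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in members if m]
            unique = set(members)
            if len(unique) < len(members):
                logger.warning(
                    "%s:%d: set %s lists %d duplicate member(s); deduplicated",
                    path, lineno, name, len(members) - len(unique),
                )
            if not unique:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in collection:
            desc = collection.descriptions.get(name, "")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


# ---------------------------------------------------------------------------
# Result tables (TSV, 6 significant digits, deterministic row order)
# ---------------------------------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


MARKER_COLUMNS = [
    "gene", "avg_log2fc", "p", "p_adj", "pct1", "pct2", "pct3",
    "selected", "high_specificity",
]


def write_marker_table(table: pd.DataFrame, path: str | Path) -> None:
    """Marker table TSV: ascending adjusted p, ties by gene ID."""
    df = table.loc[:, MARKER_COLUMNS].sort_values(
        ["p_adj", "gene"], kind="mergesort"
    )
    _write_tsv(df, path)


def write_gate_summary(summary: pd.DataFrame, path: str | Path) -> None:
    """Gate summary TSV, rows ordered by tissue label."""
    cols = ["tissue", "n_stringent", "n_enriched_cells", "proportion"]
    _write_tsv(summary.loc[:, cols].sort_values("tissue", kind="mergesort"), path)


def write_gsea_table(records: pd.DataFrame, path: str | Path) -> None:
    """GSEA TSV ordered by FDR q then set name."""
    cols = ["set", "size", "es", "nes", "p_perm", "fdr_q", "significant"]
    _write_tsv(records.loc[:, cols].sort_values(["fdr_q", "set"], kind="mergesort"), path)


def write_venn_table(regions: Mapping[str, int] | pd.DataFrame, path: str | Path) -> None:
    """Venn partition TSV: one row per membership pattern, sorted by pattern."""
    if isinstance(regions, pd.DataFrame):
        df = regions
    else:
        df = pd.DataFrame(
            {"region": list(regions), "size": [regions[k] for k in regions]}
        )
    _write_tsv(df.sort_values(df.columns[0], kind="mergesort"), path)
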