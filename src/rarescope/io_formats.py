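"""Reading and writing of every external format the pipeline touches.

All tables are UTF-8 tab-separated text with a header row.  Genome and run
identifiers are opaque, case-sensitive strings.  Floating point values are
serialized at six significant digits so repeated runs produce byte-identical
files.  Other modules never touch the filesystem for data I/O: they operate
on the in-memory containers produced here (pandas DataFrames and
:class:`~rarescope.phylo.PhyloTree`).

Gene-count tables follow the OrthoFinder ``Orthogroups.GeneCount.tsv``
dialect: first column the orthogroup id, one column per genome, and an
optional trailing ``Total`` column which is ignored.  Annotation-hit tables
follow blast tabular outfmt-6 column order plus two appended columns, a
database tag and a free-text description.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import PhyloTree, TreeError

__all__ = [
    "SchemaError",
    "ColumnSpec",
    "TableSchema",
    "parse_newick",
    "write_newick",
    "read_table",
    "read_gene_counts",
    "read_run_metadata",
    "write_report",
    "FLOAT_FORMAT",
    "ANNOTATION_DATABASES",
    "COVERAGE_SCHEMA",
    "QUALITY_SCHEMA",
    "RUN_METADATA_SCHEMA",
    "ABUNDANCE_LONG_SCHEMA",
    "ALIGNMENT_SCHEMA",
    "ANNOTATION_HITS_SCHEMA",
    "SELF_SCORE_SCHEMA",
    "IDENTITY_SCHEMA",
]

FLOAT_FORMAT = "%.6g"

ANNOTATION_DATABASES = ("KEGG", "NR", "MEROPS", "dbCAN", "TCDB", "SignalP")


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "str" | "int" | "float"
    required: bool = True


@dataclass(frozen=True)
class TableSchema:
    """Declared shape of a TSV table.

    Column names must be unique and at least one column must be required.
    Extra columns in a file are retained as opaque text.
    """

    name: str
    columns: tuple[ColumnSpec, ...]
    dialect: str = ""

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"schema {self.name}: duplicate column names")
        if not any(c.required for c in self.columns):
            raise SchemaError(f"schema {self.name}: at least one required column")

    @property
    def required_names(self) -> list[str]:
        return [c.name for c in self.columns if c.required]


_DTYPES = {"str": str, "int": np.int64, "float": np.float64}


COVERAGE_SCHEMA = TableSchema(
    "coverage",
    (
        ColumnSpec("run_id", "str"),
        ColumnSpec("genome_id", "str"),
        ColumnSpec("mean_coverage", "float"),
        ColumnSpec("breadth", "float"),
        ColumnSpec("mapped_reads", "int", required=False),
    ),
    dialect="coverm-like per-run per-genome coverage summary",
)

QUALITY_SCHEMA = TableSchema(
    "quality",
    (
        ColumnSpec("genome_id", "str"),
        ColumnSpec("completeness", "float"),
        ColumnSpec("contamination", "float"),
    ),
    dialect="checkM2-like genome quality table",
)

RUN_METADATA_SCHEMA = TableSchema(
    "run_metadata",
    (
        ColumnSpec("run_id", "str"),
        ColumnSpec("study_id", "str"),
        ColumnSpec("environment", "str", required=False),
        ColumnSpec("lat", "float", required=False),
        ColumnSpec("lon", "float", required=False),
        ColumnSpec("filter_fraction", "str", required=False),
    ),
)

ABUNDANCE_LONG_SCHEMA = TableSchema(
    "abundance",
    (
        ColumnSpec("run_id", "str"),
        ColumnSpec("genome_id", "str"),
        ColumnSpec("relative_abundance", "float"),
    ),
    dialect="long-form MAG x run relative abundances in percent",
)

ALIGNMENT_SCHEMA = TableSchema(
    "alignments",
    (
        ColumnSpec("read_id", "str"),
        ColumnSpec("genome_id", "str"),
        ColumnSpec("run_id", "str", required=False),
        ColumnSpec("read_length", "int"),
        ColumnSpec("aligned_length", "int"),
        ColumnSpec("percent_identity", "float"),
        ColumnSpec("start", "int"),
        ColumnSpec("end", "int"),
    ),
    dialect="per-read alignment summary",
)

# blast outfmt-6 column order plus database tag and description
_OUTFMT6 = (
    ("qseqid", "str", True),
    ("sseqid", "str", True),
    ("pident", "float", False),
    ("length", "int", False),
    ("mismatch", "int", False),
    ("gapopen", "int", False),
    ("qstart", "int", False),
    ("qend", "int", False),
    ("sstart", "int", False),
    ("send", "int", False),
    ("evalue", "float", False),
    ("bitscore", "float", False),
)

ANNOTATION_HITS_SCHEMA = TableSchema(
    "annotation_hits",
    tuple(ColumnSpec(n, k, r) for n, k, r in _OUTFMT6)
    + (
        ColumnSpec("database", "str"),
        ColumnSpec("description", "str"),
        ColumnSpec("genome_id", "str", required=False),
    ),
    dialect="blast outfmt-6 plus database tag and free-text description",
)

SELF_SCORE_SCHEMA = TableSchema(
    "self_scores",
    (
        ColumnSpec("gene_id", "str"),
        ColumnSpec("self_bitscore", "float"),
        ColumnSpec("genome_id", "str", required=False),
    ),
)

IDENTITY_SCHEMA = TableSchema(
    "identity",
    (
        ColumnSpec("genome_a", "str"),
        ColumnSpec("genome_b", "str"),
        ColumnSpec("ani", "float"),
        ColumnSpec("aligned_fraction", "float"),
    ),
    dialect="pairwise genome identity (ANI as fraction in [0,1])",
)


# -- trees -----------------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated rooted tree.

    Every non-root node must carry a finite non-negative branch length;
    leaf labels are preserved verbatim.
    """
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


# -- tables ----------------------------------------------------------------


def read_table(path: str | os.PathLike, schema: TableSchema) -> pd.DataFrame:
    """Read a TSV into a typed DataFrame per ``schema``.

    Missing required columns raise :class:`SchemaError` naming them;
    unparseable cells raise with row/column coordinates.  Extra columns
    are kept as text; row order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (no header row)") from None
    missing = [c for c in schema.required_names if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"for schema {schema.name}"
        )
    for col in schema.columns:
        if col.name not in df.columns or col.kind == "str":
            continue
        raw = df[col.name]
        blank = raw.str.strip() == ""
        if not col.required and blank.all():
            df[col.name] = np.nan
            continue
        converted = pd.to_numeric(raw.where(~blank, np.nan), errors="coerce")
        bad = converted.isna() & ~blank
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
            raise SchemaError(
                f"{path}: unparseable {col.kind} value {raw[bad].iloc[0]!r} "
                f"at row {row}, column {col.name!r}"
            )
        if col.kind == "int":
            if converted.isna().any():
                df[col.name] = converted  # optional int column with blanks
            else:
                df[col.name] = converted.astype(np.int64)
        else:
            df[col.name] = converted.astype(np.float64)
    return df


def read_gene_counts(path: str | os.PathLike) -> pd.DataFrame:
    """Read an OrthoFinder-dialect gene-count TSV.

    Returns an orthogroup x genome integer matrix (orthogroup ids as
    index).  A trailing ``Total`` column, if present, is dropped and never
    treated as a genome.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file (no header row)") from None
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: gene-count table needs an id column and genomes")
    id_col = df.columns[0]
    df = df.set_index(id_col)
    if df.columns[-1] == "Total":
        df = df.drop(columns="Total")
    try:
        out = df.astype(np.int64)
    except ValueError as exc:
        raise SchemaError(f"{path}: non-integer gene count: {exc}") from None
    if (out < 0).any().any():
        raise SchemaError(f"{path}: negative gene counts")
    out.index.name = "orthogroup"
    return out


def read_run_metadata(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a run metadata table (run -> study, environment).

    run_id must be unique; latitude/longitude, when present, must lie in
    [-90, 90] / [-180, 180].
    """
    df = read_table(path, RUN_METADATA_SCHEMA)
    if df["run_id"].duplicated().any():
        dupes = df.loc[df["run_id"].duplicated(), "run_id"].unique()
        raise SchemaError(f"duplicate run_id(s): {', '.join(dupes[:5])}")
    for col, lim in (("lat", 90.0), ("lon", 180.0)):
        if col in df.columns and df[col].notna().any():
            vals = df[col].dropna()
            if ((vals < -lim) | (vals > lim)).any():
                raise SchemaError(f"{col} out of range [-{lim}, {lim}]")
    return df


def write_report(
    tables: dict[str, pd.DataFrame], out_dir: str | os.PathLike
) -> pd.DataFrame:
    """Write one TSV per named table plus a ``manifest.tsv``.

    Column order is taken from each DataFrame; floats are serialized at
    six significant digits, so re-running on identical inputs produces
    byte-identical files.  Returns the manifest (file name, rows).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(tables):
        fname = f"{name}.tsv"
        table = tables[name]
        table.to_csv(
            out_dir / fname,
            sep="\t",
            index=False,
            float_format=FLOAT_FORMAT,
            lineterminator="\n",
        )
        rows.append({"file": fname, "rows": len(table)})
    manifest = pd.DataFrame(rows, columns=["file", "rows"])
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False, lineterminator="\n")
    return manifest
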