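"""Readers and writers for the plain-text formats used across the pipeline.

All tables are tab-separated text.  The two morphometric dialects are

* cell table: ``species  stage  individual  image_index  pamr  cell_id  cl
  ca_um2  clwr`` (metric columns may be absent when the table only carries
  covariates for a polygon file);
* polygon vertex table: ``cell_id  vertex_index  x_um  y_um``, joined to the
  cell table on ``cell_id``.

Expression inputs are isoform/gene count tables (first column the feature
id, remaining columns samples), a BLAST tabular hit file (either the plain
``qseqid sseqid evalue bitscore`` four-column form or full outfmt 6), a
sample sheet (``sample  species  stage  replicate``) and an annotation
table (``gene_id  description``).  Gene sets travel as GMT, ranked lists as
two-column RNK.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

CELL_TABLE_COLUMNS = [
    "species", "stage", "individual", "image_index", "pamr",
    "cell_id", "cl", "ca_um2", "clwr",
]
POLYGON_COLUMNS = ["cell_id", "vertex_index", "x_um", "y_um"]


class FormatError(ValueError):
    """Malformed input file."""


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["species", "stage", "individual", "image_index", "pamr", "cell_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: cell table missing columns {missing}")
    bad = df.index[(df["pamr"] < 0) | (df["pamr"] > 1)]
    if len(bad):
        raise FormatError(f"{path}: pamr outside [0, 1] at row {bad[0] + 2}")
    return df


def write_cell_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in CELL_TABLE_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_polygons(path) -> dict[str, np.ndarray]:
    """Return {cell_id: (n, 2) vertex array}, vertices ordered by index."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in POLYGON_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: polygon table missing columns {missing}")
    out: dict[str, np.ndarray] = {}
    for cid, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("vertex_index")
        out[str(cid)] = grp[["x_um", "y_um"]].to_numpy(dtype=float)
    return out


def write_polygons(polygons: dict[str, np.ndarray], path) -> None:
    rows = []
    for cid, verts in polygons.items():
        for i, (x, y) in enumerate(np.asarray(verts)):
            rows.append((cid, i, x, y))
    pd.DataFrame(rows, columns=POLYGON_COLUMNS).to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    """Count table: feature ids in the first column, integer sample columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise FormatError(f"{path}: count table has no sample columns")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate feature id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric counts")
    if (arr < 0).any():
        r, c = np.argwhere(arr < 0)[0]
        raise FormatError(
            f"{path}: negative count for feature {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    return df


def write_counts(df: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = ["sample", "species", "stage"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: sample sheet missing columns {missing}")
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df.set_index("sample", drop=False)


def read_blast_hits(path) -> pd.DataFrame:
    """BLAST tabular hits; accepts the 4-column (qseqid, sseqid, evalue,
    bitscore) dialect or full outfmt 6 (12 columns, headerless)."""
    with open(path) as fh:
        first = fh.readline()
    ncol = len(first.rstrip("\n").split("\t"))
    if first.startswith("qseqid") or first.startswith("#"):
        df = pd.read_csv(path, sep="\t", comment="#")
        df.columns = [c.lower() for c in df.columns]
    elif ncol >= 12:
        names = [
            "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "sstart", "send", "evalue", "bitscore",
        ]
        df = pd.read_csv(path, sep="\t", header=None, names=names + list(range(ncol - 12)))
    elif ncol == 4:
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["qseqid", "sseqid", "evalue", "bitscore"],
        )
    else:
        raise FormatError(f"{path}: unrecognized BLAST tabular layout ({ncol} columns)")
    for col in ("qseqid", "sseqid", "evalue", "bitscore"):
        if col not in df.columns:
            raise FormatError(f"{path}: hit file missing column {col!r}")
    bad = df.index[~np.isfinite(df["evalue"]) | (df["evalue"] < 0)]
    if len(bad):
        raise FormatError(f"{path}: invalid e-value at line {bad[0] + 1}")
    return df[["qseqid", "sseqid", "evalue", "bitscore"]]


def write_blast_hits(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["qseqid", "sseqid", "evalue", "bitscore"])


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene_id", "description") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: annotation missing columns {missing}")
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """GMT: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: GMT row needs name and description")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, genes in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_rnk(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "metric"], comment="#")
    s = pd.Series(df["metric"].to_numpy(dtype=float), index=df["gene"].astype(str))
    if s.index.has_duplicates:
        raise FormatError(f"{path}: duplicate gene ids in RNK file")
    return s


def write_rnk(series: pd.Series, path) -> None:
    series.to_csv(path, sep="\t", header=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
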