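"""Readers and writers for the plain-text formats used across the pipeline.

Tables travel as TSV, gene sets as GMT, sparse expression as MatrixMarket.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell annotation table (cell_id, sample_id, cluster_id, cell_type, is_epithelial)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "sample_id": str, "cluster_id": str})
    required = {"cell_id", "sample_id", "cluster_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cell table missing columns: {sorted(missing)}")
    if "is_epithelial" in df.columns:
        df["is_epithelial"] = df["is_epithelial"].astype(bool)
    return df


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read a dense labelled matrix (rows in first column)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_expression_mtx(mtx_path: str | Path, genes_path: str | Path,
                        cells_path: str | Path) -> pd.DataFrame:
    """Read a genes x cells expression matrix from MTX plus index files."""
    mat = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
    dense = mat.toarray() if scipy.sparse.issparse(mat) else mat
    if dense.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match {len(genes)} genes x {len(cells)} cells")
    return pd.DataFrame(dense, index=genes, columns=cells)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "ecotme") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_survival_table(path: str | Path) -> pd.DataFrame:
    """Read a survival table indexed by sample id with `time` and `event` columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("time", "event"):
        if col not in df.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if df["time"].isna().any() or df["event"].isna().any():
        raise ValueError("survival table has missing time/event values")
    if (df["time"] < 0).any():
        raise ValueError("survival times must be nonnegative")
    df["event"] = df["event"].astype(int)
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
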