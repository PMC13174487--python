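"""Readers and writers for the pipeline's plain-text formats.

Expression matrices travel as MatrixMarket triplets (``matrix.mtx``) with
``genes.tsv``/``barcodes.tsv`` index files; tables are UTF-8 CSV with a
header row; gene sets are GMT. Output column schemas live in
``schemas.json`` next to this module and are enforced on write.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as sio
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_cell_map",
    "validate_schema",
]

_SCHEMA_PATH = Path(__file__).parent / "schemas.json"

CELL_MAP_COLUMNS = ["cell_id", "x_um", "y_um", "compartment", "cell_type"]


def write_expression(matrix: pd.DataFrame, outdir: str | Path) -> Path:
    """Write a cells x genes matrix as MTX triplet + genes/barcodes files.

    The MTX stores genes x cells (community convention); ``genes.tsv`` and
    ``barcodes.tsv`` carry the row/column identities.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = sparse.csr_matrix(matrix.to_numpy().T)
    sio.mmwrite(str(outdir / "matrix.mtx"), sp, field="integer"
                if np.issubdtype(matrix.to_numpy().dtype, np.integer) else "real")
    (outdir / "genes.tsv").write_text("\n".join(map(str, matrix.columns)) + "\n")
    (outdir / "barcodes.tsv").write_text("\n".join(map(str, matrix.index)) + "\n")
    return outdir


def read_expression(indir: str | Path, expect_integer: bool = False) -> pd.DataFrame:
    """Read an MTX triplet directory back to a cells x genes DataFrame.

    Checks declared dimensions against the index files; duplicate gene
    symbols are disambiguated with ``.1``, ``.2`` suffixes (logged).
    """
    indir = Path(indir)
    for name in ("matrix.mtx", "genes.tsv", "barcodes.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"{name} missing from {indir}")
    mat = sio.mmread(str(indir / "matrix.mtx"))
    genes = (indir / "genes.tsv").read_text().splitlines()
    cells = (indir / "barcodes.tsv").read_text().splitlines()
    genes = [g for g in genes if g]
    cells = [c for c in cells if c]
    if mat.shape != (len(genes), len(cells)):
        raise ValueError(
            f"matrix shape {mat.shape} does not match index files "
            f"({len(genes)} genes, {len(cells)} barcodes)")
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if expect_integer and not np.allclose(dense, np.round(dense)):
        raise ValueError("expected integer counts, found non-integer values")
    if len(set(genes)) != len(genes):
        seen: dict[str, int] = {}
        fixed = []
        for g in genes:
            if g in seen:
                seen[g] += 1
                fixed.append(f"{g}.{seen[g]}")
            else:
                seen[g] = 0
                fixed.append(g)
        logger.warning("duplicate gene symbols disambiguated with suffixes")
        genes = fixed
    return pd.DataFrame(dense.T, index=pd.Index(cells, name="cell_id"),
                        columns=genes)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(gene_sets: dict, path: str | Path,
              description: str = "cd8niche") -> Path:
    path = Path(path)
    lines = [f"{name}\t{description}\t" + "\t".join(genes)
             for name, genes in gene_sets.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_cell_map(path: str | Path) -> pd.DataFrame:
    """Read a per-cell spatial table; enforces the documented schema."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell map {path} missing columns: {missing}")
    if df[["x_um", "y_um"]].isna().any().any():
        raise ValueError("cell map has missing coordinates")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("cell map has non-finite coordinates")
    return df


def _schemas() -> dict:
    return json.loads(_SCHEMA_PATH.read_text())


def validate_schema(df: pd.DataFrame, name: str) -> None:
    """Check a DataFrame against a named column schema from schemas.json."""
    schema = _schemas().get(name)
    if schema is None:
        raise KeyError(f"unknown schema {name!r}")
    missing = [c for c in schema["required_columns"] if c not in df.columns]
    if missing:
        raise ValueError(f"output {name} missing required columns: {missing}")
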