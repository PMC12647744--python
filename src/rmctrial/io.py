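"""Readers and writers for the package's text formats.

All tabular inputs are comma-separated UTF-8 with a required header and
plain decimal points.  Expression data travel as a Matrix Market sparse
file (cells x genes) plus gene and cell annotation CSVs.  Malformed
inputs raise :class:`ParseError` naming the offending column or
dimension.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .recist import LESION_COLUMNS

__all__ = [
    "ParseError",
    "read_lesion_table",
    "write_lesion_table",
    "read_survival",
    "write_survival",
    "read_expression",
    "write_expression",
    "write_report",
]

SURVIVAL_COLUMNS = ["patient_id", "time_months", "event"]
CELL_COLUMNS = ["cell_id", "compartment", "condition"]
CONDITIONS = {"baseline", "postNI"}


class ParseError(ValueError):
    """Malformed input file."""


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {', '.join(missing)}")


def read_lesion_table(path) -> pd.DataFrame:
    """Read a longitudinal lesion table (one row per patient/week/lesion)."""
    df = pd.read_csv(path)
    _require_columns(df, LESION_COLUMNS, path)
    diam = pd.to_numeric(df["longest_diameter_mm"], errors="coerce")
    bad = df.index[diam.isna()]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ParseError(
            f"{path}: non-numeric longest_diameter_mm on line(s) "
            f"{[int(i) + 2 for i in bad]}"
        )
    if (diam < 0).any():
        raise ParseError(f"{path}: negative lesion diameters")
    df["longest_diameter_mm"] = diam
    df["week"] = pd.to_numeric(df["week"], errors="raise")
    df["is_target"] = df["is_target"].astype(bool)
    df["is_new"] = df["is_new"].astype(bool)
    return df[LESION_COLUMNS]


def write_lesion_table(df: pd.DataFrame, path) -> None:
    df[LESION_COLUMNS].to_csv(path, index=False)


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, SURVIVAL_COLUMNS, path)
    time = pd.to_numeric(df["time_months"], errors="coerce")
    if time.isna().any():
        raise ParseError(f"{path}: non-numeric time_months values")
    if (time < 0).any():
        raise ParseError(f"{path}: negative survival times")
    df["time_months"] = time
    df["event"] = df["event"].astype(bool)
    return df[SURVIVAL_COLUMNS]


def write_survival(df: pd.DataFrame, path) -> None:
    df[SURVIVAL_COLUMNS].to_csv(path, index=False)


def read_expression(mtx_path, genes_path, cells_path) -> AnnData:
    """Assemble an AnnData from MTX (cells x genes) plus annotations.

    ``genes_path`` is a CSV with a ``gene_id`` column; ``cells_path``
    has columns ``cell_id, compartment, condition``.
    """
    mat = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path)
    _require_columns(genes, ["gene_id"], genes_path)
    cells = pd.read_csv(cells_path)
    _require_columns(cells, CELL_COLUMNS, cells_path)

    n_cells, n_genes = mat.shape
    if n_cells != len(cells) or n_genes != len(genes):
        raise ParseError(
            f"{mtx_path}: declared dims {mat.shape} do not match annotations "
            f"({len(cells)} cells, {len(genes)} genes)"
        )
    unknown = set(cells["condition"]) - CONDITIONS
    if unknown:
        raise ParseError(f"{cells_path}: unknown condition label(s) {unknown}")
    X = np.asarray(mat.todense(), dtype=float) if sp.issparse(mat) else np.asarray(mat)
    if (X < 0).any():
        raise ParseError(f"{mtx_path}: negative expression values")
    obs = cells.set_index("cell_id")[["compartment", "condition"]]
    obs.index = obs.index.astype(str)
    var = pd.DataFrame(index=genes["gene_id"].astype(str))
    return AnnData(X=X, obs=obs, var=var)


def write_expression(adata: AnnData, mtx_path, genes_path, cells_path) -> None:
    X = adata.X
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(X))
    pd.DataFrame({"gene_id": adata.var_names}).to_csv(genes_path, index=False)
    pd.DataFrame(
        {
            "cell_id": adata.obs_names,
            "compartment": adata.obs["compartment"].to_numpy(),
            "condition": adata.obs["condition"].to_numpy(),
        }
    ).to_csv(cells_path, index=False)


def write_report(result: dict, path) -> None:
    """Write an analysis report as JSON (numpy scalars coerced)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(result, indent=2, default=default) + "\n")
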