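"""Shared I/O: Matrix Market + CSV single-cell dialect, JSON configs, run logs.

On-disk single-cell layout (the dialect both the fixture writer and the
pipeline reader use):

* ``matrix.mtx`` — Matrix Market, cells in rows, genes in columns;
* ``genes.tsv`` — one ``gene_id`` per line (header row included);
* ``cells.csv`` — columns ``cell_id, sample_id, group``.

The cells-in-rows orientation is declared in every run log so a transposed
matrix is caught by dimension checks rather than silently accepted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .estimation import SingleCellDataset
from .model import GroupParams, InvalidParameterError, MeasurementNoise, ShiftParams
from .simulate import SimulationConfig

__all__ = [
    "read_single_cell",
    "read_single_cell_csv",
    "write_single_cell",
    "write_run_log",
    "group_params_from_dict",
    "shift_params_from_dict",
    "noise_from_dict",
    "simulation_config_from_dict",
    "load_config",
]

MATRIX_ORIENTATION = "cells_in_rows"


def read_single_cell(
    matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> SingleCellDataset:
    """Read the Matrix Market + TSV/CSV dialect into a validated dataset.

    Raises on dimension mismatches, duplicate IDs, cells whose metadata is
    missing, and samples mapped to more than one group.
    """
    matrix = sio.mmread(str(matrix_path))
    if sp.issparse(matrix):
        matrix = np.asarray(matrix.todense(), dtype=float)
    genes = pd.read_csv(genes_path, sep="\t")
    if "gene_id" not in genes.columns:
        raise InvalidParameterError(f"{genes_path}: expected a 'gene_id' column")
    meta = pd.read_csv(cells_path)
    required = {"cell_id", "sample_id", "group"}
    if not required.issubset(meta.columns):
        raise InvalidParameterError(
            f"{cells_path}: expected columns {sorted(required)}, got {list(meta.columns)}"
        )
    if matrix.shape[0] != len(meta):
        raise InvalidParameterError(
            f"matrix has {matrix.shape[0]} cell rows but metadata lists {len(meta)} cells"
        )
    if matrix.shape[1] != len(genes):
        raise InvalidParameterError(
            f"matrix has {matrix.shape[1]} gene columns but {len(genes)} gene ids given"
        )
    pairs = meta[["sample_id", "group"]].astype(str).drop_duplicates()
    dupes = pairs["sample_id"][pairs["sample_id"].duplicated()].tolist()
    if dupes:
        raise InvalidParameterError(f"samples mapped to multiple groups: {dupes}")
    return SingleCellDataset(
        matrix=matrix,
        gene_ids=genes["gene_id"].astype(str).tolist(),
        cell_ids=meta["cell_id"].astype(str).tolist(),
        cell_sample=meta["sample_id"].astype(str).to_numpy(),
        sample_group=dict(zip(pairs["sample_id"], pairs["group"])),
    )


def read_single_cell_csv(matrix_csv: str | Path, cells_path: str | Path) -> SingleCellDataset:
    """Dense alternative: a CSV with cell_id index and one column per gene."""
    dense = pd.read_csv(matrix_csv, index_col=0)
    meta = pd.read_csv(cells_path).astype(str)
    missing = sorted(set(dense.index.astype(str)) - set(meta["cell_id"]))
    if missing:
        raise InvalidParameterError(f"cells without metadata: {', '.join(missing[:10])}")
    meta = meta.set_index("cell_id").loc[dense.index.astype(str)]
    pairs = meta[["sample_id", "group"]].drop_duplicates()
    return SingleCellDataset(
        matrix=dense.to_numpy(dtype=float),
        gene_ids=[str(c) for c in dense.columns],
        cell_ids=[str(i) for i in dense.index],
        cell_sample=meta["sample_id"].to_numpy(),
        sample_group=dict(zip(pairs["sample_id"], pairs["group"])),
    )


def write_single_cell(sc: SingleCellDataset, outdir: str | Path) -> dict[str, str]:
    """Write ``matrix.mtx`` + ``genes.tsv`` + ``cells.csv``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix_path = outdir / "matrix.mtx"
    sio.mmwrite(str(matrix_path), sp.coo_matrix(sc.matrix))
    genes_path = outdir / "genes.tsv"
    pd.DataFrame({"gene_id": sc.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    cells_path = outdir / "cells.csv"
    pd.DataFrame(
        {
            "cell_id": sc.cell_ids,
            "sample_id": [str(s) for s in sc.cell_sample],
            "group": [sc.sample_group[str(s)] for s in sc.cell_sample],
        }
    ).to_csv(cells_path, index=False)
    return {
        "matrix": str(matrix_path),
        "genes": str(genes_path),
        "cells": str(cells_path),
    }


def write_run_log(path: str | Path, payload: dict[str, Any]) -> None:
    """JSON run log; always records the matrix orientation convention."""
    payload = dict(payload)
    payload.setdefault("matrix_orientation", MATRIX_ORIENTATION)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj: Any):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def group_params_from_dict(d: dict[str, Any]) -> GroupParams:
    return GroupParams(
        e_plus=d["e_plus"],
        e_minus=d["e_minus"],
        e_r=d["e_r"],
        v_plus=d.get("v_plus", 0.0),
        v_minus=d.get("v_minus", 0.0),
        v_r=d.get("v_r", 0.0),
    )


def shift_params_from_dict(d: dict[str, Any]) -> ShiftParams:
    return ShiftParams(
        d_plus=d.get("d_plus", 0.0),
        d_minus=d.get("d_minus", 0.0),
        alpha_r=d.get("alpha_r", 1.0),
    )


def noise_from_dict(d: dict[str, Any]) -> MeasurementNoise:
    return MeasurementNoise(v_err=d.get("v_err", 0.0))


def simulation_config_from_dict(d: dict[str, Any], seed: int = 0) -> SimulationConfig:
    return SimulationConfig(
        n_samples=d["n_samples"],
        n_cells=d["n_cells"],
        v_err=d.get("v_err", 0.0),
        v_y_plus=d.get("v_y_plus", 0.0),
        v_y_minus=d.get("v_y_minus", 0.0),
        k=d.get("k", 1.0),
        seed=d.get("seed", seed),
    )


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)
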