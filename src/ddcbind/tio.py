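"""Titration table readers/writers and result serialization.

The on-disk format is a plain CSV (UTF-8, header mandatory) with columns

    ligand_id, target_id, design, T_molar, s_volfrac, f_ret[, se][, replicate_id]

Units are molar and bead volume fraction — spelled out in the column names to
prevent uM/M confusion; ``read_titrations(..., units='uM')`` converts
micromolar input on the fly.  Rows are grouped into one
:class:`~ddcbind.fitting.TitrationDataset` per (ligand_id, target_id, design)
and the design geometry is validated (s constant for VTSD, s proportional to
T for CTSD, both to 1%).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .fitting import TitrationDataset, TitrationPoint
from .models import UM, DesignConstants

__all__ = ["read_titrations", "write_titrations", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ["ligand_id", "target_id", "design", "T_molar", "s_volfrac", "f_ret"]
OPTIONAL_COLUMNS = ["se", "replicate_id"]


class TitrationFormatError(ValueError):
    """Raised for schema or geometry violations, with the offending rows named."""


def _infer_constants(design: str, T: np.ndarray, s: np.ndarray) -> DesignConstants:
    T_star = float(T.max())
    if T_star <= 0:
        raise TitrationFormatError("dataset needs at least one T > 0 point")
    if design == "VTSD":
        s_star = float(np.median(s))
    else:
        s_star = float(s[np.argmax(T)])
    return DesignConstants(s_star=s_star, T_star=T_star)


def read_titrations(
    path, units: str = "molar", consts: Optional[DesignConstants] = None
) -> List[TitrationDataset]:
    """Read a titration CSV into one dataset per (ligand, target, design) group.

    ``consts`` overrides the (s_star, T_star) inferred from each group's data;
    inference takes T_star as the largest T and s_star as the median VTSD s
    (or the s at T_star for CTSD).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise TitrationFormatError(f"{path}: file is empty") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TitrationFormatError(f"{path}: missing required columns {missing}")

    scale = {"molar": 1.0, "uM": UM, "um": UM}.get(units)
    if scale is None:
        raise ValueError(f"unknown units {units!r}; use 'molar' or 'uM'")

    for col in ("T_molar", "s_volfrac", "f_ret"):
        bad = df.index[~np.isfinite(df[col]) | (df[col] < 0)]
        if len(bad):
            raise TitrationFormatError(
                f"{path}: column {col} has non-finite or negative values "
                f"at data rows {list(bad + 2)}"  # +2: header + 1-based
            )
    df["design"] = df["design"].str.upper()
    bad = df.index[~df["design"].isin(["VTSD", "CTSD"])]
    if len(bad):
        raise TitrationFormatError(
            f"{path}: design must be VTSD or CTSD at data rows {list(bad + 2)}"
        )

    key_cols = ["ligand_id", "target_id", "design", "T_molar"]
    if "replicate_id" in df.columns:
        key_cols.append("replicate_id")
    dup = df.duplicated(subset=key_cols)
    if dup.any():
        raise TitrationFormatError(
            f"{path}: duplicate (pair, design, T, replicate) rows at "
            f"{list(df.index[dup] + 2)}"
        )

    datasets = []
    for (ligand, target, design), grp in df.groupby(
        ["ligand_id", "target_id", "design"], sort=True
    ):
        T = grp["T_molar"].to_numpy() * scale
        s = grp["s_volfrac"].to_numpy()
        c = consts or _infer_constants(design, T, s)
        points = []
        for i, (_, row) in enumerate(grp.iterrows()):
            se = row.get("se")
            se = None if se is None or (isinstance(se, float) and math.isnan(se)) else float(se)
            rep = row.get("replicate_id")
            rep = None if rep is None or (isinstance(rep, float) and math.isnan(rep)) else str(rep)
            points.append(
                TitrationPoint(T=float(T[i]), s=float(s[i]), f_ret=float(row["f_ret"]),
                               se=se, replicate_id=rep)
            )
        try:
            ds = TitrationDataset(design=design, consts=c, points=points,
                                  ligand_id=str(ligand), target_id=str(target))
        except ValueError as e:
            raise TitrationFormatError(
                f"{path}: group ({ligand}, {target}, {design}): {e}"
            ) from None
        datasets.append(ds)
    return datasets


def write_titrations(datasets: List[TitrationDataset], path) -> None:
    """Write datasets to the titration CSV format (full float precision)."""
    rows = []
    for ds in datasets:
        for p in ds.points:
            rows.append(
                {
                    "ligand_id": ds.ligand_id,
                    "target_id": ds.target_id,
                    "design": ds.design,
                    "T_molar": repr(p.T),
                    "s_volfrac": repr(p.s),
                    "f_ret": repr(p.f_ret),
                    "se": "" if p.se is None else repr(p.se),
                    "replicate_id": "" if p.replicate_id is None else p.replicate_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
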