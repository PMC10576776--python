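"""Readers and writers for the three on-disk formats.

Boundary tables are TSV (embryo_id, side, boundary_index, phenotype,
condition); kymographs are 16-bit grayscale TIFF (rows = time, posterior at
column 0) with a JSON metadata sidecar, or an equivalent CSV matrix; cell
tables are CSV (cell_id, x_um, y_um, count_gene1, count_gene2).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kymo import Kymograph

__all__ = [
    "read_boundary_table",
    "write_boundary_table",
    "read_kymograph",
    "write_kymograph",
    "read_cell_table",
    "write_cell_table",
]

SIDECAR_KEYS = ("frame_interval_min", "px_size_um", "seven_somite_frame")


def read_boundary_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a boundary-phenotype TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"embryo_id": str, "side": str})
    required = ["embryo_id", "side", "boundary_index", "phenotype"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad_side = ~df["side"].isin(["L", "R"])
    if bad_side.any():
        raise ValueError(f"{path}: invalid side at row {int(np.where(bad_side)[0][0])}")
    ph = df["phenotype"]
    bad = ph.notna() & ~ph.isin([0, 1])
    if bad.any():
        raise ValueError(
            f"{path}: invalid phenotype code at row {int(np.where(bad)[0][0])}"
        )
    return df


def write_boundary_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_kymograph(kymo: Kymograph, path: str | Path) -> None:
    """Write a kymograph as 16-bit TIFF (or CSV if the suffix is .csv) plus
    a JSON sidecar carrying the acquisition metadata.

    TIFF quantizes to integer gray levels; keep synthetic intensities on a
    scale of hundreds to thousands of counts, or use the CSV route when
    exact floats matter.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        np.savetxt(path, kymo.data, delimiter=",")
    else:
        data = np.clip(np.round(kymo.data), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
    meta = {
        "frame_interval_min": kymo.frame_interval_min,
        "px_size_um": kymo.px_size_um,
        "seven_somite_frame": kymo.seven_somite_frame,
        "temperature_label": kymo.temperature_label,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def read_kymograph(path: str | Path) -> Kymograph:
    """Read a TIFF or CSV kymograph with its JSON sidecar."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"kymograph sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    for key in SIDECAR_KEYS:
        if key not in meta:
            raise ValueError(f"{sidecar}: missing metadata key {key!r}")
    if path.suffix.lower() == ".csv":
        data = np.loadtxt(path, delimiter=",")
    else:
        data = tifffile.imread(path).astype(float)
    return Kymograph(
        data,
        frame_interval_min=float(meta["frame_interval_min"]),
        px_size_um=float(meta["px_size_um"]),
        seven_somite_frame=int(meta["seven_somite_frame"]),
        temperature_label=str(meta.get("temperature_label", "")),
    )


def read_cell_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["cell_id", "x_um", "y_um", "count_gene1", "count_gene2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("count_gene1", "count_gene2"):
        if (df[col] < 0).any():
            raise ValueError(f"{path}: negative counts in {col}")
    return df


def write_cell_table(cells: pd.DataFrame, path: str | Path) -> None:
    cells.to_csv(path, index=False)
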