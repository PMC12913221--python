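"""Readers and writers for the pipeline's on-disk formats.

Single-band categorical and continuous rasters round-trip as TIFF with a JSON
geometry sidecar; monthly water stacks as a compact ``.npy`` cube with a JSON
sidecar (years, geometry); tables as CSV with a JSON schema sidecar.  Every
writer's output is readable by its reader with value equality.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grids import (
    AbundanceGrid,
    FunctionalGroupGrid,
    GridGeometry,
    HydroperiodGrid,
    MonthlyWaterStack,
)

HYDRO_CODE_MAP = {"none": 0, "temporary": 1, "seasonal": 2, "semi_permanent": 3}


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_geometry(path: Path, geometry: GridGeometry, extra: dict | None = None) -> None:
    meta = {
        "height": geometry.height,
        "width": geometry.width,
        "cell_size": geometry.cell_size,
    }
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2, sort_keys=True))


def _read_geometry(path: Path) -> tuple[GridGeometry, dict]:
    meta = json.loads(_sidecar(path).read_text())
    geom = GridGeometry(
        height=meta["height"], width=meta["width"], cell_size=meta["cell_size"]
    )
    return geom, meta


def write_raster(path: str | Path, array: np.ndarray, geometry: GridGeometry,
                 extra: dict | None = None) -> None:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array))
    _write_geometry(path, geometry, extra)


def read_raster(path: str | Path) -> tuple[np.ndarray, GridGeometry, dict]:
    path = Path(path)
    array = tifffile.imread(path)
    geom, meta = _read_geometry(path)
    return array, geom, meta


def write_hydroperiod(path: str | Path, hydro: HydroperiodGrid) -> None:
    write_raster(
        path, hydro.classes, hydro.geometry,
        {"kind": "hydroperiod", "codes": HYDRO_CODE_MAP, "provenance": hydro.provenance},
    )


def read_hydroperiod(path: str | Path) -> HydroperiodGrid:
    array, geom, meta = read_raster(path)
    return HydroperiodGrid(
        classes=array, geometry=geom, provenance=meta.get("provenance", "")
    )


def write_functional(path: str | Path, groups: FunctionalGroupGrid) -> None:
    write_raster(path, groups.labels, groups.geometry, {"kind": "functional_groups"})


def read_functional(path: str | Path) -> FunctionalGroupGrid:
    array, geom, _ = read_raster(path)
    return FunctionalGroupGrid(labels=array, geometry=geom)


def write_abundance(path: str | Path, grid: AbundanceGrid) -> None:
    write_raster(
        path, grid.values, grid.geometry,
        {"kind": "abundance", "species": grid.species, "cycle": grid.cycle},
    )


def read_abundance(path: str | Path) -> AbundanceGrid:
    array, geom, meta = read_raster(path)
    return AbundanceGrid(
        values=array, geometry=geom,
        species=meta.get("species", ""), cycle=meta.get("cycle", ""),
    )


def write_water_stack(path: str | Path, stack: MonthlyWaterStack) -> None:
    path = Path(path)
    np.save(path, stack.water)
    # np.save appends .npy when missing
    saved = path if path.suffix == ".npy" else path.with_suffix(path.suffix + ".npy")
    _write_geometry(saved, stack.geometry, {"kind": "water_stack", "years": stack.years})


def read_water_stack(path: str | Path) -> MonthlyWaterStack:
    path = Path(path)
    water = np.load(path)
    geom, meta = _read_geometry(path)
    return MonthlyWaterStack(water=water, years=list(meta["years"]), geometry=geom)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    path = Path(path)
    table.to_csv(path, index=False, float_format="%.10g")
    schema = {"columns": {c: str(table[c].dtype) for c in table.columns}}
    _sidecar(path).write_text(json.dumps(schema, indent=2, sort_keys=True))


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
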