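"""Densification of fine binary layers to the coarse abundance grid.

Covariate area is aggregated with a non-overlapping block sum aligned to the
abundance grid: each coarse cell's value is the count of true fine pixels
whose centres fall inside it times the fine-pixel area.  This preserves the
precision of the fine wetland data while matching the coarse resolution of
the abundance surfaces, and conserves total area exactly.  Fine dimensions
need not divide evenly; partial edge cells keep whatever pixels they contain.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .grids import AbundanceGrid, DensityGrid, GridGeometry


def block_density(
    layer: np.ndarray,
    geometry: GridGeometry,
    coarse_factor: int,
    covariate: str = "",
) -> DensityGrid:
    """Sum a binary fine layer into coarse cells, returning area in m²."""
    if coarse_factor < 1:
        raise ValueError("coarse_factor must be >= 1")
    layer = np.asarray(layer)
    if layer.shape != geometry.shape:
        raise ValueError("layer shape does not match geometry")
    f = coarse_factor
    coarse = geometry.coarsened(f)
    ph = coarse.height * f - geometry.height
    pw = coarse.width * f - geometry.width
    padded = np.pad(layer.astype(np.int64), ((0, ph), (0, pw)))
    counts = padded.reshape(coarse.height, f, coarse.width, f).sum(axis=(1, 3))
    return DensityGrid(
        values=counts * geometry.pixel_area_m2,
        geometry=coarse,
        covariate=covariate,
    )


def assemble_table(
    densities: dict[str, DensityGrid],
    abundance: AbundanceGrid,
    frame_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """One row per coarse study-frame cell: covariate densities (ha) + response.

    Columns: ``cell_id``, ``row``, ``col``, one hectare-valued column per
    covariate, and ``abundance``.  Cells outside the frame are dropped;
    zero-abundance cells are retained (absence is informative to the forest).
    """
    geom = abundance.geometry
    for name, d in densities.items():
        if d.geometry.shape != geom.shape:
            raise ValueError(f"density grid {name!r} geometry mismatch")
    if frame_mask is None:
        frame_mask = np.ones(geom.shape, dtype=bool)
    frame_mask = np.asarray(frame_mask, dtype=bool)
    if frame_mask.shape != geom.shape:
        raise ValueError("frame mask geometry mismatch")
    rows, cols = np.nonzero(frame_mask)
    data: dict[str, np.ndarray] = {
        "cell_id": rows * geom.width + cols,
        "row": rows,
        "col": cols,
    }
    for name, d in densities.items():
        data[name] = d.hectares[rows, cols]
    data["abundance"] = abundance.values[rows, cols]
    return pd.DataFrame(data)


def continental_proportion(
    abundance_full: AbundanceGrid, region_mask: np.ndarray
) -> float:
    """Fraction of total relative-abundance mass lying inside a region.

    This is the species-inclusion gate: a species qualifies when any annual
    cycle places at least 25% of its continental abundance inside the study
    region.
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != abundance_full.geometry.shape:
        raise ValueError("region mask geometry mismatch")
    total = float(abundance_full.values.sum())
    if total == 0.0:
        raise ValueError("all-zero abundance surface: proportion undefined")
    return float(abundance_full.values[region_mask].sum()) / total
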