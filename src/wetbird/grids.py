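"""Core grid containers shared across the pipeline.

Two grids are in play throughout: a *fine* grid (30 m pixels by default) on
which monthly surface-water presence, hydroperiod classes and functional
wetland labels live, and a *coarse* grid (2.5 km cells by default) on which
species relative-abundance surfaces and covariate densities live.  The coarse
grid is axis-aligned with the fine grid and related to it by an integer
``coarse_factor``; all areas derive from pixel counts times pixel area, never
from geometry libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Hydroperiod class codes (single-band categorical rasters use these values).
HYDRO_NONE = 0
HYDRO_TEMPORARY = 1
HYDRO_SEASONAL = 2
HYDRO_SEMI_PERMANENT = 3

HYDRO_CLASS_NAMES = {
    HYDRO_NONE: "none",
    HYDRO_TEMPORARY: "temporary",
    HYDRO_SEASONAL: "seasonal",
    HYDRO_SEMI_PERMANENT: "semi_permanent",
}

# Functional wetland group codes.  ``lake`` and ``riparian`` are raw classes
# that exist only before the deepwater exclusion; the first eight (after
# ``none``) are the model's functional covariates.
FUNC_NONE = 0
FUNC_ESTUARY = 1
FUNC_GRASS_HAY = 2
FUNC_LITTORAL_SALINE = 3
FUNC_LITTORAL = 4
FUNC_MANAGED = 5
FUNC_PALUSTRINE = 6
FUNC_POND = 7
FUNC_RICE = 8
FUNC_LAKE = 9
FUNC_RIPARIAN = 10

FUNC_CLASS_NAMES = {
    FUNC_NONE: "none",
    FUNC_ESTUARY: "estuary",
    FUNC_GRASS_HAY: "grass_hay",
    FUNC_LITTORAL_SALINE: "littoral_saline",
    FUNC_LITTORAL: "littoral",
    FUNC_MANAGED: "managed",
    FUNC_PALUSTRINE: "palustrine",
    FUNC_POND: "pond",
    FUNC_RICE: "rice",
    FUNC_LAKE: "lake",
    FUNC_RIPARIAN: "riparian",
}
FUNC_CLASS_CODES = {name: code for code, name in FUNC_CLASS_NAMES.items()}

#: The twelve model covariates, in canonical order: total inundated wetland
#: area (rice excluded), the three hydroperiod classes, and the eight
#: functional wetland groups.
COVARIATES = (
    "wetland_area",
    "temporary",
    "seasonal",
    "semi_permanent",
    "estuary",
    "grass_hay",
    "littoral_saline",
    "littoral",
    "managed",
    "palustrine",
    "pond",
    "rice",
)

FUNCTIONAL_COVARIATES = (
    "estuary",
    "grass_hay",
    "littoral_saline",
    "littoral",
    "managed",
    "palustrine",
    "pond",
    "rice",
)

CYCLE_LABELS = ("breeding", "post_breeding", "nonbreeding", "pre_breeding")


@dataclass(frozen=True)
class GridGeometry:
    """Shape and pixel size of a raster grid (row/col 0-based, origin top-left)."""

    height: int
    width: int
    cell_size: float = 30.0  # metres

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def pixel_area_m2(self) -> float:
        return self.cell_size * self.cell_size

    def coarsened(self, factor: int) -> "GridGeometry":
        """Geometry of the coarse grid obtained by blocking ``factor``×``factor`` pixels."""
        if factor < 1:
            raise ValueError("coarse factor must be >= 1")
        return GridGeometry(
            height=-(-self.height // factor),
            width=-(-self.width // factor),
            cell_size=self.cell_size * factor,
        )


@dataclass
class MonthlyWaterStack:
    """Multi-year stack of monthly binary inundation grids.

    ``water`` has shape ``(n_years, 12, height, width)`` with values in
    {0, 1}; ``years`` lists the calendar years in order.
    """

    water: np.ndarray
    years: list[int]
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.water = np.asarray(self.water, dtype=np.uint8)
        if self.water.ndim != 4 or self.water.shape[1] != 12:
            raise ValueError("water must have shape (n_years, 12, H, W)")
        if self.water.shape[0] != len(self.years):
            raise ValueError("year axis does not match years list")
        if self.water.shape[2:] != self.geometry.shape:
            raise ValueError("grid shape does not match geometry")
        if self.water.max(initial=0) > 1:
            raise ValueError("water grids must be binary")

    def year_index(self, year: int) -> int:
        try:
            return self.years.index(year)
        except ValueError:
            raise KeyError(f"year {year} not in stack ({self.years[0]}–{self.years[-1]})")

    def grid(self, year: int, month: int) -> np.ndarray:
        """Binary grid for one (year, calendar month 1–12)."""
        if not 1 <= month <= 12:
            raise ValueError(f"month must be 1–12, got {month}")
        return self.water[self.year_index(year), month - 1]


@dataclass
class MonthCountGrid:
    """Per-pixel count (0–12) of inundated months for a year or averaged window."""

    counts: np.ndarray
    geometry: GridGeometry
    window: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.geometry.shape:
            raise ValueError("counts shape does not match geometry")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > 12:
            raise ValueError("month counts must lie in 0–12")


@dataclass
class HydroperiodGrid:
    """Per-pixel hydroperiod class: none / temporary / seasonal / semi-permanent."""

    classes: np.ndarray
    geometry: GridGeometry
    provenance: str = ""

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.uint8)
        if self.classes.shape != self.geometry.shape:
            raise ValueError("classes shape does not match geometry")
        if self.classes.max(initial=0) > HYDRO_SEMI_PERMANENT:
            raise ValueError("unknown hydroperiod code")

    def class_mask(self, code: int) -> np.ndarray:
        return self.classes == code

    def histogram(self) -> dict[str, int]:
        return {
            name: int((self.classes == code).sum())
            for code, name in HYDRO_CLASS_NAMES.items()
        }


@dataclass
class FunctionalGroupGrid:
    """Per-pixel functional wetland group labels (integer coded)."""

    labels: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.geometry.shape:
            raise ValueError("labels shape does not match geometry")
        if self.labels.max(initial=0) > FUNC_RIPARIAN:
            raise ValueError("unknown functional class code")

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels == FUNC_CLASS_CODES[name]

    def counts(self) -> dict[str, int]:
        return {
            name: int((self.labels == code).sum())
            for code, name in FUNC_CLASS_NAMES.items()
        }


@dataclass(frozen=True)
class AnnualCycle:
    """A species' seasonal window expressed as ordered calendar months.

    Month lists may wrap the year end (e.g. nonbreeding Dec–Jan is
    ``[12, 1]``); months after the wrap point belong to the following
    calendar year.
    """

    species: str
    label: str
    months: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.months) <= 12:
            raise ValueError("a cycle spans 1–12 months")
        if len(set(self.months)) != len(self.months):
            raise ValueError("duplicate months in cycle")
        if any(not 1 <= m <= 12 for m in self.months):
            raise ValueError("months must be 1–12")

    @property
    def wraps(self) -> bool:
        return any(b < a for a, b in zip(self.months, self.months[1:]))

    def month_offsets(self) -> list[tuple[int, int]]:
        """(calendar month, year offset) pairs; offset 1 marks post-wrap months."""
        out: list[tuple[int, int]] = []
        offset = 0
        prev = None
        for m in self.months:
            if prev is not None and m < prev:
                offset = 1
            out.append((m, offset))
            prev = m
        return out


@dataclass
class AbundanceGrid:
    """Coarse-grid mean relative abundance surface for one species × cycle."""

    values: np.ndarray
    geometry: GridGeometry
    species: str = ""
    cycle: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")
        if np.any(self.values < 0):
            raise ValueError("relative abundance must be non-negative")

    def presence_mask(self) -> np.ndarray:
        """Cells where estimated abundance is strictly positive."""
        return self.values > 0


@dataclass
class DensityGrid:
    """Coarse-grid covariate area (m² per coarse cell) for one covariate."""

    values: np.ndarray
    geometry: GridGeometry
    covariate: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.geometry.shape:
            raise ValueError("values shape does not match geometry")

    @property
    def hectares(self) -> np.ndarray:
        return self.values / 10_000.0
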