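"""Hydroperiod classification from monthly surface-water stacks.

Hydroperiod is the annual duration of wetland inundation, obtained per pixel
by counting inundated months January–December and binning the count:
0 → none, 1–2 → temporary, 3–8 → seasonal, 9–12 → semi-permanent ("flooded
more than 8 months").  Multi-year "average condition" layers average the
annual counts first (half-up rounding) and classify the mean.  Species-level
masking restricts a hydroperiod layer to pixels that carried water during a
species' annual-cycle months.
"""

from __future__ import annotations

import logging

import numpy as np

from .grids import (
    HYDRO_NONE,
    HYDRO_SEASONAL,
    HYDRO_SEMI_PERMANENT,
    HYDRO_TEMPORARY,
    AnnualCycle,
    HydroperiodGrid,
    MonthCountGrid,
    MonthlyWaterStack,
)

logger = logging.getLogger(__name__)

# Class bin upper edges (inclusive): count<=0 none, <=2 temporary, <=8
# seasonal, <=12 semi-permanent.  Counts of exactly 2 and 8 fall in the less
# persistent class so that "more than 8 months" reads literally.
_TEMPORARY_MAX = 2
_SEASONAL_MAX = 8


def count_inundated_months(stack: MonthlyWaterStack, year: int) -> MonthCountGrid:
    """Per-pixel number of inundated months (0–12) in one calendar year."""
    iy = stack.year_index(year)
    counts = stack.water[iy].sum(axis=0, dtype=np.int16)
    return MonthCountGrid(counts=counts, geometry=stack.geometry, window=str(year))


def classify_hydroperiod(counts: MonthCountGrid) -> HydroperiodGrid:
    """Bin month counts into hydroperiod classes."""
    c = counts.counts
    if c.min(initial=0) < 0 or c.max(initial=0) > 12:
        raise ValueError("month counts outside 0–12")
    classes = np.full(c.shape, HYDRO_SEMI_PERMANENT, dtype=np.uint8)
    classes[c <= _SEASONAL_MAX] = HYDRO_SEASONAL
    classes[c <= _TEMPORARY_MAX] = HYDRO_TEMPORARY
    classes[c == 0] = HYDRO_NONE
    return HydroperiodGrid(
        classes=classes, geometry=counts.geometry, provenance=counts.window
    )


def mean_annual_counts(
    stack: MonthlyWaterStack, year_range: tuple[int, int]
) -> MonthCountGrid:
    """Average annual month counts over an inclusive year window, rounded half up."""
    y0, y1 = year_range
    years = [y for y in range(y0, y1 + 1)]
    if not years:
        raise ValueError("empty year range")
    acc = np.zeros(stack.geometry.shape, dtype=float)
    for y in years:
        acc += count_inundated_months(stack, y).counts
    mean = acc / len(years)
    rounded = np.floor(mean + 0.5).astype(np.int16)  # ties at .5 round half up
    return MonthCountGrid(
        counts=rounded, geometry=stack.geometry, window=f"{y0}-{y1}"
    )


def mean_condition_hydroperiod(
    stack: MonthlyWaterStack, year_range: tuple[int, int]
) -> HydroperiodGrid:
    """Hydroperiod classes for average conditions over a multi-year window."""
    return classify_hydroperiod(mean_annual_counts(stack, year_range))


def cycle_water_mask(
    stack: MonthlyWaterStack,
    cycle: AnnualCycle,
    year_range: tuple[int, int],
    min_months: int = 1,
) -> np.ndarray:
    """Pixels that carried water during a species' annual-cycle months.

    A pixel is cycle-available if it was inundated in at least ``min_months``
    (cycle-month, year) layers over the window — the most inclusive reading
    by default.  Cycles that wrap the year end pair December of year *y* with
    January of *y + 1*; a wrapped month falling beyond the final stack year
    drops that pair with a log entry.
    """
    y0, y1 = year_range
    if y1 < y0:
        raise ValueError("empty year range")
    total = np.zeros(stack.geometry.shape, dtype=np.int32)
    offsets = cycle.month_offsets()
    for year in range(y0, y1 + 1):
        for month, offset in offsets:
            y = year + offset
            if y not in stack.years:
                logger.info(
                    "cycle %s/%s: dropping wrapped month %d of year %d (outside stack)",
                    cycle.species, cycle.label, month, y,
                )
                continue
            total += stack.grid(y, month)
    return total >= min_months


def cycle_hydroperiod(hydro: HydroperiodGrid, mask: np.ndarray) -> HydroperiodGrid:
    """Subset a hydroperiod layer to a species/annual-cycle water mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != hydro.classes.shape:
        raise ValueError("mask shape does not match hydroperiod grid")
    classes = np.where(mask, hydro.classes, HYDRO_NONE).astype(np.uint8)
    return HydroperiodGrid(
        classes=classes,
        geometry=hydro.geometry,
        provenance=f"{hydro.provenance} (cycle-masked)",
    )
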