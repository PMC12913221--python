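"""Two-period wetland availability trends within species distributions.

For each wetland variable deemed important to a species' abundance, a 40-year
annual series of mean monthly inundated area (hectares) is built within the
species' annual-cycle months, restricted to regions where estimated abundance
is positive.  The series is split into two equal 20-year periods — P1
(1984–2003) and P2 (2004–2023) by default — and compared with an unpaired
two-sided Wilcoxon rank-sum test; a change is called significant at p < 0.1.
Percent change is 100 · (P2 − P1) / P1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .grids import (
    COVARIATES,
    FUNC_CLASS_CODES,
    FUNC_RICE,
    AbundanceGrid,
    AnnualCycle,
    FunctionalGroupGrid,
    MonthlyWaterStack,
)
from .hydroperiod import classify_hydroperiod, count_inundated_months
from .importance import DepthResult
from .overlay import _HYDRO_COVARIATE_CODES

logger = logging.getLogger(__name__)

DEFAULT_P1 = (1984, 2003)
DEFAULT_P2 = (2004, 2023)

# exact rank-sum enumeration is used up to this many pooled observations
_EXACT_MAX_N = 12


@dataclass
class AnnualSeries:
    """Year → mean monthly inundated area (ha) for one variable × species × cycle."""

    variable: str
    species: str
    cycle: str
    values: pd.Series  # index: year

    def period_values(self, period: tuple[int, int]) -> np.ndarray:
        y0, y1 = period
        sel = self.values[(self.values.index >= y0) & (self.values.index <= y1)]
        return sel.to_numpy()


@dataclass
class TrendResult:
    variable: str
    species: str
    cycle: str
    p1_mean: float
    p2_mean: float
    pct_change: float  # NaN when P1 mean is zero
    wilcoxon_p: float
    significant: bool
    direction: str  # "decline" | "increase" | "none"
    pct_change_defined: bool = True


def fine_presence_mask(abundance: AbundanceGrid, coarse_factor: int,
                       fine_shape: tuple[int, int]) -> np.ndarray:
    """Expand the coarse abundance>0 mask to the fine grid."""
    coarse_mask = abundance.presence_mask()
    fine = np.kron(coarse_mask, np.ones((coarse_factor, coarse_factor), dtype=bool))
    return fine[: fine_shape[0], : fine_shape[1]]


def annual_cycle_series(
    stack: MonthlyWaterStack,
    variable: str,
    groups: FunctionalGroupGrid,
    cycle: AnnualCycle,
    mask_abundance: AbundanceGrid,
    coarse_factor: int,
) -> AnnualSeries:
    """Annual mean monthly area (ha) of one wetland variable within a cycle.

    Hydroperiod-class variables are re-derived each year from that year's
    month counts; functional-group labels are held fixed.  A pixel counts
    toward the variable in a given month when it is inundated that month,
    belongs to the variable's class, and lies in a coarse cell with positive
    abundance.  Cycle months that wrap past the final stack year drop that
    year from the series with a log entry.
    """
    if variable not in COVARIATES:
        raise KeyError(f"unknown wetland variable {variable!r}")
    fine_mask = fine_presence_mask(mask_abundance, coarse_factor, stack.geometry.shape)
    px_ha = stack.geometry.pixel_area_m2 / 10_000.0
    offsets = cycle.month_offsets()
    hydro_code = _HYDRO_COVARIATE_CODES.get(variable)
    rice = groups.labels == FUNC_RICE

    # per-pixel class membership, possibly year-dependent
    hydro_cache: dict[int, np.ndarray] = {}

    def member(year: int) -> np.ndarray:
        if variable == "wetland_area":
            return ~rice
        if hydro_code is not None:
            if year not in hydro_cache:
                classes = classify_hydroperiod(
                    count_inundated_months(stack, year)
                ).classes
                hydro_cache[year] = classes == hydro_code
            return hydro_cache[year]
        return groups.labels == FUNC_CLASS_CODES[variable]

    years: list[int] = []
    areas: list[float] = []
    for year in stack.years:
        monthly: list[float] = []
        complete = True
        for month, offset in offsets:
            y = year + offset
            if y not in stack.years:
                complete = False
                break
            wet = stack.grid(y, month).astype(bool)
            sel = wet & member(y) & fine_mask
            monthly.append(float(sel.sum()) * px_ha)
        if not complete:
            logger.info(
                "%s/%s %s: dropping year %d (wrapped cycle month beyond stack)",
                cycle.species, cycle.label, variable, year,
            )
            continue
        years.append(year)
        areas.append(float(np.mean(monthly)))
    return AnnualSeries(
        variable=variable,
        species=cycle.species,
        cycle=cycle.label,
        values=pd.Series(areas, index=pd.Index(years, name="year")),
    )


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided unpaired Wilcoxon rank-sum p-value.

    Small pooled samples are evaluated by exhaustive enumeration of rank
    assignments (midranks for ties); larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both periods must be non-empty")
    if n1 + n2 <= _EXACT_MAX_N:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n1].sum()
        mu = n1 * (n1 + n2 + 1) / 2.0
        d_obs = abs(w_obs - mu)
        count = 0
        total = 0
        for idx in combinations(range(n1 + n2), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= d_obs - 1e-12:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def period_compare(
    series: AnnualSeries,
    p1: tuple[int, int] = DEFAULT_P1,
    p2: tuple[int, int] = DEFAULT_P2,
    alpha: float = 0.1,
) -> TrendResult:
    """Compare mean annual availability between the two periods."""
    v1 = series.period_values(p1)
    v2 = series.period_values(p2)
    if len(v1) == 0 or len(v2) == 0:
        raise ValueError("both periods must contain data")
    p1_mean = float(v1.mean())
    p2_mean = float(v2.mean())
    p_value = rank_sum_test(v1, v2)
    if p1_mean == 0.0:
        pct = math.nan
        defined = False
    else:
        pct = 100.0 * (p2_mean - p1_mean) / p1_mean
        defined = True
    significant = bool(p_value < alpha)
    if not significant or not defined or pct == 0.0:
        direction = "none"
    else:
        direction = "decline" if pct < 0 else "increase"
    return TrendResult(
        variable=series.variable,
        species=series.species,
        cycle=series.cycle,
        p1_mean=p1_mean,
        p2_mean=p2_mean,
        pct_change=pct,
        wilcoxon_p=p_value,
        significant=significant,
        direction=direction,
        pct_change_defined=defined,
    )


def build_trend_report(
    results: dict[tuple[str, str], list[TrendResult]],
    importance: dict[tuple[str, str], DepthResult],
) -> pd.DataFrame:
    """Dot-matrix table: one row per species × cycle × variable.

    ``state`` is ``excluded`` for variables not classified important (they
    carry no trend numbers), otherwise ``decline`` / ``increase`` /
    ``stable``.
    """
    rows: list[dict] = []
    for key, trend_list in results.items():
        species, cycle_label = key
        if key not in importance:
            raise KeyError(f"missing importance result for {species}/{cycle_label}")
        important = importance[key].important_set()
        by_var = {t.variable: t for t in trend_list}
        for variable in COVARIATES:
            base = {
                "species": species,
                "cycle": cycle_label,
                "variable": variable,
            }
            if variable not in important:
                rows.append(
                    {**base, "state": "excluded", "pct_change": math.nan,
                     "wilcoxon_p": math.nan, "p1_mean_ha": math.nan,
                     "p2_mean_ha": math.nan}
                )
                continue
            t = by_var.get(variable)
            if t is None:
                raise KeyError(
                    f"important variable {variable!r} has no trend result "
                    f"for {species}/{cycle_label}"
                )
            state = t.direction if t.direction != "none" else "stable"
            rows.append(
                {**base, "state": state, "pct_change": t.pct_change,
                 "wilcoxon_p": t.wilcoxon_p, "p1_mean_ha": t.p1_mean,
                 "p2_mean_ha": t.p2_mean}
            )
    return pd.DataFrame(rows)
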