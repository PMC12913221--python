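"""Canned synthetic study scenarios used by tests, examples and the demo.

Two scenarios mirror the pipeline's two statistical claims:

* :func:`importance_scenario` plants abundance on three covariates
  (wetland area, semi-permanent wetlands, littoral saline-lake wetlands)
  over a landscape of thousands of mixed wetland complexes, for checking
  that the forest importance statistics recover the planted set.
* :func:`trend_scenario` plants a fractional P1→P2 decline in one
  functional wetland class's flood probability, for checking that the
  two-period rank-sum comparison recovers the planted change.

:func:`random_landscape` is the shared landscape builder: each coarse cell
receives a few disjoint wetland patches of random functional class, size and
hydroperiod, emulating the mixed wetland complexes of real basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import assemble_table, block_density
from .grids import (
    COVARIATES,
    AbundanceGrid,
    AnnualCycle,
    FunctionalGroupGrid,
    GridGeometry,
    MonthlyWaterStack,
)
from .hydroperiod import cycle_water_mask, mean_condition_hydroperiod
from .overlay import apply_deepwater_exclusion, build_covariate_layers
from .synth import (
    EffectSpec,
    LandscapeConfig,
    PatchSpec,
    SyntheticTruth,
    generate_abundance,
    generate_functional_grid,
    generate_water_stack,
    saline_lake_mask,
)

# raw patch classes (pre-exclusion): presence probability and hydroperiod
# range (months wet per year).  Functional classes draw broad hydroperiods
# (1–12) so that no single class concentrates in one persistence band; rice
# follows its cultivation calendar instead; lakes are the landscape's
# dominant persistent-water systems — deep perennial water bodies (9–12
# months, removed from functional labels by the deepwater exclusion) with
# drawdown fringes (1–8 months) that become littoral wetlands, mostly along
# saline closed-basin lakes.
_CLASS_SLOTS: dict[str, tuple[float, tuple[int, int]]] = {
    "estuary": (0.7, (1, 12)),
    "grass_hay": (0.7, (1, 12)),
    "managed": (0.7, (1, 12)),
    "palustrine": (0.7, (1, 12)),
    "pond": (0.7, (1, 12)),
    "rice": (0.8, (0, 0)),  # rice follows its cultivation calendar instead
    "lake": (0.85, (1, 12)),  # split deepwater/fringe in _class_profile
}
_LAKE_DEEPWATER_PROB = 0.55
_LAKE_SALINE_PROB = 0.75

_RICE_GROWING = (5, 6, 7, 8)  # May–Aug flooding for cultivation
_RICE_WINTER = (10, 11, 12, 1, 2)  # Oct–Feb post-harvest stubble flooding

#: all twelve months of the calendar year; used where a scenario needs the
#: full-year surface-water picture rather than one species' seasonal window
FULL_YEAR_CYCLE = AnnualCycle(species="any", label="full_year", months=tuple(range(1, 13)))


def _crisp_profile(months: np.ndarray | tuple[int, ...]) -> np.ndarray:
    profile = np.zeros(12)
    profile[np.asarray(months, dtype=int) - 1] = 1.0
    return profile


def _class_profile(cls: str, rng: np.random.Generator) -> np.ndarray:
    """Crisp 0/1 monthly flood profile drawn from the class's hydrology."""
    if cls == "rice":
        # growing-season flooding, winter flooding, or a drought-limited
        # partial winter flood; rice is never semi-permanent
        kind = rng.integers(0, 3)
        if kind == 0:
            return _crisp_profile(_RICE_GROWING)
        months = _RICE_WINTER if kind == 1 else _RICE_WINTER[:2]
        return _crisp_profile(months)
    if cls == "lake":
        if rng.random() < _LAKE_DEEPWATER_PROB:
            months_wet = int(rng.integers(9, 13))  # perennial deep water
        else:
            months_wet = int(rng.integers(1, 9))  # drawdown fringe
    else:
        lo, hi = _CLASS_SLOTS[cls][1]
        months_wet = int(rng.integers(lo, hi + 1))
    profile = np.zeros(12)
    profile[rng.choice(12, size=months_wet, replace=False)] = 1.0
    return profile


def random_landscape(
    seed: int,
    grid_height: int,
    grid_width: int,
    coarse_factor: int = 8,
    years: tuple[int, int] = (2008, 2022),
    fine_cell_size: float = 30.0,
    coherence: str = "coherent",
    class_trends: dict[str, float] | None = None,
    stochastic_profiles: bool = False,
) -> LandscapeConfig:
    """Landscape of mixed wetland complexes with independent class sub-patches.

    Every coarse block is divided into eight fixed slots, one per raw patch
    class; each class is present with its own probability and occupies a
    rectangle of random size inside its slot, so class areas vary
    independently across cells (no compositional coupling).  Lake patches
    are saline with probability one half.  ``class_trends`` plants a
    fractional P1→P2 flood-probability change on every patch of the named
    classes; ``stochastic_profiles`` scales the 0/1 monthly profiles by a
    random sub-unit probability so inundation is partial and trend ramps
    have headroom.
    """
    class_trends = class_trends or {}
    rng = np.random.default_rng(seed)
    f = coarse_factor
    classes = list(_CLASS_SLOTS)
    # slot layout per block: the lake system occupies the left column pair
    # (full block height); the six other classes share small slots in the
    # remaining 2-row x 3-column arrangement
    small_h, small_w = max(1, f // 2), max(1, (f - f // 4) // 3)
    lake_w = max(1, f // 4)
    slot_geom: dict[str, tuple[int, int, int]] = {}  # (dr, dc, max_height)
    small = [c for c in classes if c != "lake"]
    for i, cls in enumerate(small):
        slot_geom[cls] = ((i // 3) * small_h, lake_w + (i % 3) * small_w, small_h)
    slot_geom["lake"] = (0, 0, f)
    patches: list[PatchSpec] = []
    for br in range(grid_height // f):
        for bc in range(grid_width // f):
            for cls in classes:
                presence, _ = _CLASS_SLOTS[cls]
                dr, dc, max_h = slot_geom[cls]
                present = rng.random() < presence
                profile = _class_profile(cls, rng)
                if cls == "lake" and profile.sum() <= 8:
                    # drawdown fringes are narrow strips along the lake edge
                    max_h = max(1, f // 4)
                height = int(rng.integers(1, max_h + 1))
                saline = cls == "lake" and bool(rng.random() < _LAKE_SALINE_PROB)
                scale = float(rng.uniform(0.35, 0.85)) if stochastic_profiles else 1.0
                if not present:
                    continue
                r0, c0 = br * f + dr, bc * f + dc
                width = min(small_w if cls != "lake" else lake_w, grid_width - c0)
                if width <= 0 or r0 >= grid_height:
                    continue
                patches.append(
                    PatchSpec(
                        functional_class=cls,
                        footprint=("rect", r0, c0, height, width),
                        monthly_flood_profile=tuple(profile * scale),
                        trend=class_trends.get(cls, 0.0),
                        saline=saline,
                    )
                )
    return LandscapeConfig(
        grid_height=grid_height,
        grid_width=grid_width,
        fine_cell_size=fine_cell_size,
        coarse_factor=coarse_factor,
        years=years,
        patches=tuple(patches),
        seed=seed,
        coherence=coherence,
    )


def covariate_density_table(
    config: LandscapeConfig,
    cycle: AnnualCycle = FULL_YEAR_CYCLE,
    window: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, GridGeometry, MonthlyWaterStack, FunctionalGroupGrid]:
    """Run synth → hydroperiod → overlay → densify for one cycle.

    Returns the response-free feature table (one row per coarse cell, one
    hectare column per covariate) plus the intermediate products.
    """
    window = window or config.years
    stack = generate_water_stack(config)
    groups_raw = generate_functional_grid(config)
    hydro = mean_condition_hydroperiod(stack, window)
    groups = apply_deepwater_exclusion(groups_raw, hydro, saline_lake_mask(config))
    mask = cycle_water_mask(stack, cycle, window)
    layers = build_covariate_layers(groups, hydro, mask)
    densities = {
        name: block_density(layer, config.geometry, config.coarse_factor, name)
        for name, layer in layers.items()
    }
    coarse = config.geometry.coarsened(config.coarse_factor)
    zero_abundance = AbundanceGrid(
        values=np.zeros(coarse.shape), geometry=coarse
    )
    table = assemble_table(densities, zero_abundance).drop(columns="abundance")
    return table, coarse, stack, groups


# planted generating model for the importance-recovery scenario: abundance
# responds to total wetland area, semi-permanent wetlands and littoral
# saline-lake wetlands — the study's three headline predictors
PLANTED_EFFECTS = (
    ("wetland_area", "linear", 1.0),
    ("semi_permanent", "linear", 1.0),
    ("littoral_saline", "saturating", 0.8),
)
NOISE_FRACTION = 0.25  # noise sd as a fraction of the planted signal sd


@dataclass
class ImportanceScenario:
    table: pd.DataFrame  # feature table with abundance response
    truth: SyntheticTruth
    signal_sd: float
    noise_sd: float


def importance_scenario(
    seed: int,
    grid_height: int = 400,
    grid_width: int = 400,
    coarse_factor: int = 8,
    species: str = "synthetic_waterbird",
    cycle_label: str = "breeding",
) -> ImportanceScenario:
    """Landscape + abundance with three planted covariates out of twelve.

    Defaults give a 50 × 50 coarse grid (2500 cells).  Noise is Gaussian
    with sd equal to 25% of the planted signal sd.
    """
    config = random_landscape(
        seed=seed,
        grid_height=grid_height,
        grid_width=grid_width,
        coarse_factor=coarse_factor,
        years=(2008, 2008),
    )
    table, coarse, _, _ = covariate_density_table(config)

    # measure the planted signal's spread to set the 25% noise level
    probe = EffectSpec(
        species=species, cycle=cycle_label, effects=PLANTED_EFFECTS, noise_sd=0.0
    )
    noiseless = generate_abundance(table, coarse, probe, seed=seed)
    signal = noiseless.values[table["row"], table["col"]]
    signal_sd = float(signal.std())
    noise_sd = NOISE_FRACTION * signal_sd

    truth = SyntheticTruth(seed=seed)
    effect = EffectSpec(
        species=species, cycle=cycle_label, effects=PLANTED_EFFECTS, noise_sd=noise_sd
    )
    abundance = generate_abundance(table, coarse, effect, seed=seed + 1, truth=truth)
    out = table.copy()
    out["abundance"] = abundance.values[table["row"], table["col"]]
    return ImportanceScenario(
        table=out, truth=truth, signal_sd=signal_sd, noise_sd=noise_sd
    )


@dataclass
class TrendScenario:
    config: LandscapeConfig
    stack: MonthlyWaterStack
    groups: FunctionalGroupGrid
    abundance: AbundanceGrid
    truth: SyntheticTruth
    trended_variable: str
    stationary_variables: tuple[str, ...]


def trend_scenario(
    seed: int,
    trend: float = -0.30,
    grid_height: int = 100,
    grid_width: int = 100,
    coarse_factor: int = 10,
    years: tuple[int, int] = (1984, 2023),
) -> TrendScenario:
    """40-year landscape with one declining functional class.

    Managed wetlands carry the planted flood-probability ramp; palustrine
    wetlands and ponds are stationary controls.  Inundation is realized
    per pixel (``independent`` mode) so annual areas vary smoothly, and the
    species is present everywhere (abundance 1 in every coarse cell).
    """
    half = [0.5] * 12
    patches = (
        PatchSpec(
            functional_class="managed",
            footprint=("rect", 5, 5, 40, 40),
            monthly_flood_profile=tuple(half),
            trend=trend,
        ),
        PatchSpec(
            functional_class="palustrine",
            footprint=("rect", 50, 50, 30, 30),
            monthly_flood_profile=tuple(half),
        ),
        PatchSpec(
            functional_class="pond",
            footprint=("rect", 60, 10, 20, 20),
            monthly_flood_profile=tuple([0.4] * 12),
        ),
    )
    config = LandscapeConfig(
        grid_height=grid_height,
        grid_width=grid_width,
        coarse_factor=coarse_factor,
        years=years,
        patches=patches,
        seed=seed,
        coherence="independent",
    )
    stack = generate_water_stack(config)
    groups = generate_functional_grid(config)
    coarse = config.geometry.coarsened(coarse_factor)
    abundance = AbundanceGrid(
        values=np.ones(coarse.shape), geometry=coarse,
        species="synthetic_waterbird", cycle="full_year",
    )
    truth = SyntheticTruth(planted_trends={"managed": trend}, seed=seed)
    return TrendScenario(
        config=config,
        stack=stack,
        groups=groups,
        abundance=abundance,
        truth=truth,
        trended_variable="managed",
        stationary_variables=("palustrine", "pond"),
    )
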