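"""Seeded synthetic wetland landscapes with known planted structure.

Every downstream stage of the pipeline (hydroperiod classification, covariate
densification, forest importance, two-period trends) is validated against
landscapes generated here, where the generating process — which covariates
drive abundance, and which wetland patches dry out between periods — is
recorded as ground truth.

A landscape is a set of wetland patches on a fine grid.  Each patch carries a
functional class, a 12-month flood-probability profile, and an optional
long-term trend expressed as the fractional change in flood probability
between the first and second halves of the year range (applied as a linear
ramp, mimicking gradual drying rather than a step).  Monthly inundation is
realized as Bernoulli draws: one draw per patch-month in ``coherent`` mode
(crisp hydroperiod classes, like managed wetland units that flood as a
block), or one draw per pixel-month in ``independent`` mode (speckled
inundation with smoothly varying areas).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import (
    FUNC_CLASS_CODES,
    FUNC_NONE,
    AbundanceGrid,
    FunctionalGroupGrid,
    GridGeometry,
    MonthlyWaterStack,
)

EFFECT_SHAPES = ("linear", "saturating", "exponential")


@dataclass(frozen=True)
class PatchSpec:
    """One wetland patch: class, footprint, flood profile, long-term trend."""

    functional_class: str
    footprint: tuple  # ("rect", row0, col0, height, width) or ("disc", row, col, radius)
    monthly_flood_profile: tuple[float, ...]
    trend: float = 0.0
    saline: bool = False
    target_hydroperiod: int | None = None

    def __post_init__(self) -> None:
        if self.functional_class not in FUNC_CLASS_CODES:
            raise ValueError(f"unknown functional class {self.functional_class!r}")
        if self.functional_class == "none":
            raise ValueError("patches must carry a wetland class")
        if len(self.monthly_flood_profile) != 12:
            raise ValueError("monthly_flood_profile needs 12 entries")
        if any(not 0.0 <= p <= 1.0 for p in self.monthly_flood_profile):
            raise ValueError("flood probabilities must lie in [0, 1]")
        if self.footprint[0] not in ("rect", "disc"):
            raise ValueError("footprint kind must be 'rect' or 'disc'")
        if self.target_hydroperiod is not None:
            expected = float(sum(self.monthly_flood_profile))
            if abs(expected - self.target_hydroperiod) > 1.0:
                raise ValueError(
                    "expected annual inundated months "
                    f"({expected:.2f}) inconsistent with target hydroperiod "
                    f"{self.target_hydroperiod}"
                )

    def mask(self, geometry: GridGeometry) -> np.ndarray:
        m = np.zeros(geometry.shape, dtype=bool)
        if self.footprint[0] == "rect":
            _, r0, c0, h, w = self.footprint
            m[r0 : r0 + h, c0 : c0 + w] = True
        else:
            _, cr, cc, radius = self.footprint
            rr, cc_ = np.ogrid[: geometry.height, : geometry.width]
            m[(rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2] = True
        return m

    def slices(self) -> tuple[slice, slice] | None:
        """Index slices for rectangular footprints (fast path); None for discs."""
        if self.footprint[0] != "rect":
            return None
        _, r0, c0, h, w = self.footprint
        return slice(r0, r0 + h), slice(c0, c0 + w)

    def pixel_count(self, geometry: GridGeometry) -> int:
        sl = self.slices()
        if sl is None:
            return int(self.mask(geometry).sum())
        rs, cs = sl
        h = max(0, min(rs.stop, geometry.height) - rs.start)
        w = max(0, min(cs.stop, geometry.width) - cs.start)
        return h * w


@dataclass(frozen=True)
class LandscapeConfig:
    """Frame of a synthetic study landscape."""

    grid_height: int
    grid_width: int
    fine_cell_size: float = 30.0
    coarse_factor: int = 83  # ~2.5 km coarse cells over 30 m pixels
    years: tuple[int, int] = (1984, 2023)
    patches: tuple[PatchSpec, ...] = ()
    seed: int = 0
    coherence: str = "coherent"  # or "independent"

    def __post_init__(self) -> None:
        if self.coarse_factor < 1:
            raise ValueError("coarse_factor must be >= 1")
        if self.years[1] < self.years[0]:
            raise ValueError("year range is empty")
        if self.coherence not in ("coherent", "independent"):
            raise ValueError("coherence must be 'coherent' or 'independent'")
        GridGeometry(self.grid_height, self.grid_width, self.fine_cell_size)

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(self.grid_height, self.grid_width, self.fine_cell_size)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))


@dataclass(frozen=True)
class EffectSpec:
    """Planted covariate → abundance relationship for one species × cycle."""

    species: str
    cycle: str
    effects: tuple[tuple[str, str, float], ...]  # (covariate, shape, magnitude)
    noise_sd: float = 0.0
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if not self.effects:
            raise ValueError("at least one active covariate is required")
        for _, shape, _ in self.effects:
            if shape not in EFFECT_SHAPES:
                raise ValueError(f"unknown effect shape {shape!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")

    @property
    def active_covariates(self) -> set[str]:
        return {cov for cov, _, _ in self.effects}


@dataclass
class SyntheticTruth:
    """Ground truth planted into a synthetic scenario."""

    planted_important: dict = field(default_factory=dict)  # (species, cycle) -> set
    planted_trends: dict = field(default_factory=dict)  # variable -> signed fraction
    seed: int = 0


def trend_multipliers(n_years: int, trend: float) -> np.ndarray:
    """Per-year flood-probability multipliers realizing a P1→P2 fractional change.

    A linear ramp scaled so the mean multiplier over the first half of the
    years is exactly 1 and over the second half exactly ``1 + trend``.
    """
    if trend == 0.0 or n_years == 1:
        return np.ones(n_years)
    x = np.arange(n_years) / (n_years - 1)
    n1 = n_years // 2
    x1, x2 = x[:n1].mean(), x[n1:].mean()
    denom = x2 - x1 - trend * x1
    if denom <= 0:
        raise ValueError(f"trend {trend} not realizable as a linear ramp")
    s = trend / denom
    m = 1.0 + s * x
    return m / (1.0 + s * x1)


def _check_overlaps(config: LandscapeConfig) -> np.ndarray:
    """Claimed-class grid; error on overlapping patches of conflicting classes."""
    geom = config.geometry
    claimed = np.zeros(geom.shape, dtype=np.int16)  # class code or 0
    for patch in config.patches:
        code = FUNC_CLASS_CODES[patch.functional_class]
        sl = patch.slices()
        region = claimed[sl] if sl is not None else claimed[patch.mask(geom)]
        if np.any((region != 0) & (region != code)):
            raise ValueError(
                f"patch of class {patch.functional_class!r} overlaps a patch "
                "of a different class"
            )
        if sl is not None:
            claimed[sl] = code
        else:
            claimed[patch.mask(geom)] = code
    return claimed


def generate_water_stack(config: LandscapeConfig) -> MonthlyWaterStack:
    """Realize monthly binary inundation for every (year, month) layer."""
    geom = config.geometry
    _check_overlaps(config)
    years = config.year_list
    n_years = len(years)
    rng = np.random.default_rng(config.seed)
    water = np.zeros((n_years, 12, geom.height, geom.width), dtype=np.uint8)
    for patch in config.patches:
        mult = trend_multipliers(n_years, patch.trend)
        profile = np.asarray(patch.monthly_flood_profile)
        p = np.clip(profile[None, :] * mult[:, None], 0.0, 1.0)  # (years, 12)
        sl = patch.slices()
        if config.coherence == "coherent":
            wet = (rng.random((n_years, 12)) < p).astype(np.uint8)
            if sl is not None:
                water[:, :, sl[0], sl[1]] |= wet[:, :, None, None]
            else:
                water[:, :, patch.mask(geom)] |= wet[:, :, None]
        else:
            npix = patch.pixel_count(geom)
            draws = (rng.random((n_years, 12, npix)) < p[:, :, None]).astype(np.uint8)
            if sl is not None:
                h = max(0, min(sl[0].stop, geom.height) - sl[0].start)
                w = max(0, min(sl[1].stop, geom.width) - sl[1].start)
                water[:, :, sl[0], sl[1]] |= draws.reshape(n_years, 12, h, w)
            else:
                water[:, :, patch.mask(geom)] |= draws
    return MonthlyWaterStack(water=water, years=years, geometry=geom)


def generate_functional_grid(config: LandscapeConfig) -> FunctionalGroupGrid:
    """Label every patch pixel with its functional class; background is none."""
    geom = config.geometry
    claimed = _check_overlaps(config)
    labels = claimed.astype(np.uint8)
    labels[claimed == 0] = FUNC_NONE
    return FunctionalGroupGrid(labels=labels, geometry=geom)


def saline_lake_mask(config: LandscapeConfig) -> np.ndarray:
    """Pixels belonging to lake patches flagged saline (e.g. Great Salt Lake)."""
    geom = config.geometry
    m = np.zeros(geom.shape, dtype=bool)
    for patch in config.patches:
        if patch.functional_class == "lake" and patch.saline:
            m |= patch.mask(geom)
    return m


def _shape_response(x: np.ndarray, shape: str) -> np.ndarray:
    """Monotone effect shape normalized to [0, 1] over the observed range."""
    xmax = float(np.max(x)) if x.size else 0.0
    if xmax <= 0:
        return np.zeros_like(x, dtype=float)
    u = np.asarray(x, dtype=float) / xmax
    if shape == "linear":
        return u
    if shape == "saturating":
        return -np.expm1(-3.0 * u) / -np.expm1(-3.0)
    if shape == "exponential":
        return np.expm1(3.0 * u) / np.expm1(3.0)
    raise ValueError(f"unknown effect shape {shape!r}")


def generate_abundance(
    covariates: pd.DataFrame,
    geometry: GridGeometry,
    effect: EffectSpec,
    seed: int,
    truth: SyntheticTruth | None = None,
) -> AbundanceGrid:
    """Coarse abundance surface as a monotone function of covariate densities.

    ``covariates`` is a feature table without its response: one row per coarse
    cell with ``row``/``col`` position columns and one column per covariate
    density.  Abundance is the sum of the planted effect shapes plus Gaussian
    noise, truncated at zero, with a fraction of cells forced to zero.
    """
    missing = effect.active_covariates - set(covariates.columns)
    if missing:
        raise KeyError(f"unknown covariates in effect spec: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    signal = np.zeros(len(covariates), dtype=float)
    for cov, shape, magnitude in effect.effects:
        signal += magnitude * _shape_response(covariates[cov].to_numpy(), shape)
    values = signal.copy()
    if effect.noise_sd > 0:
        values = values + rng.normal(0.0, effect.noise_sd, size=len(values))
    values = np.clip(values, 0.0, None)
    if effect.zero_inflation > 0:
        zeros = rng.random(len(values)) < effect.zero_inflation
        values[zeros] = 0.0
    grid = np.zeros(geometry.shape, dtype=float)
    grid[covariates["row"].to_numpy(), covariates["col"].to_numpy()] = values
    if truth is not None:
        truth.planted_important[(effect.species, effect.cycle)] = set(
            effect.active_covariates
        )
    return AbundanceGrid(
        values=grid, geometry=geometry, species=effect.species, cycle=effect.cycle
    )
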