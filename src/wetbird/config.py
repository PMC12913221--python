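"""Run configuration: species annual cycles, landscape specs, YAML loading.

A single YAML file drives the whole pipeline.  The bundled defaults give each
of six representative waterbird species four annual cycles (breeding,
post-breeding migration, nonbreeding, pre-breeding migration) expressed as
calendar months, some wrapping the year end (e.g. nonbreeding Dec–Jan).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .grids import CYCLE_LABELS, AnnualCycle
from .synth import EffectSpec, LandscapeConfig, PatchSpec

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


def parse_month_span(text: str) -> tuple[int, ...]:
    """Parse 'Jun' or 'Dec-Jan' / 'Nov–Feb' into an ordered month tuple.

    Spans that run past December wrap into the next calendar year:
    'Nov-Feb' → (11, 12, 1, 2).
    """
    text = text.strip().replace("–", "-")
    parts = [p.strip().lower()[:3] for p in text.split("-")]
    if any(p not in _MONTHS for p in parts):
        raise ValueError(f"unparseable month span {text!r}")
    if len(parts) == 1:
        return (_MONTHS[parts[0]],)
    if len(parts) != 2:
        raise ValueError(f"unparseable month span {text!r}")
    start, end = _MONTHS[parts[0]], _MONTHS[parts[1]]
    months = [start]
    m = start
    while m != end:
        m = m % 12 + 1
        months.append(m)
        if len(months) > 12:
            raise ValueError(f"month span {text!r} does not terminate")
    return tuple(months)


def default_cycles_path() -> Path:
    return Path(str(resources.files("wetbird").joinpath("data/cycles.csv")))


def load_cycles(path: str | Path | None = None) -> list[AnnualCycle]:
    """Load species annual-cycle definitions from a CSV table.

    The table has a ``species`` column plus one column per cycle label,
    holding month spans like ``Jun`` or ``Dec-Jan``.  The bundled default
    covers the six study species.
    """
    src = Path(path) if path is not None else default_cycles_path()
    frame = pd.read_csv(src)
    if frame.empty or "species" not in frame.columns:
        raise ValueError(f"cycle table {src} is empty or lacks a species column")
    cycles: list[AnnualCycle] = []
    seen: set[tuple[str, str]] = set()
    for _, row in frame.iterrows():
        for label in CYCLE_LABELS:
            if label not in frame.columns or pd.isna(row[label]):
                continue
            key = (row["species"], label)
            if key in seen:
                raise ValueError(f"duplicate cycle {label!r} for {row['species']!r}")
            seen.add(key)
            cycles.append(
                AnnualCycle(
                    species=row["species"],
                    label=label,
                    months=parse_month_span(str(row[label])),
                )
            )
    if not cycles:
        raise ValueError(f"no cycles parsed from {src}")
    return cycles


@dataclass(frozen=True)
class SpeciesSpec:
    """Planted abundance model for one species in a synthetic run."""

    name: str
    effects: tuple[tuple[str, str, float], ...]  # (covariate, shape, magnitude)
    noise_sd: float = 0.1
    zero_inflation: float = 0.0
    absent_cycles: tuple[str, ...] = ()  # cycles with no abundance in the frame

    def effect_spec(self, cycle: str) -> EffectSpec:
        return EffectSpec(
            species=self.name,
            cycle=cycle,
            effects=self.effects,
            noise_sd=self.noise_sd,
            zero_inflation=self.zero_inflation,
        )


@dataclass(frozen=True)
class ImportanceSettings:
    n_tree_grid: tuple[int, ...] = (1000, 1500, 2000)
    n_subsamples: int = 0  # 0 disables subsampling CIs
    alpha: float = 0.05
    subsample_fraction: float = 0.632
    mtry: int | None = None
    node_size: int = 5


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a pipeline run bit-for-bit."""

    landscape: LandscapeConfig
    species: tuple[SpeciesSpec, ...]
    cycles_path: str | None = None
    hydro_window: tuple[int, int] = (2008, 2022)
    period1: tuple[int, int] = (1984, 2003)
    period2: tuple[int, int] = (2004, 2023)
    trend_alpha: float = 0.1
    importance: ImportanceSettings = field(default_factory=ImportanceSettings)
    seed: int = 0
    output_dir: str = "wetbird_out"

    def __post_init__(self) -> None:
        if self.period1[1] >= self.period2[0]:
            raise ValueError("periods must be disjoint")
        if (self.period1[1] - self.period1[0]) != (self.period2[1] - self.period2[0]):
            raise ValueError("periods must be equal length")


def _patch_from_dict(d: dict) -> PatchSpec:
    fp = d["footprint"]
    return PatchSpec(
        functional_class=d["functional_class"],
        footprint=tuple(fp),
        monthly_flood_profile=tuple(d["monthly_flood_profile"]),
        trend=float(d.get("trend", 0.0)),
        saline=bool(d.get("saline", False)),
        target_hydroperiod=d.get("target_hydroperiod"),
    )


def load_run_config(path: str | Path, seed_override: int | None = None) -> RunConfig:
    """Load a pipeline configuration from YAML."""
    raw = yaml.safe_load(Path(path).read_text())
    land = raw["landscape"]
    seed = int(seed_override if seed_override is not None else raw.get("seed", 0))
    if "random_patches" in land:
        from .scenarios import random_landscape

        rp = land["random_patches"]
        landscape = random_landscape(
            seed=seed,
            grid_height=int(land["grid_height"]),
            grid_width=int(land["grid_width"]),
            coarse_factor=int(land.get("coarse_factor", 83)),
            years=tuple(land.get("years", (1984, 2023))),
            fine_cell_size=float(land.get("fine_cell_size", 30.0)),
            coherence=land.get("coherence", "independent"),
            class_trends={k: float(v) for k, v in rp.get("class_trends", {}).items()},
            stochastic_profiles=bool(rp.get("stochastic_profiles", False)),
        )
    else:
        landscape = LandscapeConfig(
            grid_height=int(land["grid_height"]),
            grid_width=int(land["grid_width"]),
            fine_cell_size=float(land.get("fine_cell_size", 30.0)),
            coarse_factor=int(land.get("coarse_factor", 83)),
            years=tuple(land.get("years", (1984, 2023))),
            patches=tuple(_patch_from_dict(p) for p in land.get("patches", ())),
            seed=seed,
            coherence=land.get("coherence", "coherent"),
        )
    species = tuple(
        SpeciesSpec(
            name=s["name"],
            effects=tuple(
                (e["covariate"], e.get("shape", "linear"), float(e.get("magnitude", 1.0)))
                for e in s["effects"]
            ),
            noise_sd=float(s.get("noise_sd", 0.1)),
            zero_inflation=float(s.get("zero_inflation", 0.0)),
            absent_cycles=tuple(s.get("absent_cycles", ())),
        )
        for s in raw["species"]
    )
    imp = raw.get("importance", {})
    settings = ImportanceSettings(
        n_tree_grid=tuple(imp.get("n_tree_grid", (1000, 1500, 2000))),
        n_subsamples=int(imp.get("n_subsamples", 0)),
        alpha=float(imp.get("alpha", 0.05)),
        subsample_fraction=float(imp.get("subsample_fraction", 0.632)),
        mtry=imp.get("mtry"),
        node_size=int(imp.get("node_size", 5)),
    )
    return RunConfig(
        landscape=landscape,
        species=species,
        cycles_path=raw.get("cycles_path"),
        hydro_window=tuple(raw.get("hydro_window", (2008, 2022))),
        period1=tuple(raw.get("period1", (1984, 2003))),
        period2=tuple(raw.get("period2", (2004, 2023))),
        trend_alpha=float(raw.get("trend_alpha", 0.1)),
        importance=settings,
        seed=seed,
        output_dir=raw.get("output_dir", "wetbird_out"),
    )
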