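"""End-to-end orchestration: synth → hydroperiod → overlay → features →
importance → trends, with a run manifest for bit-for-bit reproducibility.

Stage outputs are written under the configured output directory:

* ``hydroperiod.tif`` — average-condition hydroperiod classes
* ``functional_groups.tif`` — post-exclusion functional labels
* ``feature_table_<species>_<cycle>.csv`` — forest training tables
* ``vimp.csv`` / ``minimal_depth.csv`` — importance statistics
* ``trends.csv`` — annual-series period comparisons (important variables)
* ``trend_report.csv`` + ``dot_matrix.png`` — the species × cycle × variable
  decline/increase/excluded matrix
* ``manifest.json`` — config hash, seeds, timings, output inventory
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, load_cycles
from .features import assemble_table, block_density
from .grids import COVARIATES, AbundanceGrid, AnnualCycle
from .hydroperiod import cycle_water_mask, mean_condition_hydroperiod
from .importance import (
    DepthResult,
    minimal_depth,
    permutation_vimp,
    tune_and_fit,
    vimp_subsample_ci,
)
from .io import write_functional, write_hydroperiod, write_table, write_water_stack
from .overlay import apply_deepwater_exclusion, build_covariate_layers
from .synth import (
    SyntheticTruth,
    generate_abundance,
    generate_functional_grid,
    generate_water_stack,
    saline_lake_mask,
)
from .trends import TrendResult, annual_cycle_series, build_trend_report, period_compare

logger = logging.getLogger(__name__)

STAGES = ("synth", "hydroperiod", "features", "importance", "trends")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stage_seconds: dict[str, float] = field(default_factory=dict)
    species_cycle_seeds: dict[str, int] = field(default_factory=dict)
    skipped_cycles: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "seed": self.seed,
                "stage_seconds": {k: round(v, 3) for k, v in self.stage_seconds.items()},
                "species_cycle_seeds": self.species_cycle_seeds,
                "skipped_cycles": self.skipped_cycles,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(repr(config).encode()).hexdigest()[:16]


def _derived_seeds(seed: int, keys: list[str]) -> dict[str, int]:
    """Stable per-key seeds below 2**31, derived from the master seed."""
    return {
        k: int.from_bytes(
            hashlib.sha256(f"{seed}:{k}".encode()).digest()[:4], "big"
        ) % (2**31 - 1)
        for k in keys
    }


def _dot_matrix_figure(report: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = sorted(
        {(s, c) for s, c in zip(report["species"], report["cycle"])}
    )
    row_pos = {rc: i for i, rc in enumerate(rows)}
    col_pos = {v: j for j, v in enumerate(COVARIATES)}
    colors = {
        "decline": "#c0392b",
        "increase": "#2471a3",
        "stable": "#1e8449",
        "excluded": "#bdbdbd",
    }
    fig, ax = plt.subplots(
        figsize=(0.7 * len(col_pos) + 3, 0.45 * len(rows) + 2)
    )
    for _, r in report.iterrows():
        ax.scatter(
            col_pos[r["variable"]],
            row_pos[(r["species"], r["cycle"])],
            s=110,
            color=colors.get(r["state"], "#000000"),
        )
    ax.set_xticks(range(len(col_pos)), list(col_pos), rotation=60, ha="right")
    ax.set_yticks(range(len(rows)), [f"{s} · {c}" for s, c in rows], fontsize=8)
    ax.set_title("Wetland variable trends by species × annual cycle")
    ax.invert_yaxis()
    handles = [
        plt.Line2D([], [], marker="o", ls="", color=c, label=lbl)
        for lbl, c in colors.items()
    ]
    ax.legend(handles=handles, loc="upper left", bbox_to_anchor=(1.01, 1.0))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _vimp_heatmap_figure(vimp: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = vimp.pivot_table(
        index=["species", "cycle"], columns="covariate", values="vimp", sort=False
    ).reindex(columns=[c for c in COVARIATES])
    fig, ax = plt.subplots(
        figsize=(0.75 * len(pivot.columns) + 3, 0.4 * len(pivot) + 2)
    )
    im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=60, ha="right")
    ax.set_yticks(range(len(pivot)), [f"{s} · {c}" for s, c in pivot.index], fontsize=8)
    fig.colorbar(im, ax=ax, label="permutation VIMP")
    ax.set_title("Variable importance by species × annual cycle")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, write_stack: bool = False) -> RunManifest:
    """Run every stage and write all outputs; reruns are byte-identical."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), version=__version__, seed=config.seed
    )

    def _record(path: Path) -> Path:
        manifest.outputs.append(path.name)
        return path

    cycles = load_cycles(config.cycles_path)
    species_by_name = {s.name: s for s in config.species}
    cycles = [c for c in cycles if c.species in species_by_name]
    if not cycles:
        raise ValueError("no annual cycles match the configured species")
    keys = [f"{c.species}/{c.label}" for c in cycles]
    seeds = _derived_seeds(config.seed, keys)
    manifest.species_cycle_seeds = seeds

    # --- synth ---------------------------------------------------------
    t0 = time.perf_counter()
    stack = generate_water_stack(config.landscape)
    groups_raw = generate_functional_grid(config.landscape)
    saline = saline_lake_mask(config.landscape)
    if write_stack:
        write_water_stack(_record(out / "water_stack.npy"), stack)
    manifest.stage_seconds["synth"] = time.perf_counter() - t0

    # --- hydroperiod ---------------------------------------------------
    t0 = time.perf_counter()
    hydro = mean_condition_hydroperiod(stack, config.hydro_window)
    groups = apply_deepwater_exclusion(groups_raw, hydro, saline)
    write_hydroperiod(_record(out / "hydroperiod.tif"), hydro)
    write_functional(_record(out / "functional_groups.tif"), groups)
    manifest.stage_seconds["hydroperiod"] = time.perf_counter() - t0

    # --- features ------------------------------------------------------
    t0 = time.perf_counter()
    geometry = config.landscape.geometry
    factor = config.landscape.coarse_factor
    coarse = geometry.coarsened(factor)
    truth = SyntheticTruth(seed=config.seed)
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    abundances: dict[tuple[str, str], AbundanceGrid] = {}
    for cycle in cycles:
        key = f"{cycle.species}/{cycle.label}"
        spec = species_by_name[cycle.species]
        if cycle.label in spec.absent_cycles:
            logger.info("skipping %s: species absent from the study frame", key)
            manifest.skipped_cycles.append(key)
            continue
        mask = cycle_water_mask(stack, cycle, config.hydro_window)
        layers = build_covariate_layers(groups, hydro, mask)
        densities = {
            name: block_density(layer, geometry, factor, name)
            for name, layer in layers.items()
        }
        blank = AbundanceGrid(
            np.zeros(coarse.shape), coarse, cycle.species, cycle.label
        )
        bare = assemble_table(densities, blank).drop(columns="abundance")
        abundance = generate_abundance(
            bare, coarse, spec.effect_spec(cycle.label), seeds[key], truth
        )
        table = bare.copy()
        table["abundance"] = abundance.values[bare["row"], bare["col"]]
        if np.ptp(table["abundance"].to_numpy()) == 0.0:
            logger.info("skipping %s: constant abundance in the frame", key)
            manifest.skipped_cycles.append(key)
            continue
        tables[(cycle.species, cycle.label)] = table
        abundances[(cycle.species, cycle.label)] = abundance
        write_table(
            _record(out / f"feature_table_{cycle.species}_{cycle.label}.csv"), table
        )
    truth_path = _record(out / "truth.json")
    truth_path.write_text(
        json.dumps(
            {
                "planted_important": {
                    f"{s}/{c}": sorted(v)
                    for (s, c), v in truth.planted_important.items()
                },
                "planted_trends": {
                    p.functional_class: p.trend
                    for p in config.landscape.patches
                    if p.trend != 0.0
                },
                "seed": config.seed,
            },
            indent=2,
            sort_keys=True,
        )
    )
    manifest.stage_seconds["features"] = time.perf_counter() - t0

    # --- importance ----------------------------------------------------
    t0 = time.perf_counter()
    imp = config.importance
    depth_results: dict[tuple[str, str], DepthResult] = {}
    vimp_rows: list[dict] = []
    depth_rows: list[dict] = []
    for (species, label), table in tables.items():
        key = f"{species}/{label}"
        model = tune_and_fit(
            table,
            n_tree_grid=imp.n_tree_grid,
            seed=seeds[key],
            mtry=imp.mtry,
            node_size=imp.node_size,
        )
        if imp.n_subsamples > 0:
            ci = vimp_subsample_ci(
                table,
                n_subsamples=imp.n_subsamples,
                alpha=imp.alpha,
                subsample_fraction=imp.subsample_fraction,
                seed=seeds[key],
                n_trees=model.n_trees,
                mtry=imp.mtry,
                node_size=imp.node_size,
            )
            vtab = ci.table
        else:
            vimp = permutation_vimp(model, table, seed=seeds[key])
            vtab = pd.DataFrame(
                {
                    "covariate": vimp.index,
                    "vimp": vimp.to_numpy(),
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "rank": vimp.rank(ascending=False, method="min").astype(int),
                }
            )
        depth = minimal_depth(model)
        depth_results[(species, label)] = depth
        for _, r in vtab.iterrows():
            vimp_rows.append(
                {"species": species, "cycle": label, "n_trees": model.n_trees,
                 "oob_error": model.oob_error, **r.to_dict()}
            )
        for cov in depth.depths.index:
            depth_rows.append(
                {
                    "species": species,
                    "cycle": label,
                    "covariate": cov,
                    "minimal_depth": depth.depths[cov],
                    "threshold": depth.threshold,
                    "important": bool(depth.important[cov]),
                }
            )
    vimp_frame = pd.DataFrame(vimp_rows)
    write_table(_record(out / "vimp.csv"), vimp_frame)
    write_table(_record(out / "minimal_depth.csv"), pd.DataFrame(depth_rows))
    if not vimp_frame.empty:
        _vimp_heatmap_figure(vimp_frame, _record(out / "vimp_scores.png"))
    manifest.stage_seconds["importance"] = time.perf_counter() - t0

    # --- trends --------------------------------------------------------
    t0 = time.perf_counter()
    cycle_by_key = {(c.species, c.label): c for c in cycles}
    trend_results: dict[tuple[str, str], list[TrendResult]] = {}
    for key, depth in depth_results.items():
        cyc = cycle_by_key[key]
        results: list[TrendResult] = []
        for variable in sorted(depth.important_set(), key=COVARIATES.index):
            series = annual_cycle_series(
                stack, variable, groups, cyc, abundances[key], factor
            )
            results.append(
                period_compare(
                    series, config.period1, config.period2, config.trend_alpha
                )
            )
        trend_results[key] = results
    trend_rows = [
        {
            "species": t.species, "cycle": t.cycle, "variable": t.variable,
            "p1_mean_ha": t.p1_mean, "p2_mean_ha": t.p2_mean,
            "pct_change": t.pct_change, "wilcoxon_p": t.wilcoxon_p,
            "significant": t.significant, "direction": t.direction,
        }
        for results in trend_results.values()
        for t in results
    ]
    write_table(_record(out / "trends.csv"), pd.DataFrame(trend_rows))
    report = build_trend_report(trend_results, depth_results)
    write_table(_record(out / "trend_report.csv"), report)
    if not report.empty:
        _dot_matrix_figure(report, _record(out / "dot_matrix.png"))
    manifest.stage_seconds["trends"] = time.perf_counter() - t0

    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
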