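"""From fine-grid wetland layers to coarse-cell covariate densities.

Generates a random landscape of mixed wetland complexes, applies the
deepwater exclusion (perennial lake/river water removed, littoral fringes
kept), intersects everything with a full-year surface-water mask, and sums
each binary covariate layer into coarse cells as hectares.
"""

from wetbird.scenarios import FULL_YEAR_CYCLE, covariate_density_table, random_landscape

config = random_landscape(
    seed=5, grid_height=160, grid_width=160, coarse_factor=8, years=(2010, 2010)
)
table, coarse, stack, groups = covariate_density_table(config, FULL_YEAR_CYCLE)

print(f"coarse grid: {coarse.height} x {coarse.width} cells of "
      f"{coarse.cell_size:.0f} m -> {len(table)} table rows")
print()
print("mean covariate density (ha per coarse cell):")
covs = [c for c in table.columns if c not in ("cell_id", "row", "col")]
for name in covs:
    print(f"  {name:16s} {table[name].mean():7.3f}")
print()
print("wetland_area excludes cultivated rice; hydroperiod covariates")
print("(temporary/seasonal/semi_permanent) partition the wet pixels, so their")
print("means sum to roughly wetland_area plus the rice share.")
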