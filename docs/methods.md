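# Methods

This note documents the models and procedures implemented in `wetbird`, the
assumptions behind them, the tunable parameters and their defaults, what the
synthetic-data generator does and does not emulate, and the numerical
choices made where the design was genuinely open.

## Hydroperiod model

Hydroperiod — the annual duration of surface inundation — is computed per
30 m pixel by counting inundated months over January–December and binning
the count:

| count | class |
|---|---|
| 0 | none |
| 1–2 | temporary |
| 3–8 | seasonal |
| 9–12 | semi-permanent |

The verbal convention "temporary < 2, seasonal more than 2 but < 8,
semi-permanent more than 8" leaves counts of exactly 2 and 8 unassigned; we
assign each boundary count to the *less* persistent class so that "more than
8" is honored literally and the classes partition counts 1–12.  Two
invariants are enforced by tests: the three wet classes together cover
exactly the pixels with count ≥ 1, and raising a pixel's count never moves
it to a less persistent class.

Multi-year "average condition" layers average the annual counts per pixel
and round half up *before* classifying (average-then-classify, matching the
idea of classifying mean conditions; classify-then-vote would let a single
wet year flip boundary pixels).  Species/annual-cycle layers mask water to
the cycle's calendar months; a pixel is cycle-available if inundated in at
least one cycle month of the averaged window (the most inclusive reading —
the threshold is a parameter, `min_months`).  Cycles that wrap the year end
(e.g. nonbreeding December–January) pair December of year *y* with January
of year *y + 1*; a wrapped month falling beyond the last year of data drops
that year-pair and logs it.

## Functional groups and the deepwater exclusion

Functional wetland labels (estuary, grass-hay, littoral saline, littoral,
managed, palustrine, pond, rice, plus raw lake and riparian) are carried as
a categorical raster.  Reservoirs, natural lakes and river channels are
partially filtered: lake/riparian pixels with semi-permanent hydroperiod are
perennial deep water and are relabelled `none`; surviving lake fringe pixels
become `littoral` (or `littoral_saline` when the lake is flagged saline —
the saline flag is a per-patch attribute in synthetic data, standing in for
the geographic distinction of closed-basin saline lakes).  Surviving
riparian pixels are folded into `palustrine`: riparian is not one of the
model's twelve predictors, and non-deepwater river-margin wetlands behave
like unmanaged freshwater palustrine systems.  The exclusion is idempotent.

The twelve model covariates are: `wetland_area` (all wet pixels minus rice),
the three hydroperiod classes, and the eight functional groups — each
intersected with the species' cycle water mask.  `wetland_area ∪ rice`
equals the cycle mask exactly, and the hydroperiod covariates partition the
wet pixels within it.

## Densification

Fine binary layers are aggregated to the coarse abundance grid with a
non-overlapping block sum aligned to the coarse cells: each cell's value is
(number of true fine pixels inside it) × (fine pixel area).  A sliding
kernel would double-count area and break conservation; the block sum is
exact — total density equals total true area to the integer pixel count,
which the tests assert.  Values are m² internally, hectares in output
tables.  Fine dimensions need not divide evenly; partial edge cells keep
the pixels they contain.  No partial-pixel area weighting is attempted.

## Forest importance statistics

Abundance is regressed on the twelve covariate densities with a random
forest (scikit-learn backend; defaults `mtry = ⌈p/3⌉ = 4`, minimum node
size 5, tree count tuned over a grid — 1000–2000 by default — by out-of-bag
mean squared error).  The two decision statistics are implemented in this
package by walking tree structures directly, so they can be validated
against hand-built trees:

* **Permutation (Breiman–Cutler) VIMP.**  Per tree: squared error on the
  tree's out-of-bag rows, minus the same after permuting one covariate's
  out-of-bag values; averaged over trees.  Scores of unused covariates are
  ≈ 0 and may be slightly negative.
* **Minimal depth.**  Per tree, a covariate's minimal depth is the depth of
  its shallowest split (root = 0); a covariate absent from a tree is
  charged that tree's maximum node depth + 1, penalizing absence.  The
  per-covariate depths are averaged over trees, and the importance
  threshold is the mean of the per-covariate means (the "mean of the
  minimal depth distribution"; pooling per-covariate means rather than all
  per-tree depths is a documented choice — both pools have the same mean
  when every covariate appears in every tree, and the per-covariate pool is
  stable when some do not).  A covariate is *important* iff its mean depth
  is strictly below the threshold; a depth exactly at the threshold is not
  important.

Confidence intervals for VIMP use subsampling ("double bootstrap"):
`n_subsamples` forests (default 500, α = 0.05) are refit on subsamples
drawn **without replacement** at fraction 0.632 (configurable), and the CI
is the full-data point estimate ± z·SE with the delete-d jackknife variance
`(m/(n−m)) · var_b(vimp_b)`.  The CI is centred on the point estimate, so
`ci_low ≤ vimp ≤ ci_high` by construction; `n_subsamples = 1` degenerates
to the point estimate with a warning, and subsamples below 30 rows are
refused.

Partial dependence sweeps one covariate across its observed range, averaging
predictions over the table rows at each grid value.

## Two-period trends

For each wetland variable, species and annual cycle, the annual series is
the mean over cycle months of inundated variable area (ha), restricted to
fine pixels whose 2.5 km cell has abundance > 0.  The abundance > 0 mask is
computed once from the recent-window abundance surface and held fixed across
all 40 years, assuming cycle distributions represent the whole period.
Hydroperiod-class membership is re-derived each calendar year; functional
labels are static.  The mean (not sum) over cycle months makes cycles of
different lengths comparable.

The series is split into P1 = 1984–2003 and P2 = 2004–2023 (equal 20-year
periods, damping short-term climate cycles) and compared with an **unpaired
two-sample, two-sided Wilcoxon rank-sum test** — the periods are independent
year sets with no natural pairing.  With ≤ 12 pooled observations the
p-value is computed by exhaustive enumeration of rank assignments
(midranks for ties); larger samples use the normal approximation with tie
correction.  Percent change is 100 · (P2 − P1)/P1, undefined (flagged) when
the P1 mean is zero; significance is p < 0.1.  Variables not classified
important carry no trend numbers and appear as `excluded` in the dot-matrix
report.

## Synthetic landscapes

The generator builds landscapes from rectangular (or disc) wetland patches,
each with a functional class, a 12-month flood-probability profile, and an
optional long-term trend.  Monthly inundation is Bernoulli: one draw per
patch-month in `coherent` mode (crisp hydroperiods, patches flooding as
management units) or one draw per pixel-month in `independent` mode
(speckled water, smoothly varying areas).  A patch trend *t* is applied as
a linear ramp on flood probability scaled so the mean multiplier over the
first half of the year range is exactly 1 and over the second half exactly
1 + *t* — the realized P1→P2 change in expected inundated area equals the
configured fraction, which tests verify by Monte Carlo.  Abundance
surfaces are sums of monotone effect shapes (linear, saturating,
exponential — mirroring the generally linear-to-asymptotic marginal
responses such models produce) of chosen covariate densities, normalized to
the observed covariate range, plus Gaussian noise, truncated at zero, with
optional zero inflation; everything planted is recorded as ground truth.
The coarse grid is axis-aligned with the fine grid (integer
`coarse_factor`); there is no CRS or projection machinery — the algorithms
need geometry, not geodesy.

### The recovery scenario and what passing shows

The importance-recovery experiment plants abundance on
{wetland area, semi-permanent, littoral saline} over 2500 coarse cells with
noise at 25% of the signal sd, and requires the minimal-depth rule to flag
the planted set and not the other nine covariates.  This contrast only
makes sense if the non-planted covariates are close to orthogonal to the
planted signal, which is not automatic: the hydroperiod classes and the
functional classes are structural *components* of total wetland area, so in
an arbitrary landscape any large-variance component is a genuine proxy for
a planted aggregate effect.  The scenario landscape is therefore built so
that orthogonality holds:

* every functional class occupies its own independent sub-patch slot in
  each coarse cell, so class areas vary without compositional coupling;
* functional classes draw broad 1–12-month hydroperiods, so no class
  concentrates in a single persistence band and becomes a proxy for it;
* persistent-water variance is concentrated in deepwater lake pixels,
  which the exclusion removes from every functional covariate while they
  still count toward wetland area and semi-permanent density — an
  orthogonal variance source for the planted aggregates;
* lake drawdown fringes (the littoral classes) are narrow strips, limiting
  the pixel overlap between the seasonal covariate and the planted
  littoral-saline signal; and
* rice follows its cultivation calendar (growing-season or winter
  flooding, never semi-permanent), giving the seasonal covariate variance
  that is unrelated to abundance.

Passing therefore shows that the statistics recover planted structure when
noise covariates are near-orthogonal — it does **not** show that correlated
structural components would be excluded in real landscapes, where flagging
them as important can be the scientifically correct outcome.  Other known
gaps between the generator and real data: abundance noise is spatially
independent (no correlated observation error), functional labels are static
over 40 years (no land-use conversion), patch geometry is rectangular, and
inundation has no spatial autocorrelation beyond the patch.

### Trend scenario

The trend-recovery experiment plants a −30% flood-probability ramp on a
40 × 40-pixel managed-wetland patch (monthly flood probability 0.5,
per-pixel draws) with stationary palustrine and pond controls, the species
present everywhere.  With ~1600 patch pixels the annual area's sampling
noise is well under 1%, so the recovered percent change concentrates
tightly around −30 and the rank-sum test detects it essentially always,
while stationary controls are flagged at about the nominal 10% rate.

## Problem sizes and defaults

The bundled demo configuration uses a 300 × 300 fine grid (30 m pixels),
`coarse_factor` 12, years 1984–2023, six species with the bundled
annual-cycle calendar, 500-tree forests, and subsampling CIs disabled; it
runs in well under a minute on one CPU and is byte-for-byte reproducible
given its seed (all per-species/cycle seeds are derived from the master
seed by hashing).  The recovery experiments use 400 × 400 fine grids
(2500 coarse cells) and 500-tree forests.  Full-scale continental inputs
(multi-state 30 m mosaics) are outside the scope of the synthetic
generator; the pipeline operates on whatever raster extents are supplied.

## Known limitations

* The forest backend does not reproduce any specific external forest
  implementation split-for-split; the importance statistics are defined on
  tree structures and validated against hand-built trees instead.
* The subsample-CI variance correction assumes approximate normality of
  the subsampled VIMP distribution; very small `n_subsamples` gives wide,
  unstable intervals.
* Percent change is undefined for variables absent in P1 (P1 mean zero);
  such cells are flagged rather than reported as infinite growth.
* The cycle-availability mask threshold (≥ 1 wet cycle month over the
  window) is the most inclusive reading; stricter thresholds shrink every
  covariate layer and are exposed as a parameter rather than explored.
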