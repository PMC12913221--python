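"""Regression-forest variable importance for abundance models.

Relative abundance is regressed on the twelve wetland covariate densities
with a random forest.  Two importance statistics decide which wetland
variables structure a species' abundance:

* **Permutation (Breiman–Cutler) VIMP** — the mean increase in a tree's
  out-of-bag squared prediction error when one covariate's out-of-bag values
  are permuted.  Subsampling confidence intervals (the "double bootstrap")
  come from refitting the forest on subsamples drawn without replacement and
  applying a delete-d jackknife variance correction.
* **Minimal depth** — the depth of a covariate's shallowest split in each
  tree (root = 0), averaged over trees; a covariate absent from a tree is
  charged that tree's maximum depth + 1.  A covariate is classified
  *important* when its mean minimal depth falls strictly below the threshold,
  taken as the mean of the per-covariate mean-depth distribution.

Both statistics are computed here by walking tree structures directly so they
can be validated against hand-built trees; the forest fit itself is delegated
to scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

_META_COLUMNS = ("cell_id", "row", "col", "abundance")


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLUMNS]


@dataclass
class ForestModel:
    """A fitted regression forest plus the metadata needed to inspect it."""

    estimator: RandomForestRegressor
    feature_names: list[str]
    n_trees: int
    oob_error: float
    seed: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(X)


@dataclass
class TreeStructure:
    """Array view of one decision tree (the split layout, not the leaf values).

    ``feature[i]`` is the split covariate index of node ``i`` (negative for
    leaves); ``children_left``/``children_right`` give child node ids (-1 for
    leaves).  Matches scikit-learn's internal tree arrays so both fitted and
    hand-built trees walk the same code path.
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray


@dataclass
class VimpResult:
    """Per-covariate permutation importance with subsampling CIs."""

    table: pd.DataFrame  # columns: covariate, vimp, ci_low, ci_high, rank
    n_subsamples: int
    alpha: float
    subsample_fraction: float
    seed: int


@dataclass
class DepthResult:
    """Per-covariate mean minimal depth and the threshold classification."""

    depths: pd.Series  # covariate -> mean minimal depth
    threshold: float
    important: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.important = self.depths < self.threshold

    def important_set(self) -> set[str]:
        return set(self.important.index[self.important])


@dataclass
class PartialDependence:
    covariate: str
    grid: np.ndarray
    values: np.ndarray


def _design(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    names = feature_columns(table)
    X = table[names].to_numpy(dtype=np.float64)
    y = table["abundance"].to_numpy(dtype=np.float64)
    return X, y, names


def _fit_forest(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    seed: int,
    mtry: int | None,
    node_size: int,
) -> tuple[RandomForestRegressor, float]:
    p = X.shape[1]
    if mtry is None:
        mtry = max(1, -(-p // 3))  # regression default ceil(p/3)
    est = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=mtry,
        min_samples_leaf=node_size,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    oob = est.oob_prediction_
    valid = ~np.isnan(oob)
    oob_mse = float(np.mean((y[valid] - oob[valid]) ** 2))
    return est, oob_mse


def tune_and_fit(
    table: pd.DataFrame,
    n_tree_grid: tuple[int, ...] = (1000, 1500, 2000),
    seed: int = 0,
    mtry: int | None = None,
    node_size: int = 5,
) -> ForestModel:
    """Fit forests over a tree-count grid and keep the OOB-error minimizer."""
    X, y, names = _design(table)
    if len(names) < 2:
        raise ValueError("need at least 2 covariates")
    if len(table) < 50:
        raise ValueError("need at least 50 rows")
    if np.ptp(y) == 0.0:
        raise ValueError("constant response: nothing to model")
    best: tuple[float, int, RandomForestRegressor] | None = None
    for n_trees in n_tree_grid:
        est, oob_mse = _fit_forest(X, y, n_trees, seed, mtry, node_size)
        if best is None or oob_mse < best[0]:
            best = (oob_mse, n_trees, est)
    assert best is not None
    oob_mse, n_trees, est = best
    return ForestModel(
        estimator=est,
        feature_names=names,
        n_trees=n_trees,
        oob_error=oob_mse,
        seed=seed,
    )


def _oob_indices(est: RandomForestRegressor, n: int) -> list[np.ndarray]:
    all_idx = np.arange(n)
    return [
        np.setdiff1d(all_idx, inbag, assume_unique=False)
        for inbag in est.estimators_samples_
    ]


def permutation_vimp(
    model: ForestModel, table: pd.DataFrame, seed: int = 0
) -> pd.Series:
    """Breiman–Cutler permutation importance.

    For each tree: squared prediction error on its out-of-bag rows, then the
    error increase after permuting one covariate's out-of-bag values; the
    VIMP score is the mean increase over trees.  Noise covariates may come
    out slightly negative.
    """
    X, y, names = _design(table)
    if names != model.feature_names:
        raise ValueError("table covariates do not match the fitted model")
    X32 = X.astype(np.float32)
    rng = np.random.default_rng(seed)
    n = len(y)
    p = len(names)
    increases = np.zeros(p)
    used_trees = 0
    for est, oob in zip(model.estimator.estimators_, _oob_indices(model.estimator, n)):
        if oob.size == 0:
            continue
        used_trees += 1
        Xo = X32[oob]
        yo = y[oob]
        base = float(np.mean((yo - est.tree_.predict(Xo).ravel()) ** 2))
        for j in range(p):
            perm = rng.permutation(oob.size)
            Xp = Xo.copy()
            Xp[:, j] = Xo[perm, j]
            err = float(np.mean((yo - est.tree_.predict(Xp).ravel()) ** 2))
            increases[j] += err - base
    if used_trees == 0:
        raise ValueError("no tree has out-of-bag rows")
    return pd.Series(increases / used_trees, index=names, name="vimp")


def vimp_subsample_ci(
    table: pd.DataFrame,
    n_subsamples: int = 500,
    alpha: float = 0.05,
    subsample_fraction: float = 0.632,
    seed: int = 0,
    n_trees: int = 500,
    mtry: int | None = None,
    node_size: int = 5,
) -> VimpResult:
    """Subsampling ("double bootstrap") confidence intervals for VIMP.

    The point estimate comes from a forest on the full table.  Each of
    ``n_subsamples`` replicates refits the forest on a subsample drawn
    without replacement at ``subsample_fraction`` and recomputes VIMP; the CI
    is the point estimate ± z(alpha) times the delete-d jackknife standard
    error  var = (m / (n − m)) · mean((vimp_b − mean_b)²).
    """
    X, y, names = _design(table)
    n = len(y)
    m = int(round(subsample_fraction * n))
    if m < 30:
        raise ValueError(f"subsample of {m} rows is too small (need >= 30)")
    est, oob_mse = _fit_forest(X, y, n_trees, seed, mtry, node_size)
    model = ForestModel(est, names, n_trees, oob_mse, seed)
    point = permutation_vimp(model, table, seed=seed)
    rng = np.random.default_rng(seed)
    if n_subsamples < 2:
        warnings.warn(
            "n_subsamples < 2: degenerate CI equal to the point estimate",
            stacklevel=2,
        )
        lo = hi = point.to_numpy()
    else:
        reps = np.empty((n_subsamples, len(names)))
        for b in range(n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            sub = table.iloc[idx].reset_index(drop=True)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            est_b, oob_b = _fit_forest(
                sub[names].to_numpy(), sub["abundance"].to_numpy(),
                n_trees, sub_seed, mtry, node_size,
            )
            model_b = ForestModel(est_b, names, n_trees, oob_b, sub_seed)
            reps[b] = permutation_vimp(model_b, sub, seed=sub_seed).to_numpy()
        var = (m / (n - m)) * reps.var(axis=0)
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * np.sqrt(var)
        lo = point.to_numpy() - half
        hi = point.to_numpy() + half
    out = pd.DataFrame(
        {"covariate": names, "vimp": point.to_numpy(), "ci_low": lo, "ci_high": hi}
    )
    out["rank"] = out["vimp"].rank(ascending=False, method="min").astype(int)
    return VimpResult(
        table=out,
        n_subsamples=n_subsamples,
        alpha=alpha,
        subsample_fraction=subsample_fraction,
        seed=seed,
    )


def tree_minimal_depths(tree: TreeStructure, n_features: int) -> np.ndarray:
    """Minimal split depth per covariate in one tree (root = 0).

    Covariates that never split in the tree receive the tree's maximum node
    depth + 1, penalizing absence.
    """
    n_nodes = len(tree.feature)
    if n_nodes == 0:
        raise ValueError("empty tree")
    depth = np.zeros(n_nodes, dtype=np.int64)
    # children arrays are topologically ordered (parent before child)
    for node in range(n_nodes):
        for child in (tree.children_left[node], tree.children_right[node]):
            if child >= 0:
                depth[child] = depth[node] + 1
    max_depth = int(depth.max())
    depths = np.full(n_features, max_depth + 1, dtype=float)
    split_nodes = tree.feature >= 0
    for node in np.nonzero(split_nodes)[0]:
        f = tree.feature[node]
        if depth[node] < depths[f]:
            depths[f] = depth[node]
    return depths


def forest_minimal_depth(
    trees: list[TreeStructure], feature_names: list[str]
) -> DepthResult:
    """Mean minimal depth over trees and the mean-of-means threshold rule."""
    if not trees:
        raise ValueError("empty forest")
    p = len(feature_names)
    acc = np.zeros(p)
    for t in trees:
        acc += tree_minimal_depths(t, p)
    means = acc / len(trees)
    threshold = float(means.mean())
    return DepthResult(
        depths=pd.Series(means, index=feature_names, name="minimal_depth"),
        threshold=threshold,
    )


def minimal_depth(model: ForestModel) -> DepthResult:
    """Minimal-depth importance for a fitted forest."""
    structures = [
        TreeStructure(
            children_left=est.tree_.children_left,
            children_right=est.tree_.children_right,
            feature=est.tree_.feature,
        )
        for est in model.estimator.estimators_
    ]
    return forest_minimal_depth(structures, model.feature_names)


def partial_dependence(
    model: ForestModel,
    table: pd.DataFrame,
    covariate: str,
    grid_size: int = 25,
) -> PartialDependence:
    """Mean prediction as one covariate sweeps its observed range."""
    if covariate not in model.feature_names:
        raise KeyError(f"unknown covariate {covariate!r}")
    X, _, names = _design(table)
    j = names.index(covariate)
    lo, hi = float(X[:, j].min()), float(X[:, j].max())
    grid = np.linspace(lo, hi, grid_size)
    values = np.empty(grid_size)
    Xw = X.copy()
    for i, v in enumerate(grid):
        Xw[:, j] = v
        values[i] = float(model.estimator.predict(Xw).mean())
    return PartialDependence(covariate=covariate, grid=grid, values=values)
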