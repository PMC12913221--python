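"""Forest fitting, permutation VIMP, minimal depth, and partial dependence."""

import numpy as np
import pandas as pd
import pytest

from wetbird.importance import (
    TreeStructure,
    forest_minimal_depth,
    minimal_depth,
    partial_dependence,
    permutation_vimp,
    tree_minimal_depths,
    tune_and_fit,
    vimp_subsample_ci,
)


def make_table(rng, n=300, signal="linear"):
    """Four-covariate table: cov0 drives abundance, cov1-3 are noise."""
    X = rng.uniform(0, 1, size=(n, 4))
    if signal == "linear":
        y = 2.0 * X[:, 0]
    elif signal == "saturating":
        y = 1.0 - np.exp(-4.0 * X[:, 0])
    else:
        raise ValueError(signal)
    table = pd.DataFrame(X, columns=[f"cov{i}" for i in range(4)])
    table["abundance"] = y
    return table


class TestTuneAndFit:
    def test_single_grid_value_gives_that_many_trees(self, rng):
        model = tune_and_fit(make_table(rng), n_tree_grid=(100,), seed=0)
        assert model.n_trees == 100
        assert len(model.estimator.estimators_) == 100

    def test_same_seed_reproduces_oob_error(self, rng):
        table = make_table(rng)
        a = tune_and_fit(table, n_tree_grid=(80,), seed=5)
        b = tune_and_fit(table, n_tree_grid=(80,), seed=5)
        assert a.oob_error == b.oob_error

    def test_noiseless_linear_response_high_oob_r2(self, rng):
        table = make_table(rng, n=2500)
        model = tune_and_fit(table, n_tree_grid=(200,), seed=0)
        r2 = 1.0 - model.oob_error / table["abundance"].var()
        assert r2 > 0.95

    def test_grid_selection_minimizes_oob(self, rng):
        table = make_table(rng, n=400)
        model = tune_and_fit(table, n_tree_grid=(10, 100), seed=0)
        assert model.n_trees in (10, 100)

    def test_constant_response_raises(self, rng):
        table = make_table(rng)
        table["abundance"] = 3.0
        with pytest.raises(ValueError, match="constant"):
            tune_and_fit(table, n_tree_grid=(50,), seed=0)

    def test_too_few_rows_raises(self, rng):
        with pytest.raises(ValueError, match="rows"):
            tune_and_fit(make_table(rng, n=20), n_tree_grid=(50,), seed=0)


class TestPermutationVimp:
    def test_constant_covariate_scores_near_zero(self, rng):
        table = make_table(rng)
        table["cov3"] = 1.0  # never split on
        model = tune_and_fit(table, n_tree_grid=(150,), seed=0)
        vimp = permutation_vimp(model, table, seed=0)
        assert abs(vimp["cov3"]) < 0.05 * vimp.max()

    def test_sole_generative_covariate_ranks_first(self, rng):
        table = make_table(rng, n=500)
        model = tune_and_fit(table, n_tree_grid=(150,), seed=0)
        vimp = permutation_vimp(model, table, seed=0)
        assert vimp.idxmax() == "cov0"

    def test_duplicated_covariate_pair_beats_noise(self, rng):
        table = make_table(rng, n=500)
        table["cov1"] = table["cov0"]  # exact duplicate of the signal
        model = tune_and_fit(table, n_tree_grid=(200,), seed=0)
        vimp = permutation_vimp(model, table, seed=0).sort_values(ascending=False)
        assert set(vimp.index[:2]) == {"cov0", "cov1"}

    def test_deterministic_given_seed(self, rng):
        table = make_table(rng)
        model = tune_and_fit(table, n_tree_grid=(80,), seed=1)
        a = permutation_vimp(model, table, seed=7)
        b = permutation_vimp(model, table, seed=7)
        pd.testing.assert_series_equal(a, b)


class TestSubsampleCI:
    def test_strong_effect_ci_excludes_zero(self, rng):
        table = make_table(rng, n=300)
        res = vimp_subsample_ci(
            table, n_subsamples=20, seed=0, n_trees=60, subsample_fraction=0.632
        )
        row = res.table.set_index("covariate").loc["cov0"]
        assert row["ci_low"] > 0
        assert row["rank"] == 1

    def test_noise_covariate_ci_covers_zero(self, rng):
        table = make_table(rng, n=300)
        table["abundance"] += rng.normal(0, 0.3, size=len(table))
        res = vimp_subsample_ci(
            table, n_subsamples=20, seed=0, n_trees=60, subsample_fraction=0.632
        )
        t = res.table.set_index("covariate")
        covers = [
            t.loc[c, "ci_low"] <= 0 <= t.loc[c, "ci_high"]
            for c in ("cov1", "cov2", "cov3")
        ]
        assert sum(covers) >= 2

    def test_single_subsample_degenerates_to_point_with_warning(self, rng):
        table = make_table(rng, n=200)
        with pytest.warns(UserWarning, match="degenerate"):
            res = vimp_subsample_ci(table, n_subsamples=1, seed=0, n_trees=40)
        assert (res.table["ci_low"] == res.table["vimp"]).all()

    def test_tiny_subsample_raises(self, rng):
        with pytest.raises(ValueError, match="too small"):
            vimp_subsample_ci(
                make_table(rng, n=40), n_subsamples=5, seed=0,
                n_trees=20, subsample_fraction=0.5,
            )

    def test_ci_brackets_point_estimate(self, rng):
        table = make_table(rng, n=300)
        res = vimp_subsample_ci(table, n_subsamples=15, seed=3, n_trees=50)
        assert (res.table["ci_low"] <= res.table["vimp"]).all()
        assert (res.table["vimp"] <= res.table["ci_high"]).all()


# Hand-built two-tree forest with known structure.
#
# Tree A:          f0            Tree B:          f2
#                 /  \                           /  \
#              leaf   f1                       f0   leaf
#                    /  \                     /  \
#                 leaf  leaf               leaf  leaf
#
# Minimal depths (root = 0): tree A: f0 -> 0, f1 -> 1, f2 unused -> 3
#                            tree B: f2 -> 0, f0 -> 1, f1 unused -> 3
TREE_A = TreeStructure(
    children_left=np.array([1, -1, 3, -1, -1]),
    children_right=np.array([2, -1, 4, -1, -1]),
    feature=np.array([0, -2, 1, -2, -2]),
)
TREE_B = TreeStructure(
    children_left=np.array([1, 3, -1, -1, -1]),
    children_right=np.array([2, 4, -1, -1, -1]),
    feature=np.array([2, 0, -2, -2, -2]),
)


class TestMinimalDepth:
    def test_hand_traced_single_tree_depths(self):
        np.testing.assert_array_equal(
            tree_minimal_depths(TREE_A, 3), [0.0, 1.0, 3.0]
        )
        np.testing.assert_array_equal(
            tree_minimal_depths(TREE_B, 3), [1.0, 3.0, 0.0]
        )

    def test_hand_traced_forest_means_threshold_and_classification(self):
        res = forest_minimal_depth([TREE_A, TREE_B], ["f0", "f1", "f2"])
        assert res.depths["f0"] == pytest.approx(0.5)
        assert res.depths["f1"] == pytest.approx(2.0)
        assert res.depths["f2"] == pytest.approx(1.5)
        assert res.threshold == pytest.approx(4.0 / 3.0)
        assert res.important_set() == {"f0"}

    def test_depth_at_threshold_is_not_important(self):
        # mirror-image trees make both covariates' mean depth equal the
        # threshold; the tie rule classifies neither as important
        tree_ab = TreeStructure(
            children_left=np.array([1, 3, -1, -1, -1]),
            children_right=np.array([2, 4, -1, -1, -1]),
            feature=np.array([0, 1, -2, -2, -2]),
        )
        tree_ba = TreeStructure(
            children_left=np.array([1, 3, -1, -1, -1]),
            children_right=np.array([2, 4, -1, -1, -1]),
            feature=np.array([1, 0, -2, -2, -2]),
        )
        res = forest_minimal_depth([tree_ab, tree_ba], ["f0", "f1"])
        assert res.depths["f0"] == res.depths["f1"] == res.threshold
        assert res.important_set() == set()

    def test_root_splitter_in_every_tree_has_depth_zero(self, rng):
        table = make_table(rng, n=400)
        model = tune_and_fit(table, n_tree_grid=(100,), seed=0)
        res = minimal_depth(model)
        assert res.depths.min() >= 0
        assert res.important["cov0"]

    def test_empty_forest_raises(self):
        with pytest.raises(ValueError, match="empty"):
            forest_minimal_depth([], ["f0"])


class TestPartialDependence:
    def test_monotone_linear_fixture_gives_increasing_profile(self, rng):
        table = make_table(rng, n=800)
        model = tune_and_fit(table, n_tree_grid=(150,), seed=0)
        pd_res = partial_dependence(model, table, "cov0", grid_size=15)
        assert pd_res.values[-1] > pd_res.values[0]
        assert np.sum(np.diff(pd_res.values) < -1e-3) <= 1

    def test_saturating_fixture_flattens_in_upper_half(self, rng):
        table = make_table(rng, n=1200, signal="saturating")
        model = tune_and_fit(table, n_tree_grid=(150,), seed=0)
        pd_res = partial_dependence(model, table, "cov0", grid_size=20)
        increments = np.diff(pd_res.values)
        assert increments[:5].mean() > increments[-5:].mean()
        assert pd_res.values[-1] > pd_res.values[0]

    def test_noise_covariate_profile_is_nearly_flat(self, rng):
        table = make_table(rng, n=800)
        model = tune_and_fit(table, n_tree_grid=(150,), seed=0)
        sig = partial_dependence(model, table, "cov0", grid_size=10)
        noise = partial_dependence(model, table, "cov2", grid_size=10)
        assert np.ptp(noise.values) < 0.2 * np.ptp(sig.values)

    def test_unknown_covariate_raises(self, rng):
        table = make_table(rng)
        model = tune_and_fit(table, n_tree_grid=(50,), seed=0)
        with pytest.raises(KeyError):
            partial_dependence(model, table, "wetland_area")

    def test_grid_spans_observed_range(self, rng):
        table = make_table(rng)
        model = tune_and_fit(table, n_tree_grid=(50,), seed=0)
        res = partial_dependence(model, table, "cov0", grid_size=7)
        assert res.grid[0] == table["cov0"].min()
        assert res.grid[-1] == table["cov0"].max()
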