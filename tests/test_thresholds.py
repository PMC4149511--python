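"""Penalized-spline smooths and conditional-inference trees."""

import numpy as np
import pandas as pd
import pytest

from gridrep import count_splits_by_covariate, fit_ctree, fit_smooth
from gridrep.thresholds import _best_cutpoint


def make_xtable(rng, n, sizes=(4, 8, 16, 30, 60, 120), sd_range=(1.0, 56.0)):
    return pd.DataFrame(
        {
            "sample_size": rng.choice(sizes, n).astype(float),
            "sd": rng.uniform(*sd_range, n),
        }
    )


class TestFitSmooth:
    def test_reproduces_a_line(self, rng):
        x = make_xtable(rng, 200)
        y = 3.0 * x["sample_size"].to_numpy() - 7.0
        fit = fit_smooth(x, y)
        assert fit.deviance_explained >= 0.999

    def test_pure_noise_explains_little(self):
        # deviance explained stays near zero for a response independent of
        # both covariates (20 seeded datasets, 500 rows each)
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            x = make_xtable(rng, 500)
            y = rng.standard_normal(500)
            fit = fit_smooth(x, y)
            assert fit.deviance_explained <= 0.15

    def test_constant_response_gives_zero(self, rng):
        x = make_xtable(rng, 50)
        fit = fit_smooth(x, np.full(50, 3.14))
        assert fit.deviance_explained == 0.0

    def test_zero_variance_covariate_dropped_with_warning(self, rng):
        x = make_xtable(rng, 100)
        x["sd"] = 5.0
        y = x["sample_size"].to_numpy() + rng.normal(0, 0.1, 100)
        with pytest.warns(UserWarning, match="zero variance"):
            fit = fit_smooth(x, y)
        assert [t.name for t in fit.terms] == ["sample_size"]
        assert fit.deviance_explained > 0.9

    def test_nan_rows_dropped(self, rng):
        x = make_xtable(rng, 100)
        y = 2.0 * x["sd"].to_numpy()
        y[:10] = np.nan
        fit = fit_smooth(x, y)
        assert len(fit.fitted) == 90
        assert fit.deviance_explained >= 0.999

    def test_too_few_rows_rejected(self, rng):
        x = make_xtable(rng, 5)
        with pytest.raises(ValueError, match="10 rows"):
            fit_smooth(x, np.ones(5))

    def test_fitted_values_invariant_to_row_order(self, rng):
        x = make_xtable(rng, 120)
        y = np.sin(x["sd"].to_numpy() / 10) + 0.05 * rng.standard_normal(120)
        fit = fit_smooth(x, y)
        perm = rng.permutation(120)
        fit_p = fit_smooth(x.iloc[perm].reset_index(drop=True), y[perm])
        assert np.allclose(fit_p.fitted, fit.fitted[perm], atol=1e-4)

    def test_band_contains_fit_and_is_ordered(self, rng):
        x = make_xtable(rng, 100)
        y = x["sd"].to_numpy() + rng.standard_normal(100)
        fit = fit_smooth(x, y)
        band = fit.band(x)
        assert (band["lower"] <= band["fit"]).all()
        assert (band["fit"] <= band["upper"]).all()


class TestFitCtree:
    def test_step_in_sample_size_recovered(self):
        rng = np.random.default_rng(0)
        x = make_xtable(rng, 240)
        y = (x["sample_size"] >= 30).astype(float).to_numpy()
        y = y + rng.normal(0, 0.05, len(y))
        tree = fit_ctree(x, y, permutations=999, rng=rng)
        assert not tree.is_leaf
        assert tree.split_covariate == "sample_size"
        assert 16 <= tree.split_value < 30

    def test_step_in_sd_recovered(self):
        rng = np.random.default_rng(1)
        x = make_xtable(rng, 240)
        y = (x["sd"] > 20.0).astype(float).to_numpy()
        y = y + rng.normal(0, 0.05, len(y))
        tree = fit_ctree(x, y, permutations=999, rng=rng)
        assert tree.split_covariate == "sd"
        assert abs(tree.split_value - 20.0) < 5.0

    def test_independent_noise_usually_single_leaf(self):
        leaves = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            x = make_xtable(rng, 400)
            y = rng.standard_normal(400)
            tree = fit_ctree(x, y, permutations=499, rng=rng)
            leaves += tree.is_leaf
        assert leaves >= 8

    def test_constant_response_never_splits(self, rng):
        x = make_xtable(rng, 100)
        tree = fit_ctree(x, np.full(100, 2.0), permutations=199, rng=rng)
        assert tree.is_leaf

    def test_leaves_respect_min_node(self):
        rng = np.random.default_rng(3)
        x = make_xtable(rng, 300)
        y = x["sample_size"].to_numpy() + rng.normal(0, 1.0, 300)
        tree = fit_ctree(x, y, permutations=499, min_node=25, rng=rng)

        def leaf_sizes(node):
            if node.is_leaf:
                return [node.n_observations]
            return leaf_sizes(node.left) + leaf_sizes(node.right)

        assert min(leaf_sizes(tree)) >= 25

    def test_children_partition_parent(self):
        rng = np.random.default_rng(4)
        x = make_xtable(rng, 200)
        y = (x["sample_size"] > 10).astype(float).to_numpy() + rng.normal(0, 0.1, 200)
        tree = fit_ctree(x, y, permutations=499, rng=rng)

        def check(node):
            if node.is_leaf:
                return
            assert node.left.n_observations + node.right.n_observations == \
                node.n_observations
            assert node.adjusted_p < 0.05
            check(node.left)
            check(node.right)

        check(tree)

    def test_permutation_p_invariant_to_affine_y(self):
        rng_x = np.random.default_rng(5)
        x = make_xtable(rng_x, 150)
        y = (x["sd"] > 25).astype(float).to_numpy() + rng_x.normal(0, 0.2, 150)
        t1 = fit_ctree(x, y, permutations=499, rng=np.random.default_rng(11))
        t2 = fit_ctree(x, 10.0 * y - 3.0, permutations=499,
                       rng=np.random.default_rng(11))
        assert t1.is_leaf == t2.is_leaf
        if not t1.is_leaf:
            assert t1.adjusted_p == pytest.approx(t2.adjusted_p)
            assert t1.split_value == pytest.approx(t2.split_value)

    def test_cutpoint_matches_brute_force_argmax(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 100, 120)
        y = (x > 40).astype(float) * 5.0 + rng.normal(0, 0.01, 120)

        # oracle: scan every midpoint between distinct sorted values
        xs = np.sort(np.unique(x))
        best_stat, best_cut = -np.inf, None
        n = len(x)
        for lo, hi in zip(xs[:-1], xs[1:]):
            cut = 0.5 * (lo + hi)
            left = y[x <= cut]
            right = y[x > cut]
            if len(left) < 20 or len(right) < 20:
                continue
            stat = abs(left.mean() - right.mean()) * np.sqrt(
                len(left) * len(right) / n
            )
            if stat > best_stat:
                best_stat, best_cut = stat, cut
        cut, stat = _best_cutpoint(x, y, min_node=20)
        assert cut == pytest.approx(best_cut)
        assert stat == pytest.approx(best_stat)

    def test_invalid_alpha_rejected(self, rng):
        x = make_xtable(rng, 100)
        with pytest.raises(ValueError):
            fit_ctree(x, np.zeros(100), alpha=1.5, rng=rng)

    def test_few_permutations_warns(self, rng):
        x = make_xtable(rng, 100)
        with pytest.warns(UserWarning, match="permutations"):
            fit_ctree(x, rng.standard_normal(100), permutations=50, rng=rng)


class TestCountSplits:
    def test_single_leaf_empty_mapping(self, rng):
        x = make_xtable(rng, 80)
        tree = fit_ctree(x, np.zeros(80), permutations=199, rng=rng)
        assert count_splits_by_covariate(tree) == {}

    def test_step_tree_counts_sample_size(self):
        rng = np.random.default_rng(8)
        x = make_xtable(rng, 240)
        y = (x["sample_size"] >= 30).astype(float).to_numpy()
        y = y + rng.normal(0, 0.05, 240)
        tree = fit_ctree(x, y, permutations=499, rng=rng)
        counts = count_splits_by_covariate(tree)
        assert counts.get("sample_size", 0) >= 1

    def test_counts_sum_to_internal_nodes(self):
        rng = np.random.default_rng(9)
        x = make_xtable(rng, 300)
        y = x["sample_size"].to_numpy() / 10 + x["sd"].to_numpy() / 5
        y = y + rng.normal(0, 0.5, 300)
        tree = fit_ctree(x, y, permutations=499, rng=rng)

        def internal(node):
            return 0 if node.is_leaf else 1 + internal(node.left) + internal(node.right)

        assert sum(count_splits_by_covariate(tree).values()) == internal(tree)


class TestTreeSerialization:
    def test_json_and_text_round_trip_structure(self, tmp_path):
        rng = np.random.default_rng(10)
        x = make_xtable(rng, 200)
        y = (x["sample_size"] >= 30).astype(float).to_numpy() + rng.normal(
            0, 0.05, 200
        )
        tree = fit_ctree(x, y, permutations=499, rng=rng)
        d = tree.to_dict()
        assert d["is_leaf"] is False
        assert set(d) >= {"split_covariate", "split_value", "left", "right"}
        path = tmp_path / "tree.json"
        tree.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded == d
        text = tree.to_text()
        assert "sample_size <=" in text
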