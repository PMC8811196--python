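"""RF/NN importance, indicator species analysis and consensus logic."""

import itertools

import numpy as np
import pandas as pd
import pytest

from doclinker.feature_select import (
    ConsensusSelector,
    IndicatorSpecies,
    consensus_select,
    indval,
    make_group_labels,
    nn_importance,
    rf_importance,
)


def brute_force_indval(x, is_high, sqrt_form=True):
    """Loop-based IndVal for one table: stat and group per OTU."""
    stats, groups = [], []
    for j in range(x.shape[1]):
        col = x[:, j]
        res = {}
        for name, mask in (("high", is_high), ("low", ~is_high)):
            mean_in = col[mask].mean()
            mean_out = col[~mask].mean()
            a = mean_in / (mean_in + mean_out) if (mean_in + mean_out) > 0 else 0.0
            b = (col[mask] > 0).mean()
            iv = a * b
            res[name] = np.sqrt(iv) if sqrt_form else iv
        best = "high" if res["high"] >= res["low"] else "low"
        stats.append(res[best])
        groups.append(best)
    return np.array(stats), groups


class TestGroupLabels:
    def test_median_split_sizes(self):
        doc = np.arange(125.0)
        labels = make_group_labels(doc)
        assert (labels == "low").sum() == 63
        assert (labels == "high").sum() == 62

    def test_low_cohort_has_lower_doc(self, rng):
        doc = rng.uniform(0, 50, 40)
        labels = make_group_labels(doc)
        assert doc[labels == "low"].max() <= doc[labels == "high"].min()

    def test_quantile_split_excludes_middle(self, rng):
        doc = rng.uniform(0, 50, 100)
        labels = make_group_labels(doc, quantiles=(0.25, 0.75))
        assert (labels == "low").sum() == 25
        assert (labels == "high").sum() == 25
        assert (labels == "excluded").sum() == 50


class TestIndval:
    def test_perfect_indicator(self):
        x = np.zeros((8, 1))
        x[:4, 0] = 5.0
        groups = ["high"] * 4 + ["low"] * 4
        res = indval(x, groups, exact=True)
        assert res["stat"].iloc[0] == pytest.approx(1.0)
        assert res["group"].iloc[0] == "high"
        # minimum attainable exact p: only the observed split and its
        # complement reproduce stat 1.0 among the C(8,4) labelings
        assert res["p"].iloc[0] == pytest.approx(2 / 70)

    def test_symmetric_otu_is_sqrt_half(self):
        x = np.full((8, 1), 3.0)
        groups = ["high"] * 4 + ["low"] * 4
        res = indval(x, groups, n_perm=99, seed=0)
        assert res["stat"].iloc[0] == pytest.approx(np.sqrt(0.5))
        assert res["p"].iloc[0] > 0.05

    def test_exact_p_matches_exhaustive_oracle(self, rng):
        x = rng.poisson(3, size=(6, 4)).astype(float)
        is_high = np.array([True, True, True, False, False, False])
        groups = np.where(is_high, "high", "low")
        res = indval(x, groups, exact=True)
        stat_obs, _ = brute_force_indval(x, is_high)
        hits = np.zeros(4)
        total = 0
        for combo in itertools.combinations(range(6), 3):
            perm = np.zeros(6, dtype=bool)
            perm[list(combo)] = True
            s, _ = brute_force_indval(x, perm)
            hits += s >= stat_obs - 1e-12
            total += 1
        np.testing.assert_allclose(res["stat"], stat_obs, atol=1e-12)
        np.testing.assert_allclose(res["p"], hits / total, atol=1e-12)

    def test_group_relabeling_swaps_group_not_stat(self, rng):
        x = rng.poisson(4, size=(10, 3)).astype(float)
        g1 = ["high"] * 5 + ["low"] * 5
        g2 = ["low"] * 5 + ["high"] * 5
        r1 = indval(x, g1, n_perm=49, seed=1)
        r2 = indval(x, g2, n_perm=49, seed=1)
        np.testing.assert_allclose(r1["stat"], r2["stat"], atol=1e-12)
        assert (r1["group"] != r2["group"]).all() or (r1["stat"] == np.sqrt(0.5)).all()

    def test_classic_variant_is_square_of_sqrt_form(self, rng):
        x = rng.poisson(4, size=(10, 3)).astype(float)
        groups = ["high"] * 5 + ["low"] * 5
        sq = indval(x, groups, n_perm=9, seed=0, sqrt_form=True)
        classic = indval(x, groups, n_perm=9, seed=0, sqrt_form=False)
        np.testing.assert_allclose(classic["stat"], sq["stat"] ** 2, atol=1e-12)

    def test_stat_bounded_and_p_floor(self, rng):
        x = rng.poisson(2, size=(12, 20)).astype(float)
        groups = ["high"] * 6 + ["low"] * 6
        res = indval(x, groups, n_perm=99, seed=0)
        assert ((res["stat"] >= 0) & (res["stat"] <= 1)).all()
        assert ((res["p"] >= 1 / 100) & (res["p"] <= 1)).all()

    def test_estimator_wrapper(self, rng):
        x = rng.poisson(2, size=(12, 5)).astype(float)
        groups = ["high"] * 6 + ["low"] * 6
        est = IndicatorSpecies(n_perm=49, random_state=0).fit(x, groups)
        assert est.stats_.shape == (5,)
        assert est.pvalues_.shape == (5,)

    def test_empty_group_is_an_error(self, rng):
        x = rng.poisson(2, size=(6, 3)).astype(float)
        with pytest.raises(ValueError):
            indval(x, ["high"] * 6, n_perm=9)


class TestRfImportance:
    def test_planted_feature_scores_one(self, rng):
        n = 60
        x = rng.poisson(5, size=(n, 25)).astype(float)
        y = 3.0 * x[:, 7] + rng.normal(0, 1, n)
        imp = rf_importance(x, y, n_iter=10, seed=0)
        assert imp[7] == pytest.approx(1.0)
        assert imp.max() == 1.0

    def test_constant_column_near_zero(self, rng):
        n = 60
        x = rng.poisson(5, size=(n, 10)).astype(float)
        x[:, 3] = 0.0
        y = 2.0 * x[:, 0] + rng.normal(0, 1, n)
        imp = rf_importance(x, y, n_iter=10, seed=0)
        assert imp[3] < 0.05

    def test_deterministic_given_seed(self, rng):
        x = rng.poisson(5, size=(30, 8)).astype(float)
        y = rng.normal(size=30)
        np.testing.assert_array_equal(
            rf_importance(x, y, n_iter=5, seed=3), rf_importance(x, y, n_iter=5, seed=3)
        )

    def test_bad_frac_is_an_error(self, rng):
        x = rng.poisson(5, size=(30, 4)).astype(float)
        with pytest.raises(ValueError, match="frac"):
            rf_importance(x, np.arange(30.0), frac=1.5)


class TestNnImportance:
    def test_planted_signs_recovered(self, rng):
        n = 80
        x = rng.normal(size=(n, 12))
        y = 2.0 * x[:, 2] - 2.0 * x[:, 5] + rng.normal(0, 0.5, n)
        imp = nn_importance(x, y, n_search=4, seed=0)
        assert imp[2] > 0.3
        assert imp[5] < -0.3
        assert np.abs(imp).max() == pytest.approx(1.0)

    def test_small_sample_reduces_layer_with_warning(self, rng):
        x = rng.normal(size=(12, 4))
        y = x[:, 0] + rng.normal(0, 0.1, 12)
        with pytest.warns(UserWarning, match="hidden nodes"):
            nn_importance(x, y, n_search=2, seed=0, hidden_layer_size=15, n_ensemble=1)

    def test_noise_response_gives_no_dominant_feature(self, rng):
        # against a permuted-label null the importance profile is flat
        n = 80
        x = rng.normal(size=(n, 10))
        signal_y = 3.0 * x[:, 0] + rng.normal(0, 0.3, n)
        null_y = rng.permutation(signal_y)
        imp_signal = nn_importance(x, signal_y, n_search=3, seed=1)
        imp_null = nn_importance(x, null_y, n_search=3, seed=1)
        # normalized |importance| concentrates on the true feature only under signal
        conc_signal = np.abs(imp_signal[0]) / np.abs(imp_signal).mean()
        conc_null = np.abs(imp_null[0]) / np.abs(imp_null).mean()
        assert conc_signal > conc_null


def _scores(rf, nn, p, group="high"):
    k = len(rf)
    return pd.DataFrame(
        {
            "rf_importance": rf,
            "nn_importance": nn,
            "indval_stat": [0.8] * k,
            "indval_p": p,
            "indval_group": [group] * k,
        },
        index=[f"o{i}" for i in range(k)],
    )


class TestConsensus:
    def test_requires_all_three_methods(self):
        scores = _scores([1.0, 0.9], [1.0, 0.9], [0.001, 0.2])
        res = consensus_select(scores, rf_cutoff=0.5, nn_cutoff=0.5)
        assert res.selected == ["o0"]

    def test_empty_intersection_is_not_an_error(self):
        scores = _scores([1.0], [1.0], [0.5])
        assert consensus_select(scores, rf_cutoff=0.5, nn_cutoff=0.5).selected == []

    def test_subset_of_each_method_and_monotone_in_cutoffs(self, rng):
        k = 30
        scores = _scores(rng.uniform(0, 1, k), rng.uniform(-1, 1, k), rng.uniform(0, 1, k))
        res = consensus_select(scores, rf_cutoff=0.3, nn_cutoff=0.3)
        sel = set(res.selected)
        assert sel <= set(res.scores.index[res.scores["rf_selected"]])
        assert sel <= set(res.scores.index[res.scores["nn_selected"]])
        assert sel <= set(res.scores.index[res.scores["is_selected"]])
        stricter = consensus_select(scores, rf_cutoff=0.6, nn_cutoff=0.3)
        assert set(stricter.selected) <= sel

    def test_cutoff_out_of_range_is_an_error(self):
        scores = _scores([1.0], [1.0], [0.01])
        with pytest.raises(ValueError, match="rf_cutoff"):
            consensus_select(scores, rf_cutoff=1.5)

    def test_selector_recovers_planted_taxa_small(self, rng):
        n, k = 60, 30
        z = rng.normal(size=n)
        x = rng.poisson(5, size=(n, k)).astype(float)
        x[:, 0] = rng.poisson(np.exp(1.5 + 1.2 * z))
        x[:, 1] = rng.poisson(np.exp(1.5 - 1.2 * z))
        doc = 25 + 15 * z
        sel = ConsensusSelector(
            rf_n_iter=10, nn_search=4, n_perm=199, random_state=0
        ).fit(pd.DataFrame(x, columns=[f"o{i}" for i in range(k)]), doc)
        assert {"o0", "o1"} <= set(sel.selected_)
        assert sel.scores_.loc["o0", "nn_importance"] > 0
        assert sel.scores_.loc["o1", "nn_importance"] < 0
        assert sel.transform(pd.DataFrame(x)).shape[1] == len(sel.selected_)
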