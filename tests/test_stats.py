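"""Spearman, distances, PERMANOVA, ANOSIM and PCA against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from doclinker.stats import (
    anosim,
    distance_matrix,
    doc_class_correlations,
    pca_biplot,
    permanova,
    spearman,
)


def brute_force_permanova(d, labels):
    """Pseudo-F and R^2 straight from the definition, with python loops."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            d[i, j] ** 2 for i in idx for j in idx if i < j
        ) / len(idx)
    ss_between = ss_total - ss_within
    f = (ss_between / (len(groups) - 1)) / (ss_within / (n - len(groups)))
    return f, ss_between / ss_total


def brute_force_anosim_r(d, labels):
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    dists = [d[i, j] for i, j in pairs]
    ranks = scipy.stats.rankdata(dists)
    within = [labels[i] == labels[j] for i, j in pairs]
    rw = np.mean([r for r, w in zip(ranks, within) if w])
    rb = np.mean([r for r, w in zip(ranks, within) if not w])
    return (rb - rw) / (len(pairs) / 2)


@pytest.fixture()
def toy_distance(rng):
    x = rng.normal(size=(6, 4))
    x[3:] += 2.0
    d = distance_matrix(x, "euclidean")
    labels = ["a", "a", "a", "b", "b", "b"]
    return d, labels


class TestSpearman:
    def test_monotone_transform_gives_rho_one(self):
        x = np.array([1.0, 3.0, 2.0, 8.0, 5.0, 4.0])
        assert spearman(x, np.exp(x)).rho == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = np.arange(10.0)
        assert spearman(x, -(x**3)).rho == pytest.approx(-1.0)

    def test_symmetry_and_monotone_invariance(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        a, b = spearman(x, y), spearman(y, x)
        assert a.rho == pytest.approx(b.rho)
        assert spearman(np.exp(x), y).rho == pytest.approx(a.rho)

    def test_rho_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 4, size=25).astype(float)
        y = rng.integers(0, 4, size=25).astype(float)
        expected = scipy.stats.spearmanr(x, y).statistic
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_exact_p_matches_exhaustive_enumeration(self, rng):
        x = np.array([3.0, 1.0, 4.0, 1.5, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.5, 6.0])
        obs = spearman(x, y)
        # independent enumeration of all orderings of y
        rx = scipy.stats.rankdata(x)
        hits = total = 0
        for perm in itertools.permutations(y):
            rho = scipy.stats.spearmanr(rx, scipy.stats.rankdata(perm)).statistic
            total += 1
            hits += abs(rho) >= abs(obs.rho) - 1e-12
        assert obs.p == pytest.approx(hits / total, abs=1e-12)

    def test_constant_vector_is_an_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman(np.ones(6), np.arange(6.0))


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        x = np.ones((3, 4))
        d = distance_matrix(x, "euclidean")
        assert d == pytest.approx(np.zeros((3, 3)))

    def test_disjoint_presence_jaccard_one(self):
        x = np.array([[1, 1, 0, 0], [0, 0, 2, 3]])
        assert distance_matrix(x, "jaccard")[0, 1] == pytest.approx(1.0)

    def test_jaccard_hand_oracle(self):
        x = np.array([[1, 1, 0, 0], [1, 0, 1, 0], [0, 1, 1, 1]])
        d = distance_matrix(x, "jaccard")
        assert d[0, 1] == pytest.approx(1 - 1 / 3)
        assert d[0, 2] == pytest.approx(1 - 1 / 4)
        assert d[1, 2] == pytest.approx(1 - 1 / 4)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_empty_row_distance_one_with_warning(self):
        x = np.array([[0, 0, 0], [1, 0, 1], [0, 2, 0]])
        with pytest.warns(UserWarning, match="empty"):
            d = distance_matrix(x, "jaccard")
        assert d[0, 1] == 1.0 and d[0, 2] == 1.0 and d[0, 0] == 0.0


class TestPermanova:
    def test_matches_brute_force_oracle(self, toy_distance):
        d, labels = toy_distance
        res = permanova(d, labels, n_perm=99, seed=1)
        f, r2 = brute_force_permanova(d, labels)
        assert res.f_stat == pytest.approx(f, abs=1e-10)
        assert res.r2 == pytest.approx(r2, abs=1e-10)

    def test_exhaustive_p_matches_enumeration(self, toy_distance):
        d, labels = toy_distance
        res = permanova(d, labels, exhaustive=True)
        f_obs, _ = brute_force_permanova(d, labels)
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            perm = ["b" if i in combo else "a" for i in range(6)]
            total += 1
            hits += brute_force_permanova(d, perm)[0] >= f_obs - 1e-12
        assert res.p == pytest.approx(hits / total, abs=1e-12)

    def test_relabeling_symmetry(self, toy_distance):
        d, labels = toy_distance
        swapped = ["x" if l == "b" else "y" for l in labels]
        assert permanova(d, labels, n_perm=9, seed=0).f_stat == pytest.approx(
            permanova(d, swapped, n_perm=9, seed=0).f_stat
        )

    def test_agrees_with_skbio(self, rng):
        x = rng.normal(size=(12, 5))
        x[6:] += 1.0
        d = distance_matrix(x, "euclidean")
        labels = ["a"] * 6 + ["b"] * 6
        ours = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_permanova(DistanceMatrix(d), grouping=labels, permutations=99)
        assert ours.f_stat == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_singleton_group_is_an_error(self, toy_distance):
        d, _ = toy_distance
        with pytest.raises(ValueError, match="at least 2"):
            permanova(d, ["a", "b", "b", "b", "b", "b"], n_perm=9)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        d = np.array(
            [
                [0.0, 0.1, 0.9, 0.8],
                [0.1, 0.0, 0.95, 0.85],
                [0.9, 0.95, 0.0, 0.2],
                [0.8, 0.85, 0.2, 0.0],
            ]
        )
        res = anosim(d, ["a", "a", "b", "b"], n_perm=9, seed=0)
        assert res.r_stat == pytest.approx(1.0)

    def test_matches_hand_ranked_oracle(self, toy_distance):
        d, labels = toy_distance
        res = anosim(d, labels, n_perm=9, seed=0)
        assert res.r_stat == pytest.approx(brute_force_anosim_r(d, labels), abs=1e-10)

    def test_agrees_with_skbio(self, rng):
        x = rng.normal(size=(10, 4))
        x[5:] += 1.5
        d = distance_matrix(x, "euclidean")
        labels = ["a"] * 5 + ["b"] * 5
        ours = anosim(d, labels, n_perm=99, seed=0)
        ref = skbio_anosim(DistanceMatrix(d), grouping=labels, permutations=99)
        assert ours.r_stat == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_random_labels_give_small_r(self, rng):
        x = rng.normal(size=(30, 4))
        d = distance_matrix(x, "euclidean")
        rs = []
        for _ in range(20):
            labels = rng.permutation(["a"] * 15 + ["b"] * 15)
            rs.append(anosim(d, labels, n_perm=9, seed=0).r_stat)
        assert abs(np.mean(rs)) < 0.1


class TestPcaBiplot:
    def test_variance_fractions_sum_to_one(self, rng):
        scores, loadings, frac = pca_biplot(rng.normal(size=(20, 5)))
        assert frac.sum() == pytest.approx(1.0)

    def test_rank_one_matrix_single_component(self, rng):
        u = rng.normal(size=(15, 1))
        v = rng.normal(size=(1, 4))
        _, _, frac = pca_biplot(u @ v)
        assert frac[0] == pytest.approx(1.0)

    def test_scores_match_svd_oracle_up_to_sign(self, rng):
        x = rng.normal(size=(4, 3))
        scores, loadings, _ = pca_biplot(x)
        c = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(c, full_matrices=False)
        ref = u * s
        for k in range(3):
            assert np.allclose(scores[:, k], ref[:, k]) or np.allclose(
                scores[:, k], -ref[:, k]
            )
        # reconstruction is sign-independent
        assert np.allclose(scores @ loadings.T, c, atol=1e-10)


class TestDocClassCorrelations:
    def test_ordering_and_signs(self, rng):
        n = 60
        doc = rng.uniform(5, 50, size=n)
        profiles = pd.DataFrame(
            {
                "protein": doc * 2 + rng.normal(0, 3, n),
                "tannin": -doc + rng.normal(0, 3, n),
                "carbohydrate": rng.normal(0, 1, n),
            }
        )
        res = doc_class_correlations(profiles, doc)
        assert res.loc["protein", "rho"] > 0
        assert res.loc["tannin", "rho"] < 0
        assert res.index[0] in ("protein", "tannin")  # strongest |rho| first
        assert res.index[-1] == "carbohydrate"
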