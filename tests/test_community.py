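"""Diversity measures, PERMANOVA, dispersion and ordination."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova

from beeqmp.community import (
    bray_curtis,
    dispersion,
    effective_species,
    log_transform,
    pca,
    permanova,
    shannon,
)
from beeqmp.errors import DesignError


def _euclid_dm(x):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1:
        x = x.T
    return DistanceMatrix(squareform(pdist(x)), ids=[str(i) for i in range(x.shape[0])])


class TestAlpha:
    @pytest.mark.parametrize(
        "p,expected",
        [([0.5, 0.5], np.log(2)), ([1.0], 0.0), ([0.25] * 4, np.log(4))],
    )
    def test_shannon(self, p, expected):
        assert shannon(p) == pytest.approx(expected, abs=1e-12)

    def test_effective_species(self):
        assert effective_species(np.log(2)) == pytest.approx(2.0)
        assert effective_species(0.0) == 1.0
        assert effective_species(shannon([1 / 7] * 7)) == pytest.approx(7.0)

    def test_invariance_to_order_and_scale(self):
        rng = np.random.default_rng(0)
        p = rng.random(9)
        h = shannon(p)
        assert shannon(p[::-1]) == pytest.approx(h, rel=1e-12)
        assert shannon(p * 1234.5) == pytest.approx(h, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            shannon([-0.1, 1.1])


class TestBrayCurtis:
    def test_examples(self):
        df = pd.DataFrame([[2.0, 2.0], [1.0, 3.0], [2.0, 2.0], [0.0, 5.0]],
                          index=list("wxyz"), columns=["t1", "t2"])
        dm = bray_curtis(df)
        assert dm["w", "x"] == pytest.approx(0.25)  # (1+1)/8
        assert dm["w", "y"] == 0.0
        disjoint = pd.DataFrame([[3.0, 0.0], [0.0, 7.0]], index=["a", "b"])
        assert bray_curtis(disjoint)["a", "b"] == 1.0

    def test_all_zero_sample_named(self):
        df = pd.DataFrame([[1.0, 1.0], [0.0, 0.0]], index=["ok", "void"])
        with pytest.raises(ValueError, match="void"):
            bray_curtis(df)

    def test_bounds_and_taxon_permutation_invariance(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((6, 8)) + 0.01)
        d = bray_curtis(df).data
        assert (d >= 0).all() and (d <= 1).all()
        shuffled = df[rng.permutation(df.columns)]
        np.testing.assert_allclose(bray_curtis(shuffled).data, d, atol=1e-12)


class TestPermanova:
    def test_univariate_euclidean_equals_classical_anova(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=18)
        g = np.repeat(["a", "b", "c"], 6)
        res = permanova(_euclid_dm(x), g, 99, 0)
        f_classic = sps.f_oneway(*(x[g == lv] for lv in "abc")).statistic
        assert res.observed == pytest.approx(f_classic, abs=1e-9)

    def test_matches_independent_implementation(self):
        rng = np.random.default_rng(6)
        ab = rng.random((12, 5)) + 0.05
        dm = DistanceMatrix(squareform(pdist(ab, "braycurtis")),
                            ids=[str(i) for i in range(12)])
        g = np.repeat(["a", "b", "c"], 4)
        mine = permanova(dm, g, 9, 0).observed
        other = skbio_permanova(dm, g, permutations=9)["test statistic"]
        assert mine == pytest.approx(other, rel=1e-12)

    def test_exhaustive_enumeration_n6(self):
        x = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        dm = _euclid_dm(x)
        g = np.array([0, 0, 0, 1, 1, 1])
        d2 = dm.data ** 2

        def pseudo_f(members):
            ss_t = d2.sum() / 12.0
            ss_w = sum(d2[np.ix_(m, m)].sum() / 6.0 for m in members)
            return (ss_t - ss_w) / (ss_w / 4.0)

        observed = pseudo_f([np.array([0, 1, 2]), np.array([3, 4, 5])])
        all_f = [
            pseudo_f([np.array(c), np.setdiff1d(np.arange(6), c)])
            for c in combinations(range(6), 3)
        ]
        exact_p = np.mean([f >= observed - 1e-12 for f in all_f])
        assert exact_p == pytest.approx(0.1)
        res = permanova(dm, g, 10_000, 7)
        assert abs(res.p - exact_p) < 3 * np.sqrt(exact_p * (1 - exact_p) / 10_000) + 1e-4

    def test_null_relabeling_not_significant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=20)
        res = permanova(_euclid_dm(x), np.repeat([0, 1], 10), 199, 1)
        assert res.p > 0.05 or res.observed < 2.0

    def test_group_name_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        g1 = np.repeat(["a", "b"], 6)
        g2 = np.repeat(["winter", "forager"], 6)
        r1 = permanova(_euclid_dm(x), g1, 99, 3)
        r2 = permanova(_euclid_dm(x), g2, 99, 3)
        assert r1.p == r2.p and r1.observed == r2.observed

    def test_singleton_group_rejected(self):
        with pytest.raises(DesignError):
            permanova(_euclid_dm(np.arange(5.0)), np.array([0, 0, 0, 0, 1]), 99, 0)


class TestDispersion:
    def test_toy_configuration_matches_hand_geometry(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 2.0],
                        [5.0, 0.0], [7.0, 0.0], [6.0, 2.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcdef"))
        res = dispersion(dm, ["g1"] * 3 + ["g2"] * 3, 199, 0)
        for k, ix in enumerate((slice(0, 3), slice(3, 6))):
            centroid = pts[ix].mean(axis=0)
            hand = np.linalg.norm(pts[ix] - centroid, axis=1)
            np.testing.assert_allclose(res.distances.to_numpy()[ix], hand, atol=1e-9)

    def test_mirror_groups_equal_spread_not_significant(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0],
                        [10.0, 10.0], [11.0, 10.0], [10.0, 11.0]])
        dm = DistanceMatrix(squareform(pdist(pts)), ids=list("abcdef"))
        res = dispersion(dm, ["a"] * 3 + ["b"] * 3, 199, 0)
        assert res.p > 0.5  # identical per-sample distances, F ~ 0

    def test_power_against_5x_spread_ratio(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(100):
            tight = rng.normal(0.0, 1.0, size=(10, 2))
            loose = rng.normal(0.0, 5.0, size=(10, 2))
            pts = np.vstack([tight, loose])
            dm = DistanceMatrix(squareform(pdist(pts)),
                                ids=[str(i) for i in range(20)])
            if dispersion(dm, np.repeat([0, 1], 10), 199, rng).p <= 0.05:
                rejections += 1
        assert rejections > 90


class TestLogTransform:
    def test_zero_maps_to_zero_and_powers_to_exponents(self):
        x = pd.DataFrame([[0.0, 1e6], [10.0, 1.0]])
        out = log_transform(x)
        np.testing.assert_allclose(out.to_numpy(), [[0.0, 6.0], [1.0, 0.0]])
        # idempotent on the zero set: zeros stay at log10(1) = 0
        np.testing.assert_allclose(log_transform(out * 0).to_numpy(), 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([[-1.0]]))


class TestPca:
    def _data(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(20, 4))
        x[10:, 0] += 8.0  # two clusters separated along the first variable
        return pd.DataFrame(x, columns=list("wxyz"))

    def test_separating_variable_dominates_pc1(self):
        res = pca(self._data())
        assert res.loadings["PC1"].abs().idxmax() == "w"

    def test_explained_variance_is_total_variance(self):
        data = self._data()
        res = pca(data)
        assert res.explained_variance.sum() == pytest.approx(
            data.var(ddof=1).sum(), rel=1e-9
        )
        assert res.proportion_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.explained_variance) <= 1e-12).all()

    def test_scores_match_eigendecomposition(self):
        data = self._data()
        res = pca(data)
        cov = np.cov(data.to_numpy(), rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        np.testing.assert_allclose(res.explained_variance, evals, rtol=1e-9)
        centred = data.to_numpy() - data.to_numpy().mean(axis=0)
        # scores agree with projection on eigenvectors up to per-axis sign
        proj = centred @ evecs
        for j in range(4):
            s = res.scores.iloc[:, j].to_numpy()
            assert np.allclose(s, proj[:, j], atol=1e-8) or np.allclose(
                s, -proj[:, j], atol=1e-8
            )

    def test_sign_convention_deterministic(self):
        res = pca(self._data())
        for col in res.loadings:
            v = res.loadings[col].to_numpy()
            assert v[np.abs(v).argmax()] > 0

    def test_constant_column_dropped_with_warning(self):
        data = self._data()
        data["const"] = 3.14
        with pytest.warns(UserWarning, match="const"):
            res = pca(data)
        assert "const" not in res.loadings.index
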