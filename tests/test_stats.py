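"""Diversity, ordination, PERMANOVA, and differential testing — hand
examples plus independent cross-checks against scikit-bio / statsmodels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import permanova as skbio_permanova
from skbio.stats.ordination import pcoa as skbio_pcoa
from statsmodels.stats.multitest import multipletests

from multikingdom import stats


def _profile(rows, samples=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    samples = samples or [f"s{i}" for i in range(rows.shape[0])]
    return pd.DataFrame(rows, index=samples,
                        columns=[f"f{j}" for j in range(rows.shape[1])])


class TestAlphaDiversity:
    @pytest.mark.parametrize(
        "p, h, d",
        [
            ([1.0], 0.0, 0.0),
            ([0.25] * 4, np.log(4), 0.75),
            ([0.5, 0.5], np.log(2), 0.5),
        ],
    )
    def test_closed_forms(self, p, h, d):
        assert stats.shannon(p) == pytest.approx(h)
        assert stats.simpson(p) == pytest.approx(d)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            stats.shannon([-0.1, 1.1])
        with pytest.raises(ValueError):
            stats.simpson([-0.1, 1.1])

    def test_diversity_comparison_symmetric_in_group_order(self, rng):
        profile = _profile(rng.dirichlet(np.ones(8), size=12))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=profile.index)
        flipped = groups.map({"A": "B", "B": "A"})
        t1, p1 = stats.compare_diversity(profile, groups)
        t2, p2 = stats.compare_diversity(profile, flipped)
        assert p1 == pytest.approx(p2)
        assert abs(t1) == pytest.approx(abs(t2))
        assert 0.0 <= p1 <= 1.0


class TestRarefaction:
    def test_full_size_equals_union_richness(self, rng):
        profile = _profile((rng.random((6, 20)) < 0.4) * 1.0)
        groups = pd.Series(["g"] * 6, index=profile.index)
        curve = stats.rarefaction_curve(profile, groups, n_reps=10, seed=0)
        full = curve[curve["size"] == 6]
        union = (profile.to_numpy() > 0).any(axis=0).sum()
        assert (full[["median", "q1", "q3"]] == union).all().all()

    def test_identical_samples_zero_iqr(self):
        profile = _profile([[0.5, 0.5, 0.0]] * 4)
        groups = pd.Series(["g"] * 4, index=profile.index)
        curve = stats.rarefaction_curve(profile, groups, n_reps=10, seed=0)
        assert (curve["q3"] - curve["q1"] == 0).all()
        assert (curve["median"] == 2).all()

    def test_median_curve_non_decreasing(self, rng):
        profile = _profile((rng.random((8, 30)) < 0.3) * 1.0)
        groups = pd.Series(["g"] * 8, index=profile.index)
        curve = stats.rarefaction_curve(profile, groups, n_reps=30, seed=1)
        med = curve.sort_values("size")["median"].to_numpy()
        assert (np.diff(med) >= 0).all()


class TestBrayCurtis:
    def test_hand_examples(self):
        prof = _profile([[0.5, 0.5], [1.0, 0.0], [0.5, 0.5]])
        d = stats.bray_curtis(prof)
        assert d.iloc[0, 1] == pytest.approx(0.5)
        assert d.iloc[0, 2] == pytest.approx(0.0)
        disjoint = _profile([[1.0, 0.0], [0.0, 1.0]])
        assert stats.bray_curtis(disjoint).iloc[0, 1] == pytest.approx(1.0)

    def test_agrees_with_scipy(self, rng):
        prof = _profile(rng.dirichlet(np.ones(15), size=10))
        ours = stats.bray_curtis(prof).to_numpy()
        ref = squareform(pdist(prof.to_numpy(), metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_metric_axioms_on_normalized_input(self, seed):
        rng = np.random.default_rng(seed)
        prof = _profile(rng.dirichlet(np.ones(6), size=4))
        d = stats.bray_curtis(prof).to_numpy()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        assert (np.diag(d) == 0).all()
        assert (d >= 0).all() and (d <= 1 + 1e-12).all()


class TestPcoa:
    def test_three_equidistant_points(self):
        d = pd.DataFrame(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            index=list("abc"), columns=list("abc"),
        )
        coords, frac = stats.pcoa(d, k=2)
        assert frac[0] == pytest.approx(frac[1])

    def test_euclidean_round_trip(self, rng):
        pts = rng.normal(size=(7, 2))
        d = pd.DataFrame(squareform(pdist(pts)),
                         index=[f"s{i}" for i in range(7)],
                         columns=[f"s{i}" for i in range(7)])
        coords, _ = stats.pcoa(d, k=2)
        rec = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(rec, d.to_numpy(), atol=1e-8)

    def test_duplicate_samples_coincide(self, rng):
        prof = _profile(rng.dirichlet(np.ones(5), size=4))
        prof.iloc[3] = prof.iloc[0]
        coords, _ = stats.pcoa(stats.bray_curtis(prof), k=2)
        np.testing.assert_allclose(coords.iloc[3], coords.iloc[0], atol=1e-9)

    def test_agrees_with_skbio(self, rng):
        prof = _profile(rng.dirichlet(np.ones(12), size=9))
        d = stats.bray_curtis(prof)
        ours_coords, ours_frac = stats.pcoa(d, k=2)
        ref = skbio_pcoa(DistanceMatrix(d.to_numpy(), ids=list(d.index)))
        np.testing.assert_allclose(
            ours_frac, ref.proportion_explained.iloc[:2], atol=1e-8
        )
        np.testing.assert_allclose(
            np.abs(ours_coords.to_numpy()),
            np.abs(ref.samples.iloc[:, :2].to_numpy()),
            atol=1e-6,
        )


class TestPermanova:
    def test_separated_clouds_hit_permutation_floor(self, rng):
        a = rng.normal(0, 0.05, size=(10, 3)) + [1, 0, 0]
        b = rng.normal(0, 0.05, size=(10, 3)) + [0, 1, 0]
        prof = _profile(np.abs(np.vstack([a, b])))
        prof = prof.div(prof.sum(axis=1), axis=0)
        d = stats.bray_curtis(prof)
        groups = pd.Series(["A"] * 10 + ["B"] * 10, index=prof.index)
        f, p = stats.permanova(d, groups, n_perm=1000, seed=0)
        assert p == pytest.approx(1 / 1001)
        assert f > 1

    def test_statistic_matches_skbio(self, rng):
        prof = _profile(rng.dirichlet(np.ones(10), size=12))
        d = stats.bray_curtis(prof)
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=prof.index)
        f_ours, _ = stats.permanova(d, groups, n_perm=10, seed=0)
        ref = skbio_permanova(
            DistanceMatrix(d.to_numpy(), ids=list(d.index)),
            list(groups),
            permutations=10,
        )
        assert f_ours == pytest.approx(ref["test statistic"], rel=1e-10)

    def test_duplicating_samples_increases_f(self, rng):
        prof = _profile(rng.dirichlet(np.ones(8), size=10))
        groups = pd.Series(["A"] * 5 + ["B"] * 5, index=prof.index)
        f1, _ = stats.permanova(stats.bray_curtis(prof), groups, n_perm=10, seed=0)
        doubled = pd.concat([prof, prof.set_index(prof.index + "_bis")])
        g2 = pd.concat([groups, groups.set_axis(prof.index + "_bis")])
        f2, _ = stats.permanova(stats.bray_curtis(doubled), g2, n_perm=10, seed=0)
        assert f2 > f1

    def test_seed_reproducibility_and_p_range(self, rng):
        prof = _profile(rng.dirichlet(np.ones(6), size=12))
        groups = pd.Series(["A"] * 6 + ["B"] * 6, index=prof.index)
        d = stats.bray_curtis(prof)
        r1 = stats.permanova(d, groups, n_perm=200, seed=5)
        r2 = stats.permanova(d, groups, n_perm=200, seed=5)
        assert r1 == r2
        assert 1 / 201 <= r1[1] <= 1.0

    def test_degenerate_grouping_rejected(self, rng):
        prof = _profile(rng.dirichlet(np.ones(6), size=4))
        groups = pd.Series(["A"] * 4, index=prof.index)
        with pytest.raises(ValueError):
            stats.permanova(stats.bray_curtis(prof), groups)


class TestBhAdjust:
    def test_hand_examples(self):
        np.testing.assert_allclose(stats.bh_adjust([0.02]), [0.02])
        np.testing.assert_allclose(
            stats.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4
        )

    def test_agrees_with_statsmodels(self, rng):
        p = rng.random(50)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(stats.bh_adjust(p), ref, atol=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_bounds_and_monotonicity(self, p):
        q = stats.bh_adjust(p)
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1 + 1e-12)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])


class TestDifferentialAbundance:
    def _cohort(self, rng, effect=8.0, n_feat=30, n_diff=6, n_per=20):
        x = np.exp(rng.standard_normal((2 * n_per, n_feat)))
        for k in range(n_diff):
            rows = slice(0, n_per) if k % 2 == 0 else slice(n_per, 2 * n_per)
            x[rows, k] *= effect
        x = x / x.sum(axis=1, keepdims=True)
        prof = _profile(x)
        groups = pd.Series(["OA"] * n_per + ["HC"] * n_per, index=prof.index)
        return prof, groups

    def test_constant_feature_p_one(self, rng):
        prof, groups = self._cohort(rng)
        prof.iloc[:, -1] = 0.0
        res = stats.differential_abundance(prof, groups)
        assert res.iloc[-1]["p"] == 1.0

    def test_label_swap_flips_direction_keeps_p(self, rng):
        prof, groups = self._cohort(rng)
        res1 = stats.differential_abundance(prof, groups)
        res2 = stats.differential_abundance(prof, groups.map({"OA": "HC", "HC": "OA"}))
        np.testing.assert_allclose(res1["p"], res2["p"], atol=1e-12)
        sig = res1["enriched"].notna()
        swapped = res2.loc[sig, "enriched"].map({"OA": "HC", "HC": "OA"})
        assert (res1.loc[sig, "enriched"] == swapped).all()

    def test_planted_features_found_with_direction(self, rng):
        prof, groups = self._cohort(rng, effect=10.0)
        res = stats.differential_abundance(prof, groups, q_threshold=0.05)
        for k in range(6):
            row = res.loc[f"f{k}"]
            assert row["q"] < 0.05
            assert row["enriched"] == ("OA" if k % 2 == 0 else "HC")

    def test_wilcoxon_matches_scipy_reference(self, rng):
        from scipy.stats import mannwhitneyu

        x, y = rng.normal(size=25), rng.normal(0.5, 1, size=30)
        u, p = stats.rank_sum_test(x, y)
        u_ref, p_ref = mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic", use_continuity=False)
        assert (u, p) == (u_ref, p_ref)
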