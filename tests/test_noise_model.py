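"""Pair enumeration, coverage profiles, thresholds, silhouette, GEV/PWM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from evdcnv.core import Segment
from evdcnv.noise_model import (
    ComparisonSegments,
    collect_extremes,
    coverage_entropy,
    coverage_profile,
    enumerate_pairs,
    fit_gev_pwm,
    fraction_of_coverage,
    noise_threshold,
    silhouette_index,
    corroborate_germline,
)


def seg(chrom, start, end, lr, n=10):
    return Segment(chrom=chrom, start=start, end=end, n_windows=n, seg_logratio=lr)


def comp(pair, segments):
    return ComparisonSegments(pair=pair, segments=segments)


class TestEnumeratePairs:
    def test_pair_count_30(self):
        assert len(enumerate_pairs([f"S{i}" for i in range(30)])) == 435

    @pytest.mark.parametrize("n,expected", [(2, 1), (4, 6), (10, 45)])
    def test_small_counts(self, n, expected):
        assert len(enumerate_pairs([f"S{i}" for i in range(n)])) == expected

    def test_lexicographic_unique(self):
        pairs = enumerate_pairs(["b", "a", "c"])
        assert pairs == [("a", "b"), ("a", "c"), ("b", "c")]

    def test_errors(self):
        with pytest.raises(ValueError):
            enumerate_pairs(["only"])
        with pytest.raises(ValueError):
            enumerate_pairs(["x", "x"])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(2, 100))
    def test_count_formula(self, n):
        assert len(enumerate_pairs([f"S{i}" for i in range(n)])) == n * (n - 1) // 2


class TestCoverageProfile:
    def test_single_positive_segment_threshold_boundary(self):
        c = comp(("A", "B"), [seg("chr1", 0, 25_000, 0.30)])
        prof = coverage_profile([c], "chr1", "positive", span_end=100_000)
        frac = fraction_of_coverage(prof)
        g = prof.grid.tolist()
        # covered at R_T = 0.25 and at the 0.30 boundary (at-or-above), not 0.35
        assert prof.F[g.index(0.25), :3].tolist() == [1, 1, 1]
        assert prof.F[g.index(0.30), :3].tolist() == [1, 1, 1]
        assert prof.F[g.index(0.35)].sum() == 0
        assert frac[g.index(0.25)] == pytest.approx(0.3)

    def test_additivity_across_pairs(self):
        c1 = comp(("A", "B"), [seg("chr1", 0, 25_000, 0.30)])
        c2 = comp(("A", "C"), [seg("chr1", 0, 25_000, 0.30)])
        prof = coverage_profile([c1, c2], "chr1", "positive", span_end=100_000)
        assert prof.F[0, :3].tolist() == [2, 2, 2]

    def test_direction_filtering(self):
        c = comp(("A", "B"), [seg("chr1", 0, 25_000, 0.30)])
        prof = coverage_profile([c], "chr1", "negative", span_end=100_000)
        assert prof.F.sum() == 0

    def test_entrywise_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        segs = [
            seg("chr1", int(s), int(s) + 20_000, float(lr))
            for s, lr in zip(rng.integers(0, 180_000, 30), rng.normal(0, 0.4, 30))
        ]
        prof = coverage_profile([comp(("A", "B"), segs)], "chr1", "positive", 200_000)
        assert np.all(np.diff(prof.F.astype(int), axis=0) <= 0)
        assert np.all(np.diff(fraction_of_coverage(prof)) <= 1e-12)


class TestEntropy:
    def _profile_with_counts(self, counts):
        prof = coverage_profile(
            [comp(("A", "B"), [seg("chr1", 0, 10_000, 0.01)])],
            "chr1",
            "positive",
            span_end=len(counts) * 10_000,
        )
        prof.F = np.asarray([counts], dtype=np.int64)
        prof.grid = np.array([0.0])
        return prof

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ([3, 3], 1.0),
            ([2, 2, 2, 2], 2.0),
            ([5, 0, 0], 0.0),
            ([0, 0, 0], 0.0),
        ],
    )
    def test_known_entropies(self, counts, expected):
        prof = self._profile_with_counts(counts)
        assert coverage_entropy(prof)[0] == pytest.approx(expected)


class TestNoiseThreshold:
    def test_fraction_cliff(self):
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        fraction = np.where(grid <= 0.25, 1.0, 0.05)
        entropy = np.zeros_like(grid)
        r_tf, r_te, r_nt, flags = noise_threshold(fraction, entropy, grid)
        assert r_tf == pytest.approx(0.30)

    def test_first_major_entropy_loss(self):
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        entropy = np.full_like(grid, 5.0)
        # drops: 0.1 at 0.15, 2.0 at 0.30, 0.9 at 0.40
        entropy[grid >= 0.15] -= 0.1
        entropy[grid >= 0.30] -= 2.0
        entropy[grid >= 0.40] -= 0.9
        fraction = np.ones_like(grid)
        r_tf, r_te, r_nt, flags = noise_threshold(fraction, entropy, grid)
        assert r_te == pytest.approx(0.30)

    def test_r_nt_is_max(self):
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        fraction = np.where(grid <= 0.25, 1.0, 0.1)  # R_TF = 0.30
        entropy = np.where(grid <= 0.40, 3.0, 0.0)  # R_TE = 0.45
        r_tf, r_te, r_nt, _ = noise_threshold(fraction, entropy, grid)
        assert (r_tf, r_te, r_nt) == (pytest.approx(0.30), pytest.approx(0.45), pytest.approx(0.45))

    def test_flat_vectors_flagged(self):
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        r_tf, r_te, r_nt, flags = noise_threshold(
            np.ones_like(grid), np.zeros_like(grid), grid
        )
        assert r_nt == pytest.approx(1.0)
        assert "no_structure" in flags


class TestSilhouette:
    def _two_cluster_profile(self, low_vec, high_vec, r_nt=0.5):
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        F = np.array([low_vec if g < r_nt else high_vec for g in grid], dtype=np.int64)
        prof = coverage_profile(
            [comp(("A", "B"), [seg("chr1", 0, 10_000, 0.01)])],
            "chr1",
            "positive",
            span_end=len(low_vec) * 10_000,
        )
        prof.F = F
        prof.grid = grid
        return prof

    def test_perfectly_separated_clusters(self):
        prof = self._two_cluster_profile([10, 10, 10], [0, 0, 0])
        assert silhouette_index(prof, 0.5) == pytest.approx(1.0)

    def test_identical_vectors_convention_zero(self):
        prof = self._two_cluster_profile([5, 5, 5], [5, 5, 5])
        assert silhouette_index(prof, 0.5) == pytest.approx(0.0)

    def test_tight_clusters_large_gap(self):
        rng = np.random.default_rng(0)
        grid = np.round(np.arange(0, 1.0001, 0.05), 10)
        F = np.array(
            [
                (100 + rng.integers(-2, 3, 5)) if g < 0.5 else rng.integers(0, 2, 5)
                for g in grid
            ],
            dtype=np.int64,
        )
        prof = self._two_cluster_profile([0] * 5, [0] * 5)
        prof.F = F
        assert silhouette_index(prof, 0.5) >= 0.8

    def test_one_sided_split_undefined(self):
        prof = self._two_cluster_profile([1, 1, 1], [0, 0, 0])
        assert silhouette_index(prof, -0.1) is None

    def test_agrees_with_sklearn_on_generic_profile(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(3)
        prof = self._two_cluster_profile([0] * 6, [0] * 6)
        prof.F = rng.integers(0, 50, size=(len(prof.grid), 6))
        labels = (prof.grid >= 0.4).astype(int)
        ours = silhouette_index(prof, 0.4)
        ref = silhouette_score(prof.F.astype(float), labels, metric="euclidean")
        assert ours == pytest.approx(ref, abs=1e-12)


class TestCollectExtremes:
    def test_per_comparison_maxima(self):
        comps = [
            comp(("A", "B"), [seg("chr1", 0, 1000, 0.1), seg("chr1", 1000, 2000, 0.2)]),
            comp(("A", "C"), [seg("chr1", 0, 1000, 0.05)]),
            comp(("B", "C"), []),
        ]
        assert collect_extremes(comps, "chr1", "positive", r_nt=0.5) == [0.2, 0.05]

    def test_negative_direction_minima_strict_threshold(self):
        comps = [comp(("A", "B"), [seg("chr1", 0, 1000, -0.1), seg("chr1", 1000, 2000, -0.3)])]
        assert collect_extremes(comps, "chr1", "negative", r_nt=0.25) == [-0.1]

    def test_all_above_threshold_empty(self):
        comps = [comp(("A", "B"), [seg("chr1", 0, 1000, 0.9)])]
        assert collect_extremes(comps, "chr1", "positive", r_nt=0.5) == []


class TestFitGevPwm:
    def test_gumbel_recovery(self):
        rng = np.random.default_rng(101)
        draws = stats.gumbel_r.rvs(loc=0.0, scale=1.0, size=5000, random_state=rng)
        xi, mu, sigma = fit_gev_pwm(draws)
        assert abs(xi) <= 0.05
        assert abs(mu) <= 0.05
        assert 0.95 <= sigma <= 1.05

    def test_gev_recovery(self):
        rng = np.random.default_rng(202)
        # scipy's shape c equals -xi in the block-maxima convention
        draws = stats.genextreme.rvs(c=-0.2, loc=1.0, scale=2.0, size=5000, random_state=rng)
        xi, mu, sigma = fit_gev_pwm(draws)
        assert xi == pytest.approx(0.2, abs=0.05)
        assert mu == pytest.approx(1.0, abs=0.1)
        assert sigma == pytest.approx(2.0, abs=0.1)

    def test_recovery_bias_over_replicates(self):
        rng = np.random.default_rng(303)
        errs = []
        for _ in range(100):
            draws = stats.genextreme.rvs(c=-0.1, loc=0.0, scale=1.0, size=400,
                                         random_state=rng)
            xi, mu, sigma = fit_gev_pwm(draws)
            errs.append((xi - 0.1, mu, sigma - 1.0))
        bias = np.mean(errs, axis=0)
        assert np.all(np.abs(bias) < 0.05)

    def test_negative_direction_fits_negated_minima(self):
        rng = np.random.default_rng(404)
        maxima = stats.gumbel_r.rvs(loc=0.3, scale=0.05, size=2000, random_state=rng)
        xi_p, mu_p, sig_p = fit_gev_pwm(maxima, "positive")
        xi_n, mu_n, sig_n = fit_gev_pwm(-maxima, "negative")
        assert (xi_n, mu_n, sig_n) == (xi_p, mu_p, sig_p)

    def test_agrees_with_scipy_mle_roughly(self):
        rng = np.random.default_rng(505)
        draws = stats.genextreme.rvs(c=-0.15, loc=0.5, scale=1.5, size=3000, random_state=rng)
        xi, mu, sigma = fit_gev_pwm(draws)
        c_mle, loc_mle, scale_mle = stats.genextreme.fit(draws)
        assert xi == pytest.approx(-c_mle, abs=0.05)
        assert mu == pytest.approx(loc_mle, abs=0.1)
        assert sigma == pytest.approx(scale_mle, abs=0.1)

    def test_floor_and_degeneracy_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_gev_pwm(np.linspace(0, 1, 14))
        with pytest.raises(ValueError, match="degenerate"):
            fit_gev_pwm(np.full(20, 0.3))


class TestCorroborateGermline:
    def _nn_comps(self, rng, n=8):
        comps = []
        for i in range(n):
            segs = [
                seg("chr1", 0, 20_000, float(rng.normal(0, 0.05))),
                seg("chr1", 20_000, 40_000, float(rng.choice([0.6, -0.6]))),
                seg("chr1", 40_000, 60_000, float(rng.normal(0, 0.05))),
            ]
            comps.append(comp((f"N{i}", f"N{i+1}"), segs))
        return comps

    def test_identical_tracks_give_unit_correlation(self):
        rng = np.random.default_rng(1)
        nn = self._nn_comps(rng)
        tt = [comp(c.pair, list(c.segments)) for c in nn]
        r = corroborate_germline(nn, tt, {("chr1", d): 0.3 for d in ("positive", "negative")}, seed=5)
        assert r["r_above_matched"] == pytest.approx(1.0)
        assert r["r_below_matched"] == pytest.approx(1.0)

    def test_independent_noise_kills_correlation(self):
        rng = np.random.default_rng(2)
        nn = self._nn_comps(rng, n=40)
        tt = [
            comp(
                c.pair,
                [seg(s.chrom, s.start, s.end, float(rng.normal(0, 0.3))) for s in c.segments],
            )
            for c in nn
        ]
        r = corroborate_germline(nn, tt, {("chr1", d): 0.3 for d in ("positive", "negative")}, seed=5)
        for key in ("r_above_matched", "r_above_random"):
            assert abs(r[key]) < 0.35

    def test_sparse_stratum_undefined(self):
        rng = np.random.default_rng(3)
        nn = self._nn_comps(rng, n=2)
        tt = [comp(c.pair, list(c.segments)) for c in nn]
        r = corroborate_germline(nn, tt, {("chr1", d): 10.0 for d in ("positive", "negative")}, seed=5)
        assert r["r_above_matched"] is None  # nothing above an impossible threshold
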