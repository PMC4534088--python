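"""GEV tail evaluation, call classification, pooled normals, evaluation."""

import math

import numpy as np
import pytest
from scipy import stats

from evdcnv.caller import (
    call_scnas,
    evaluate_calls,
    gev_cdf,
    pool_normals,
    segment_pvalue,
)
from evdcnv.core import ChromDirectionModel, NoiseModel, SCNACall, Segment

from conftest import make_depth_table


def model_with(xi=0.0, mu=0.2, sigma=0.05, chrom="chr1", both=True):
    model = NoiseModel(
        tile_width=100, grid_step=0.05, grid_max=1.0, bin_size=10_000,
        seed=1, n_comparisons=10,
    )
    for direction in ("positive", "negative") if both else ("positive",):
        model.entries[(chrom, direction)] = ChromDirectionModel(
            chrom=chrom, direction=direction, r_tf=0.3, r_te=0.3, r_nt=0.3,
            silhouette=0.8, k=20, xi=xi, mu=mu, sigma=sigma, modeled=True,
        )
    return model


def seg(lr, chrom="chr1", start=0, end=10_000, n=10):
    return Segment(chrom=chrom, start=start, end=end, n_windows=n, seg_logratio=lr)


class TestGevCdf:
    def test_value_at_location_is_exp_minus_one(self):
        for xi in (-0.5, -0.1, 0.0, 0.1, 0.5):
            assert gev_cdf(0.7, xi, 0.7, 1.3) == pytest.approx(math.exp(-1))

    def test_direct_evaluation(self):
        # xi=0.5, mu=0, sigma=1, y=2: exp(-(1+1)^(-2)) = exp(-0.25)
        assert gev_cdf(2.0, 0.5, 0.0, 1.0) == pytest.approx(math.exp(-0.25))

    def test_support_clamping(self):
        assert gev_cdf(3.0, -0.5, 0.0, 1.0) == 1.0  # above upper bound mu - sigma/xi = 2
        assert gev_cdf(-3.0, 0.5, 0.0, 1.0) == 0.0  # below lower bound

    def test_gumbel_limit_matches_tiny_xi(self):
        for y in (-1.0, 0.0, 0.5, 2.0):
            exact = math.exp(-math.exp(-y))
            assert gev_cdf(y, 0.0, 0.0, 1.0) == pytest.approx(exact)
            assert abs(gev_cdf(y, 1e-12, 0.0, 1.0) - exact) < 1e-6

    def test_matches_scipy_genextreme(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            xi = float(rng.uniform(-0.8, 0.8))
            mu = float(rng.uniform(-1, 1))
            sigma = float(rng.uniform(0.1, 2))
            y = float(rng.uniform(-3, 3))
            ours = gev_cdf(y, xi, mu, sigma)
            ref = stats.genextreme.cdf(y, c=-xi, loc=mu, scale=sigma)
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_sigma_validation(self):
        with pytest.raises(ValueError):
            gev_cdf(0.0, 0.0, 0.0, 0.0)


class TestSegmentPvalue:
    def test_at_location_p(self):
        model = model_with(mu=0.2)
        assert segment_pvalue(seg(0.2), model) == pytest.approx(1 - math.exp(-1))

    def test_monotone_decreasing_in_magnitude(self):
        model = model_with(xi=0.1)
        ps = [segment_pvalue(seg(lr), model) for lr in (0.05, 0.2, 0.4, 0.8, 2.0)]
        assert all(a > b for a, b in zip(ps[:-1], ps[1:]))
        assert ps[-1] < 1e-6

    def test_mirrored_models_give_equal_p(self):
        model = model_with()
        assert segment_pvalue(seg(0.4), model) == pytest.approx(
            segment_pvalue(seg(-0.4), model)
        )

    def test_zero_logratio(self):
        assert segment_pvalue(seg(0.0), model_with()) == 1.0

    def test_unmodeled_chromosome_undefined(self):
        assert segment_pvalue(seg(0.5, chrom="chrX"), model_with()) is None


class TestCallScnas:
    def test_classification_rules(self):
        model = model_with(mu=0.2, sigma=0.05)
        segments = [seg(0.6, start=0, end=10_000), seg(0.21, start=10_000, end=20_000),
                    seg(-0.6, start=20_000, end=30_000)]
        calls = call_scnas(segments, model, alpha=0.05, sample_id="T")
        assert [c.direction for c in calls] == ["amplification", "neutral", "deletion"]
        assert all(c.sample_id == "T" for c in calls)

    def test_unmodeled_is_neutral_flagged(self):
        model = model_with()
        calls = call_scnas([seg(-0.5, chrom="chr9")], model)
        assert calls[0].direction == "neutral"
        assert "unmodeled" in calls[0].flags
        assert calls[0].p_value is None

    def test_output_sorted(self):
        model = model_with()
        segments = [seg(0.1, start=50_000, end=60_000), seg(0.1, start=0, end=10_000)]
        calls = call_scnas(segments, model)
        assert calls[0].start == 0


class TestPoolNormals:
    def test_lambda_one_returns_exact_sums(self):
        a = make_depth_table([10.0, 20.0, 30.0], "A")
        b = make_depth_table([5.0, 10.0, 15.0], "B")
        pooled_total = a.total_mapped_bases + b.total_mapped_bases
        pooled = pool_normals([a, b], pooled_total, seed=1)
        assert np.allclose(pooled.mean_depth, [15.0, 30.0, 45.0])

    def test_thinning_hits_target_within_two_percent(self):
        rng = np.random.default_rng(10)
        tables = [make_depth_table(rng.uniform(40, 80, 400), f"N{i}") for i in range(4)]
        target = tables[0].total_mapped_bases
        pooled = pool_normals(tables, target, seed=3)
        assert pooled.total_mapped_bases == pytest.approx(target, rel=0.02)
        # expected depth equals the depth-weighted average profile
        expected = sum(t.mean_depth for t in tables) * (
            target / sum(t.total_mapped_bases for t in tables)
        )
        assert np.corrcoef(pooled.mean_depth, expected)[0, 1] > 0.95

    def test_determinism(self):
        tables = [make_depth_table([50.0] * 50, "A"), make_depth_table([60.0] * 50, "B")]
        p1 = pool_normals(tables, 100_000, seed=9)
        p2 = pool_normals(tables, 100_000, seed=9)
        assert np.array_equal(p1.mean_depth, p2.mean_depth)

    def test_target_above_pooled_total_is_error(self):
        tables = [make_depth_table([50.0] * 5, "A"), make_depth_table([60.0] * 5, "B")]
        with pytest.raises(ValueError, match="exceeds pooled total"):
            pool_normals(tables, 1e12, seed=1)


class TestEvaluateCalls:
    def _call(self, chrom, start, end, direction, sample="T"):
        return SCNACall(
            sample_id=sample, chrom=chrom, start=start, end=end, n_windows=10,
            seg_logratio=0.5 if direction == "amplification" else -0.5,
            direction=direction, p_value=0.01,
        )

    def test_perfect_calls(self):
        truth = [("chr1", 0, 10_000, "amplification")]
        calls = [self._call("chr1", 0, 10_000, "amplification"),
                 self._call("chr1", 10_000, 50_000, "neutral")]
        res = evaluate_calls(calls, truth)
        assert res.sensitivity == 1.0
        assert res.specificity == 1.0

    def test_no_calls(self):
        truth = [("chr1", 0, 10_000, "deletion")]
        calls = [self._call("chr1", 0, 50_000, "neutral")]
        res = evaluate_calls(calls, truth)
        assert res.sensitivity == 0.0
        assert res.specificity == 1.0

    def test_direction_flip_scores_zero_sensitivity(self):
        truth = [("chr1", 0, 10_000, "amplification")]
        calls = [self._call("chr1", 0, 10_000, "deletion"),
                 self._call("chr1", 10_000, 50_000, "neutral")]
        res = evaluate_calls(calls, truth)
        assert res.sensitivity == 0.0
        # the miscalled bases lie inside truth regions, so specificity
        # (which only charges calls on neutral bases) is unaffected
        assert res.specificity == 1.0

    def test_empty_truth_flagged(self):
        calls = [self._call("chr1", 0, 10_000, "neutral")]
        res = evaluate_calls(calls, [])
        assert res.sensitivity is None
        assert "empty_truth" in res.flags
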