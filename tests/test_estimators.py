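"""The Wald ratio and the five-method causal-estimator battery."""

import numpy as np
import pytest

from mrmediate.estimators import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    MethodFailure,
    MREstimate,
    MRSettings,
    METHOD_ORDER,
    ivw,
    mr_egger,
    run_all_methods,
    simple_mode,
    wald_ratio,
    weighted_median,
    weighted_mode,
)
from mrmediate.instruments import HarmonizedPair


def pair(bx, by, sy, sx=0.01):
    return HarmonizedPair(
        snp_id="rs1", effect_allele="A", other_allele="G",
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
    )


class TestWaldRatio:
    @pytest.mark.parametrize(
        "bx,by,sy,ratio,se",
        [(0.2, 0.1, 0.02, 0.5, 0.1), (0.2, 0.0, 0.02, 0.0, 0.1),
         (-0.2, 0.1, 0.02, -0.5, 0.1)],
    )
    def test_ratio_and_first_order_se(self, bx, by, sy, ratio, se):
        est = wald_ratio(pair(bx, by, sy))
        assert est.ratio == pytest.approx(ratio)
        assert est.se_ratio == pytest.approx(se)

    def test_zero_exposure_effect_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(pair(0.0, 0.1, 0.02))


class TestIVW:
    def test_matches_inverse_variance_weighted_average(self, make_dataset):
        # ratios 0.4 (se 0.1), 0.6 (se 0.2) with beta_X = 1:
        # (0.4/0.01 + 0.6/0.04) / (1/0.01 + 1/0.04) = 0.44
        data = make_dataset([1.0, 1.0], [0.4, 0.6], [0.1, 0.2])
        assert ivw(data).beta == pytest.approx(0.44)

    def test_exact_line_fixed_and_multiplicative_agree(self, make_dataset):
        bx = np.array([0.1, 0.2, 0.3])
        data = make_dataset(bx, 0.5 * bx, [0.02, 0.03, 0.01])
        fixed = ivw(data, model="fixed")
        mult = ivw(data, model="multiplicative_random")
        assert fixed.beta == pytest.approx(0.5)
        assert mult.beta == pytest.approx(0.5)
        assert fixed.extra["Q"] == pytest.approx(0.0, abs=1e-24)
        assert mult.se == pytest.approx(fixed.se)

    def test_point_estimate_model_invariant_and_mult_se_wider(self, make_dataset):
        rng = np.random.default_rng(3)
        data = make_dataset(rng.normal(0.2, 0.05, 8), rng.normal(0, 0.1, 8),
                            rng.uniform(0.01, 0.05, 8))
        fixed = ivw(data, model="fixed")
        mult = ivw(data, model="multiplicative_random")
        assert mult.beta == pytest.approx(fixed.beta)
        assert mult.se >= fixed.se

    def test_orientation_invariance(self, make_dataset):
        bx = np.array([0.1, -0.2, 0.3, 0.15])
        by = np.array([0.05, 0.01, -0.02, 0.04])
        sy = np.array([0.02, 0.03, 0.01, 0.02])
        base = ivw(make_dataset(bx, by, sy))
        flip = np.array([1, -1, -1, 1.0])
        flipped = ivw(make_dataset(bx * flip, by * flip, sy))
        assert flipped.beta == pytest.approx(base.beta)
        assert flipped.se == pytest.approx(base.se)

    def test_single_snp_degrades_to_wald_ratio(self, make_dataset):
        est = ivw(make_dataset([0.2], [0.1], [0.02]))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.n_snp == 1

    def test_empty_dataset_is_error(self, make_dataset):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_dataset([], [], []))


def egger_oracle(bx, by, sy):
    """Independent 2x2 normal-equations solve with the bx>=0 orientation."""
    sign = np.where(np.asarray(bx) < 0, -1.0, 1.0)
    x, y = np.asarray(bx) * sign, np.asarray(by) * sign
    w = 1.0 / np.asarray(sy) ** 2
    lhs = np.array([[w.sum(), (w * x).sum()], [(w * x).sum(), (w * x * x).sum()]])
    rhs = np.array([(w * y).sum(), (w * x * y).sum()])
    return np.linalg.solve(lhs, rhs)  # (intercept, slope)


class TestMREgger:
    def test_exact_affine_data_recovered(self, make_dataset):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        data = make_dataset(bx, 0.01 + 0.5 * bx, [0.02, 0.01, 0.03, 0.02])
        est = mr_egger(data)
        assert est.beta == pytest.approx(0.5)
        assert est.extra["egger_intercept"] == pytest.approx(0.01)
        assert est.extra["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_zero_intercept_data_matches_ivw_slope(self, make_dataset):
        bx = np.array([0.1, 0.25, 0.4])
        data = make_dataset(bx, 0.5 * bx, [0.02, 0.01, 0.03])
        est = mr_egger(data)
        assert est.extra["egger_intercept"] == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(ivw(data).beta)

    def test_random_instance_matches_normal_equations_oracle(self, make_dataset):
        rng = np.random.default_rng(11)
        bx = rng.normal(0, 0.2, 6)
        by = rng.normal(0, 0.1, 6)
        sy = rng.uniform(0.01, 0.05, 6)
        est = mr_egger(make_dataset(bx, by, sy))
        intercept, slope = egger_oracle(bx, by, sy)
        assert est.beta == pytest.approx(slope)
        assert est.extra["egger_intercept"] == pytest.approx(intercept)

    def test_fewer_than_three_instruments_is_error(self, make_dataset):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_dataset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


def weighted_median_oracle(ratios, weights):
    """Independent cumulative-weight interpolation at weight 0.5."""
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    if 0.5 <= s[0]:
        return r[0]
    for k in range(1, len(r)):
        if s[k] >= 0.5:
            return r[k - 1] + (r[k] - r[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1])
    return r[-1]


class TestWeightedMedian:
    def test_equal_weight_symmetric_ratios(self, make_dataset):
        data = make_dataset([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], [0.05, 0.05, 0.05])
        assert weighted_median(data, n_boot=200, seed=1).beta == pytest.approx(0.2)

    def test_identical_ratios_with_tight_ses(self, make_dataset):
        data = make_dataset([1.0, 1.0, 1.0], [0.3, 0.3, 0.3], [1e-4, 1e-4, 1e-4])
        est = weighted_median(data, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.3)
        assert est.se < 0.01

    def test_unequal_weights_match_cumulative_weight_oracle(self, make_dataset):
        bx = np.array([1.0, 0.5, 2.0, 1.5, 0.8])
        by = np.array([0.12, 0.04, 0.5, 0.11, 0.2])
        sy = np.array([0.02, 0.01, 0.1, 0.05, 0.03])
        est = weighted_median(make_dataset(bx, by, sy), n_boot=0, seed=0)
        ratios = by / bx
        weights = (np.abs(bx) / sy) ** 2
        assert est.beta == pytest.approx(weighted_median_oracle(ratios, weights))

    def test_insufficient_instruments(self, make_dataset):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(make_dataset([1, 1], [0.1, 0.2], [0.05, 0.05]), seed=0)


def mode_oracle(ratios, weights, phi=1.0):
    """Independent density-grid argmax with the modified Silverman bandwidth."""
    r = np.asarray(ratios, dtype=float)
    j = len(r)
    sd = np.std(r, ddof=1)
    iqr = np.percentile(r, 75) - np.percentile(r, 25)
    h = phi * 0.9 * min(sd, iqr / 1.349) * j ** (-1 / 5)
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 512)
    w = np.ones(j) / j if weights is None else np.asarray(weights) / np.sum(weights)
    best, best_d = grid[0], -1.0
    for g in grid:
        d = float(np.sum(w * np.exp(-0.5 * ((g - r) / h) ** 2)))
        if d > best_d:
            best, best_d = g, d
    return best


class TestModes:
    def test_simple_mode_finds_dominant_cluster(self, make_dataset):
        data = make_dataset([1.0] * 4, [0.5, 0.5, 0.5, 5.0], [0.05] * 4)
        est = simple_mode(data, n_boot=0, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_identical_ratios_return_common_value(self, make_dataset):
        data = make_dataset([1.0, 2.0, 0.5], [0.3, 0.6, 0.15], [0.05] * 3)
        assert simple_mode(data, n_boot=0, seed=0).beta == pytest.approx(0.3)
        assert weighted_mode(data, n_boot=0, seed=0).beta == pytest.approx(0.3)

    def test_bimodal_instance_matches_grid_oracle(self, make_dataset):
        bx = np.ones(7)
        by = np.array([0.1, 0.12, 0.11, 0.09, 0.5, 0.52, 0.48])
        sy = np.array([0.02, 0.03, 0.02, 0.04, 0.05, 0.03, 0.06])
        est = simple_mode(make_dataset(bx, by, sy), n_boot=0, seed=0)
        assert est.beta == pytest.approx(mode_oracle(by / bx, None))

    def test_weighted_mode_precision_outweighs_cluster_size(self, make_dataset):
        data = make_dataset([1.0, 1.0, 1.0], [0.5, 2.0, 2.1], [0.01, 1.0, 1.0])
        est = weighted_mode(data, n_boot=0, seed=0)
        assert est.beta == pytest.approx(0.5, abs=0.1)
        ratios = np.array([0.5, 2.0, 2.1])
        weights = 1.0 / np.array([0.01, 1.0, 1.0]) ** 2
        assert est.beta == pytest.approx(mode_oracle(ratios, weights))

    def test_equal_weights_reduce_weighted_to_simple(self, make_dataset):
        data = make_dataset(
            [1.0] * 5, [0.1, 0.3, 0.32, 0.28, 0.9], [0.05] * 5, sx=[1e-12] * 5
        )
        simple = simple_mode(data, n_boot=50, seed=9)
        weighted = weighted_mode(data, n_boot=50, seed=9)
        assert weighted.beta == pytest.approx(simple.beta)
        assert weighted.se == pytest.approx(simple.se)


class TestBattery:
    def test_method_order_and_primary_flag(self, make_dataset):
        bx = np.linspace(0.1, 0.4, 5)
        data = make_dataset(bx, 0.3 * bx, [0.02] * 5)
        results = run_all_methods(data, MRSettings(n_boot=50, seed=4))
        assert [r.method for r in results] == list(METHOD_ORDER)
        primary = [r for r in results if isinstance(r, MREstimate) and r.extra.get("primary")]
        assert len(primary) == 1 and primary[0].method == "ivw"

    def test_exact_line_collapses_all_methods_to_slope(self, make_dataset):
        bx = np.array([0.1, -0.2, 0.3, 0.25, 0.15])
        data = make_dataset(bx, 0.7 * bx, [0.02, 0.01, 0.03, 0.02, 0.01])
        results = run_all_methods(data, MRSettings(n_boot=50, seed=4))
        for est in results:
            assert isinstance(est, MREstimate)
            assert est.beta == pytest.approx(0.7, abs=1e-6), est.method

    def test_two_snp_battery_reports_per_method_failures(self, make_dataset):
        data = make_dataset([0.1, 0.2], [0.05, 0.1], [0.02, 0.02])
        results = run_all_methods(data, MRSettings(n_boot=50, seed=4))
        by_method = {r.method: r for r in results}
        assert isinstance(by_method["ivw"], MREstimate)
        for m in ("mr_egger", "weighted_median", "simple_mode", "weighted_mode"):
            assert isinstance(by_method[m], MethodFailure)

    def test_or_and_ci_are_exp_transform(self, make_dataset):
        data = make_dataset([1.0, 1.0], [0.4, 0.6], [0.1, 0.2])
        est = ivw(data)
        assert est.or_ == pytest.approx(np.exp(est.beta))
        assert est.ci_low <= est.or_ <= est.ci_high
        assert est.ci_low == pytest.approx(np.exp(est.beta - 1.959964 * est.se), rel=1e-5)


class TestScaleEquivariance:
    @pytest.mark.parametrize("k", [0.5, 2.0, 10.0])
    def test_outcome_rescaling_scales_all_estimates(self, make_dataset, k):
        rng = np.random.default_rng(21)
        bx = rng.normal(0.2, 0.05, 6)
        by = rng.normal(0.1, 0.05, 6)
        sy = rng.uniform(0.01, 0.04, 6)
        settings = MRSettings(n_boot=100, seed=5)
        base = run_all_methods(make_dataset(bx, by, sy), settings)
        scaled = run_all_methods(make_dataset(bx, k * by, k * sy), settings)
        for b, s in zip(base, scaled):
            assert s.beta == pytest.approx(k * b.beta, rel=1e-6), b.method
            assert s.se == pytest.approx(k * b.se, rel=1e-6), b.method

    def test_instrument_orientation_invariance_all_methods(self, make_dataset):
        rng = np.random.default_rng(22)
        bx = rng.normal(0.2, 0.1, 6)
        by = rng.normal(0.1, 0.05, 6)
        sy = rng.uniform(0.01, 0.04, 6)
        flip = np.array([1, -1, 1, -1, -1, 1.0])
        settings = MRSettings(n_boot=0, seed=5)
        base = run_all_methods(make_dataset(bx, by, sy), settings)
        flipped = run_all_methods(make_dataset(flip * bx, flip * by, sy), settings)
        for b, f in zip(base, flipped):
            assert f.beta == pytest.approx(b.beta, rel=1e-9), b.method
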