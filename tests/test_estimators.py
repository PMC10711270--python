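"""Wald / IVW / weighted-median / MR-Egger estimators against independent oracles."""

import numpy as np
import pytest

from mrbodycomp import (
    CollinearityError,
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)

from conftest import make_hset


def wls_origin_oracle(bx, by, sy):
    """No-intercept weighted least squares via explicit normal equations."""
    w = 1.0 / np.asarray(sy) ** 2
    bx, by = np.asarray(bx), np.asarray(by)
    beta = np.sum(w * bx * by) / np.sum(w * bx * bx)
    se_fixed = np.sum(w * bx * bx) ** -0.5
    return beta, se_fixed


def egger_oracle(bx, by, sy):
    """Two-parameter weighted normal equations solved directly."""
    sign = np.where(np.asarray(bx) < 0, -1.0, 1.0)
    x, y = np.asarray(bx) * sign, np.asarray(by) * sign
    w = 1.0 / np.asarray(sy) ** 2
    sw, swx, swxx = np.sum(w), np.sum(w * x), np.sum(w * x * x)
    swy, swxy = np.sum(w * y), np.sum(w * x * y)
    xtx = np.array([[sw, swx], [swx, swxx]])
    xty = np.array([swy, swxy])
    intercept, slope = np.linalg.solve(xtx, xty)
    resid = y - intercept - slope * x
    rss = np.sum(w * resid**2)
    n = len(x)
    phi = max(1.0, np.sqrt(rss / (n - 2)))
    cov = np.linalg.inv(xtx)
    return slope, intercept, phi * np.sqrt(cov[1, 1]), phi * np.sqrt(cov[0, 0])


def wm_oracle(ratios, weights):
    """Hand-traced cumulative-weight interpolation at 0.5."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    p = np.cumsum(w) - w / 2
    below = np.flatnonzero(p < 0.5)
    if below.size == 0:
        return r[0]
    i = below[-1]
    if i == len(r) - 1:
        return r[-1]
    return r[i] + (r[i + 1] - r[i]) * (0.5 - p[i]) / (p[i + 1] - p[i])


class TestWald:
    def test_ratio_arithmetic(self):
        assert wald_ratio(0.5, 0.01, -0.12, 0.02).beta == pytest.approx(-0.24)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.3, 0.01, 0.0, 0.02).beta == 0.0

    def test_first_order_delta_se(self):
        assert wald_ratio(0.5, 0.01, -0.12, 0.02).se == pytest.approx(0.04)
        assert wald_ratio(-0.5, 0.01, -0.12, 0.02).se == pytest.approx(0.04)

    def test_zero_exposure_effect_errors(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(0.0, 0.01, 0.1, 0.02)


class TestIVW:
    def test_single_instrument_equals_wald(self):
        h = make_hset([0.5], [0.01], [-0.12], [0.02])
        est = ivw(h, "fixed")
        w = wald_ratio(0.5, 0.01, -0.12, 0.02)
        assert est.beta == pytest.approx(w.beta)
        assert est.se == pytest.approx(w.se)

    def test_equal_weights_average_ratios(self):
        # same bx and sy => equal weights; beta = mean of ratios
        h = make_hset([0.5, 0.5], [0.01, 0.01], [0.1, 0.2], [0.02, 0.02])
        assert ivw(h, "fixed").beta == pytest.approx((0.2 + 0.4) / 2)

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_matches_wls_oracle_to_10_digits(self, random_hset, n):
        h = random_hset(n, seed=n)
        beta, se = wls_origin_oracle(h.bx, h.by, h.sy)
        est = ivw(h, "fixed")
        assert est.beta == pytest.approx(beta, rel=1e-10)
        assert est.se == pytest.approx(se, rel=1e-10)

    def test_mre_se_never_below_fixed(self, random_hset):
        for seed in range(10):
            h = random_hset(6, seed=seed)
            assert ivw(h, "multiplicative_random").se >= ivw(h, "fixed").se

    def test_mre_needs_two_instruments(self):
        h = make_hset([0.5], [0.01], [0.1], [0.02])
        with pytest.raises(InsufficientInstrumentsError):
            ivw(h, "multiplicative_random")

    def test_default_mode_is_mre_for_multiple(self, random_hset):
        h = random_hset(5, seed=1)
        assert ivw(h).method == "ivw_mre"
        assert ivw(h.subset([0])).method == "ivw_fe"


class TestWeightedMedian:
    def test_constant_ratios_recovered(self):
        h = make_hset([0.2, 0.4, 0.5], [0.01] * 3, [0.06, 0.12, 0.15], [0.02] * 3)
        assert weighted_median(h, seed=0).beta == pytest.approx(0.3)

    def test_equal_weights_middle_ratio(self):
        # ratios 1, 2, 9 with equal weights: cumulative midpoint is ratio 2
        h = make_hset([0.1, 0.1, 0.1], [0.01] * 3, [0.1, 0.2, 0.9], [0.02] * 3)
        assert weighted_median(h, seed=0).beta == pytest.approx(2.0)

    def test_four_instrument_interpolation_matches_hand_trace(self):
        bx = np.array([0.2, 0.3, 0.25, 0.5])
        sy = np.array([0.02, 0.03, 0.025, 0.04])
        by = np.array([0.02, 0.09, 0.0125, 0.30])
        h = make_hset(bx, [0.01] * 4, by, sy)
        expected = wm_oracle(by / bx, bx**2 / sy**2)
        assert weighted_median(h, seed=0).beta == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_random_sets_match_oracle(self, random_hset, n):
        h = random_hset(n, seed=100 + n)
        expected = wm_oracle(h.by / h.bx, h.bx**2 / h.sy**2)
        assert weighted_median(h, seed=0).beta == pytest.approx(expected, rel=1e-10)

    def test_bootstrap_se_stable_across_seeds(self, random_hset):
        h = random_hset(8, seed=77)
        se1 = weighted_median(h, n_boot=5000, seed=1).se
        se2 = weighted_median(h, n_boot=5000, seed=2).se
        assert abs(se1 - se2) / se1 < 0.05

    def test_beta_within_ratio_range(self, random_hset):
        for seed in range(10):
            h = random_hset(6, seed=seed)
            ratios = h.by / h.bx
            beta = weighted_median(h, n_boot=50, seed=0).beta
            assert ratios.min() - 1e-12 <= beta <= ratios.max() + 1e-12

    def test_needs_three_instruments(self):
        h = make_hset([0.5, 0.4], [0.01] * 2, [0.1, 0.1], [0.02] * 2)
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(h, seed=0)


class TestEgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        h = make_hset(bx, [0.01] * 4, 0.3 * bx, [0.02] * 4)
        est = mr_egger(h)
        assert est.beta == pytest.approx(0.3, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_added_to_by_shifts_intercept_only(self):
        bx = np.array([0.1, 0.25, 0.3, 0.45, 0.2])
        by = 0.3 * bx + np.array([0.001, -0.002, 0.0, 0.003, -0.001])
        h1 = make_hset(bx, [0.01] * 5, by, [0.02] * 5)
        h2 = make_hset(bx, [0.01] * 5, by + 0.05, [0.02] * 5)
        e1, e2 = mr_egger(h1), mr_egger(h2)
        assert e2.beta == pytest.approx(e1.beta, rel=1e-9)
        assert e2.intercept - e1.intercept == pytest.approx(0.05, rel=1e-9)

    @pytest.mark.parametrize("n", [3, 6, 10])
    def test_matches_normal_equations_oracle(self, random_hset, n):
        h = random_hset(n, seed=200 + n)
        slope, intercept, slope_se, int_se = egger_oracle(h.bx, h.by, h.sy)
        est = mr_egger(h)
        assert est.beta == pytest.approx(slope, rel=1e-10)
        assert est.intercept == pytest.approx(intercept, rel=1e-10)
        assert est.se == pytest.approx(slope_se, rel=1e-8)
        assert est.intercept_se == pytest.approx(int_se, rel=1e-8)

    def test_degenerate_design_errors(self):
        h = make_hset([0.2, 0.2, 0.2], [0.01] * 3, [0.1, 0.2, 0.3], [0.02] * 3)
        with pytest.raises(CollinearityError):
            mr_egger(h)


class TestEggerCalibration:
    def test_intercept_recovers_mean_pleiotropic_effect(self):
        """Under InSIDE-satisfying directional pleiotropy the Egger intercept
        estimates the mean direct effect across instruments (to within 20%
        over 100 replicates)."""
        from mrbodycomp import SimulationConfig, harmonize_sets, simulate_sumstats

        intercepts, true_means = [], []
        for seed in range(100):
            exp, out, truth = simulate_sumstats(
                SimulationConfig(pleiotropy_mode="directional", seed=seed))
            hset, _ = harmonize_sets(exp, out)
            intercepts.append(mr_egger(hset).intercept)
            true_means.append(truth.alpha.mean())
        target = np.mean(true_means)
        assert abs(np.mean(intercepts) - target) <= 0.2 * target


class TestSharedProperties:
    def test_scale_equivariance(self, random_hset):
        """Multiplying by and sy by k scales every estimate and SE by k."""
        h = random_hset(6, seed=9)
        k = 3.7
        hk = make_hset(h.bx, h.sx, k * h.by, k * h.sy)
        assert ivw(hk).beta == pytest.approx(k * ivw(h).beta, rel=1e-10)
        assert ivw(hk).se == pytest.approx(k * ivw(h).se, rel=1e-10)
        assert mr_egger(hk).beta == pytest.approx(k * mr_egger(h).beta, rel=1e-10)
        wm_h = weighted_median(h, n_boot=50, seed=4)
        wm_hk = weighted_median(hk, n_boot=50, seed=4)
        assert wm_hk.beta == pytest.approx(k * wm_h.beta, rel=1e-10)

    def test_instrument_permutation_invariance(self, random_hset, rng):
        h = random_hset(7, seed=13)
        perm = rng.permutation(7)
        hp = h.subset(perm)
        assert ivw(hp).beta == pytest.approx(ivw(h).beta, rel=1e-12)
        assert mr_egger(hp).beta == pytest.approx(mr_egger(h).beta, rel=1e-12)
        assert weighted_median(hp, n_boot=10, seed=0).beta == pytest.approx(
            weighted_median(h, n_boot=10, seed=0).beta, rel=1e-12)

    def test_ci_brackets_beta_with_normal_multiplier(self, random_hset):
        h = random_hset(5, seed=21)
        for est in (ivw(h), mr_egger(h), weighted_median(h, n_boot=50, seed=0)):
            assert est.ci_low <= est.beta <= est.ci_high
            assert est.ci_high - est.beta == pytest.approx(1.959964 * est.se, rel=1e-9)
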