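import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrbidir.gwas_io import InputError
from mrbidir.mr_estimators import (cochran_q, ivw, leave_one_out, mr_egger,
                                   simple_median, wald_ratio, weighted_median,
                                   _weighted_median_point)
from mrbidir.synthetic_data import SimulationParams, simulate_gwas_pair
from mrbidir.harmonization import harmonize_all

from conftest import make_insts


def _random_insts(rng, n=20):
    bx = rng.uniform(0.05, 0.2, n) * rng.choice([-1, 1], n)
    by = 0.1 * bx + rng.normal(0, 0.01, n)
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.005, 0.02, n)
    return make_insts(bx, by, sx, sy)


class TestWaldRatio:
    def test_direct_arithmetic(self):
        inst = make_insts([0.1], [0.05], [0.01], [0.02])[0]
        est = wald_ratio(inst)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)
        assert est.ci_low == pytest.approx(0.5 - 1.959964 * 0.2)

    def test_zero_outcome_effect_gives_zero_symmetric_ci(self):
        est = wald_ratio(make_insts([0.1], [0.0], [0.01], [0.02])[0])
        assert est.beta == 0.0
        assert est.ci_low == pytest.approx(-est.ci_high)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(InputError, match="zero exposure"):
            wald_ratio(make_insts([0.0], [0.05])[0])

    def test_second_order_se_close_for_strong_instrument(self):
        # exposure z = 10, causal ratio 0.1: the exposure-noise term of the
        # second-order delta SE adds < 1% to the first-order SE
        inst = make_insts([0.1], [0.01], [0.01], [0.02])[0]
        first = wald_ratio(inst).se
        second = wald_ratio(inst, second_order=True).se
        assert second > first
        assert (second - first) / first < 0.01


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        inst = make_insts([0.1], [0.05], [0.01], [0.02])[0]
        with pytest.warns(UserWarning):
            est = ivw([inst])
        wr = wald_ratio(inst)
        assert est.beta == wr.beta and est.se == wr.se
        assert est.method == "ivw_fixed"

    def test_equal_weight_mean_of_two_ratios(self):
        # ratios 0.4 and 0.6 with equal ratio-scale SEs (0.2): mean 0.5,
        # se 0.2/sqrt(2)
        insts = make_insts([0.1, 0.1], [0.04, 0.06], [0.01, 0.01], [0.02, 0.02])
        est = ivw(insts)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2 / np.sqrt(2))

    def test_fixed_equals_zero_intercept_wls_slope(self, rng):
        # algebraic identity, cross-checked against statsmodels WLS
        for _ in range(10):
            insts = _random_insts(rng)
            est = ivw(insts)
            x = np.array([i.beta_exp for i in insts])
            y = np.array([i.beta_out for i in insts])
            w = np.array([1 / i.se_out**2 for i in insts])
            slope = sm.WLS(y, x, weights=w).fit().params[0]
            assert est.beta == pytest.approx(slope, abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        insts = _random_insts(rng)
        assert ivw(insts, "random").se >= ivw(insts, "fixed").se
        assert ivw(insts, "random").beta == pytest.approx(ivw(insts).beta)

    def test_no_instruments_is_error(self):
        with pytest.raises(InputError):
            ivw([])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_order_and_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        insts = _random_insts(rng, n=8)
        est = ivw(insts)
        perm = list(insts)
        rng.shuffle(perm)
        flipped = [dataclasses.replace(i, beta_exp=-i.beta_exp,
                                       beta_out=-i.beta_out) for i in perm]
        est2 = ivw(flipped)
        assert est2.beta == pytest.approx(est.beta, rel=1e-12)
        assert est2.se == pytest.approx(est.se, rel=1e-12)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        insts = make_insts([0.1, 0.2], [0.05, 0.10], [0.01, 0.01], [0.02, 0.02])
        het = cochran_q(insts)
        assert het.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)

    def test_hand_evaluated_q_of_two(self):
        # ratios 0 and 1, ratio SEs 0.5 (weights 4): Q = 4*(0.5)^2 + 4*(0.5)^2
        insts = make_insts([1.0, 1.0], [0.0, 1.0], [0.01, 0.01], [0.5, 0.5])
        het = cochran_q(insts)
        assert het.q_statistic == pytest.approx(2.0)
        assert het.df == 1

    def test_single_instrument_is_error(self):
        with pytest.raises(InputError):
            cochran_q(make_insts([0.1], [0.05]))


class TestMrEgger:
    def test_points_on_line_through_origin(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        insts = make_insts(bx, 0.5 * bx, 0.01 * np.ones(4), 0.02 * np.ones(4))
        res = mr_egger(insts)
        assert res.slope.beta == pytest.approx(0.5, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.intercept_pvalue > 0.99

    def test_directional_pleiotropy_recovered(self):
        # constant pleiotropy 0.02 on every outcome effect, strong
        # instruments, low noise: intercept ~= 0.02, slope ~= theta
        rng = np.random.default_rng(5)
        n = 100
        bx = rng.uniform(0.05, 0.2, n)
        by = 0.1 * bx + 0.02 + rng.normal(0, 0.001, n)
        insts = make_insts(bx, by, 0.002 * np.ones(n), 0.001 * np.ones(n))
        res = mr_egger(insts)
        assert res.intercept == pytest.approx(0.02, abs=0.002)
        assert res.slope.beta == pytest.approx(0.1, abs=0.02)

    def test_matches_statsmodels_wls_fit(self, rng):
        insts = _random_insts(rng)
        res = mr_egger(insts)
        bx = np.array([i.beta_exp for i in insts])
        by = np.array([i.beta_out for i in insts])
        sy = np.array([i.se_out for i in insts])
        sign = np.where(bx < 0, -1, 1)
        x, y = bx * sign, by * sign
        fit = sm.WLS(y, sm.add_constant(x), weights=1 / sy**2).fit()
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.slope.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_too_few_or_collinear_instruments_error(self):
        with pytest.raises(InputError):
            mr_egger(make_insts([0.1, 0.2], [0.01, 0.02]))
        with pytest.raises(InputError, match="collinear"):
            mr_egger(make_insts([0.1, 0.1, 0.1], [0.01, 0.02, 0.03]))


class TestMedians:
    def test_odd_count_simple_median(self):
        insts = make_insts([0.1, 0.1, 0.1], [0.01, 0.02, 0.09])
        est = simple_median(insts, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.2)

    def test_noise_free_bootstrap_se_vanishes(self):
        insts = make_insts([0.1, 0.1, 0.1], [0.01, 0.02, 0.03],
                           se_out=[1e-12, 1e-12, 1e-12])
        est = simple_median(insts, n_boot=200, seed=1)
        assert est.se < 1e-9

    def test_weighted_median_interpolation_hand_value(self):
        # ratios {1, 2, 10}, normalized weights {0.45, 0.45, 0.10}:
        # interpolate 0.5 between percentiles 0.225 and 0.675 -> 1.6111
        ratios = np.array([1.0, 2.0, 10.0])
        weights = np.array([0.45, 0.45, 0.10])
        assert _weighted_median_point(ratios, weights) == \
            pytest.approx(1.0 + 0.275 / 0.45)

    @pytest.mark.parametrize("n", [5, 6])
    def test_equal_weights_reduce_to_simple_median(self, n, rng):
        bx = rng.uniform(0.05, 0.2, n)
        by = rng.normal(0.1, 0.05, n) * bx
        insts = make_insts(bx, by, 0.01 * np.ones(n), 0.02 * bx / 0.1)
        # equal ratio-scale weights: se_out proportional to |beta_exp|
        wm = weighted_median(insts, n_boot=200, seed=3)
        smed = simple_median(insts, n_boot=200, seed=3)
        assert wm.beta == pytest.approx(smed.beta, abs=1e-12)

    def test_bootstrap_se_matches_asymptotic_median_se(self):
        # n identical instruments: median SE ~ 1.2533 * se / sqrt(n)
        n = 200
        insts = make_insts(np.full(n, 0.1), np.full(n, 0.01),
                           np.full(n, 0.001), np.full(n, 0.005))
        est = simple_median(insts, n_boot=2000, seed=7)
        expected = 1.2533 * 0.05 / np.sqrt(n)
        assert est.se == pytest.approx(expected, rel=0.15)

    def test_fewer_than_three_instruments_error(self):
        with pytest.raises(InputError):
            simple_median(make_insts([0.1, 0.2], [0.01, 0.02]))
        with pytest.raises(InputError):
            weighted_median(make_insts([0.1, 0.2], [0.01, 0.02]))

    def test_bootstrap_deterministic_given_seed(self):
        insts = make_insts([0.1, 0.12, 0.15, 0.2], [0.01, 0.015, 0.012, 0.02])
        a = weighted_median(insts, n_boot=300, seed=42)
        b = weighted_median(insts, n_boot=300, seed=42)
        assert a == b


class TestLeaveOneOut:
    def test_cardinality(self):
        insts = make_insts([0.1, 0.12, 0.15], [0.01, 0.012, 0.015])
        loo = leave_one_out(insts)
        assert len(loo) == 3
        assert {e.label for e in loo} == {i.snp_id for i in insts}

    def test_homogeneous_instruments_agree(self, rng):
        insts = _random_insts(rng, n=15)
        loo = leave_one_out(insts)
        for a in loo:
            for b in loo:
                assert b.ci_low <= a.beta <= b.ci_high

    def test_outlier_omission_shifts_estimate_most(self, rng):
        insts = _random_insts(rng, n=15)
        outlier = dataclasses.replace(insts[0], beta_out=insts[0].beta_out + 0.5)
        insts = [outlier] + insts[1:]
        full = ivw(insts).beta
        loo = leave_one_out(insts)
        shifts = {e.label: abs(e.beta - full) for e in loo}
        assert max(shifts, key=shifts.get) == outlier.snp_id


class TestCalibration:
    """Sampling-distribution checks of the IVW estimator on simulated data."""

    def test_weighted_median_robust_to_minority_pleiotropy(self):
        # 30% of instruments given directional pleiotropy: the weighted
        # median's bias stays below half the IVW bias on seed averages
        theta, n_bad_frac, shift = 0.1, 0.3, 0.05
        ivw_err, wm_err = [], []
        for seed in range(300):
            exposure, outcome, _ = simulate_gwas_pair(SimulationParams(
                n_snps=50, theta=theta, min_instrument_z=10, seed=seed))
            rng = np.random.default_rng(seed + 10**6)
            bad = rng.random(len(outcome)) < n_bad_frac
            # pleiotropy oriented along the exposure-raising allele
            signs = [np.sign(e.beta) for e in exposure]
            recs = [dataclasses.replace(r, beta=r.beta + signs[j] * shift)
                    if bad[j] else r for j, r in enumerate(outcome)]
            insts, _ = harmonize_all(exposure, outcome.replace_records(recs))
            ivw_err.append(ivw(insts).beta - theta)
            ratios = np.array([i.beta_out / i.beta_exp for i in insts])
            w = np.array([(abs(i.beta_exp) / i.se_out) ** 2 for i in insts])
            wm_err.append(_weighted_median_point(ratios, w) - theta)
        assert abs(np.mean(wm_err)) < 0.5 * abs(np.mean(ivw_err))
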