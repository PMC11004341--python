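"""Causal estimators: Wald ratio, IVW, Egger, weighted median, weighted mode."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from mrchain.estimators import (
    egger,
    estimate_all,
    ivw,
    wald_ratio,
    weighted_median,
    weighted_mode,
    _weighted_median,
)
from mrchain.exceptions import InsufficientInstrumentsError
from mrchain.synthetic import simulate_instruments


def frame_from(bx, by, sy, sx=0.005):
    j = len(bx)
    return pd.DataFrame(
        {
            "rsid": [f"i{k}" for k in range(j)],
            "beta_exp": np.asarray(bx, dtype=float),
            "se_exp": np.full(j, sx),
            "p_exp": np.full(j, 1e-10),
            "n_exp": np.full(j, 100_000),
            "beta_out": np.asarray(by, dtype=float),
            "se_out": np.asarray(sy, dtype=float)
            if np.ndim(sy)
            else np.full(j, float(sy)),
            "p_out": np.full(j, 0.01),
            "n_out": np.full(j, 100_000),
        }
    )


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(frame_from([0.1], [0.05], 0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)
        assert est.odds_ratio == pytest.approx(math.exp(0.5))

    def test_zero_outcome_effect(self):
        assert wald_ratio(frame_from([0.1], [0.0], 0.01)).beta == 0.0

    def test_joint_sign_flip_invariance(self):
        a = wald_ratio(frame_from([0.1], [0.05], 0.01))
        b = wald_ratio(frame_from([-0.1], [-0.05], 0.01))
        assert a.beta == pytest.approx(b.beta) and a.se == pytest.approx(b.se)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(frame_from([0.0], [0.05], 0.01))


class TestIVW:
    def test_worked_three_instrument_solution(self, three_instruments):
        est = ivw(three_instruments, "fixed")
        assert est.beta == pytest.approx(0.108 / 0.21)
        assert est.se == pytest.approx(math.sqrt(0.0004 / 0.21))
        assert est.n_snps == 3

    def test_proportional_data_fixed_equals_random(self, proportional_instruments):
        fixed = ivw(proportional_instruments, "fixed")
        random = ivw(proportional_instruments, "random")
        assert fixed.beta == pytest.approx(0.5)
        assert fixed.se == pytest.approx(random.se)  # Q = 0 -> floor at 1

    def test_single_instrument_equals_wald_ratio(self):
        fr = frame_from([0.13], [0.071], 0.02)
        assert ivw(fr, "fixed").beta == pytest.approx(wald_ratio(fr).beta)
        assert ivw(fr, "fixed").se == pytest.approx(wald_ratio(fr).se)

    def test_order_and_joint_sign_flip_invariance(self, three_instruments):
        base = ivw(three_instruments, "fixed")
        shuffled = ivw(three_instruments.iloc[[2, 0, 1]], "fixed")
        flipped = three_instruments.copy()
        flipped.loc[1, ["beta_exp", "beta_out"]] *= -1
        assert ivw(flipped, "fixed").beta == pytest.approx(base.beta)
        assert shuffled.beta == pytest.approx(base.beta)

    def test_random_se_never_below_fixed(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            j = int(rng.integers(2, 15))
            fr = frame_from(
                rng.uniform(0.02, 0.2, j),
                rng.normal(0, 0.05, j),
                rng.uniform(0.005, 0.03, j),
            )
            assert ivw(fr, "random").se >= ivw(fr, "fixed").se - 1e-15

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            ivw(frame_from([0.0, 0.0], [0.1, 0.1], 0.01), "fixed")


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.05, 0.08, 0.1, 0.12, 0.15])
        est = egger(frame_from(bx, 0.02 + 0.5 * bx, 0.01))
        assert est.beta == pytest.approx(0.5)
        assert est.intercept == pytest.approx(0.02)

    def test_no_pleiotropy_zero_intercept(self):
        bx = np.array([0.05, 0.08, 0.1, 0.12])
        est = egger(frame_from(bx, 0.5 * bx, 0.01))
        assert est.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constrained_intercept_equals_ivw_same_weights(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.02, 0.2, 10)
        by = 0.3 * bx + rng.normal(0, 0.01, 10)
        fr = frame_from(bx, by, 0.01)
        constrained = egger(fr, constrain_intercept=True)
        # IVW with weights 1/se_out^2 on (bx, by) is exactly IVW on ratios
        assert constrained.beta == pytest.approx(ivw(fr, "fixed").beta)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(11)
        bx = rng.uniform(0.02, 0.2, 30)
        sy = rng.uniform(0.005, 0.02, 30)
        by = 0.01 + 0.4 * bx + rng.normal(0, sy)
        fr = frame_from(bx, by, sy)
        est = egger(fr)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert est.intercept == pytest.approx(fit.params[0])
        assert est.beta == pytest.approx(fit.params[1])
        sigma = math.sqrt(fit.scale)
        adjust = max(1.0, sigma) / sigma  # package floors the dispersion at 1
        assert est.se == pytest.approx(fit.bse[1] * adjust)
        assert est.intercept_se == pytest.approx(fit.bse[0] * adjust)
        if sigma >= 1:
            assert est.intercept_p == pytest.approx(fit.pvalues[0])

    def test_directional_pleiotropy_intercept_recovery(self):
        fr, _ = simulate_instruments(
            200, theta=0.14, seed=17,
            pleiotropy_mode="directional", pleiotropy_mean=0.03, pleiotropy_sd=0.005,
        )
        est = egger(fr)
        assert est.intercept == pytest.approx(0.03, abs=0.01)

    def test_too_few_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(frame_from([0.1, 0.2], [0.05, 0.1], 0.01))


class TestWeightedMedian:
    def test_symmetric_ratios_give_middle(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.04, 0.05, 0.06])
        est = weighted_median(frame_from(bx, by, 0.01), n_boot=100, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_outlier_resistant_with_majority_weight(self):
        # 10 valid instruments at ratio 0.5 carry most weight; 3 outliers at 5.0
        bx = np.concatenate([np.full(10, 0.2), np.full(3, 0.05)])
        by = np.concatenate([np.full(10, 0.1), np.full(3, 0.25)])
        fr = frame_from(bx, by, 0.01)
        est = weighted_median(fr, n_boot=200, seed=1)
        ratios = fr["beta_out"] / fr["beta_exp"]
        weights = (fr["beta_exp"] / fr["se_out"]) ** 2
        oracle = _weighted_median(ratios.to_numpy(), weights.to_numpy())
        assert est.beta == pytest.approx(oracle)
        assert abs(est.beta - 0.5) < 0.05

    def test_seeded_bootstrap_reproducible(self, three_instruments):
        a = weighted_median(three_instruments, n_boot=300, seed=9)
        b = weighted_median(three_instruments, n_boot=300, seed=9)
        assert a.se == b.se

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_estimate_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(3, 12))
        fr = frame_from(
            rng.uniform(0.05, 0.2, j), rng.normal(0.02, 0.05, j), 0.01
        )
        est = weighted_median(fr, n_boot=50, seed=seed)
        ratios = fr["beta_out"] / fr["beta_exp"]
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12


class TestWeightedMode:
    def test_degenerate_ratios_return_exact(self, proportional_instruments):
        est = weighted_mode(proportional_instruments, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)
        assert est.se == 0.0

    def test_bimodal_mass_wins(self):
        # heavy cluster at 0.5 (7 SNPs, high weight), light cluster at 2.0
        bx = np.concatenate([np.full(7, 0.2), np.full(3, 0.05)])
        by = np.concatenate([0.1 + np.linspace(-0.004, 0.004, 7), np.full(3, 0.1)])
        fr = frame_from(bx, by, 0.01)
        est = weighted_mode(fr, n_boot=50, seed=2)
        # independent dense-grid oracle over the same kernel density
        ratios = (fr["beta_out"] / fr["beta_exp"]).to_numpy()
        weights = ((fr["beta_exp"] / fr["se_out"]) ** 2).to_numpy()
        weights = weights / weights.sum()
        wm = _weighted_median(ratios, weights)
        mad = _weighted_median(np.abs(ratios - wm), weights)
        grid = np.linspace(ratios.min() - 3 * mad, ratios.max() + 3 * mad, 20_001)
        dens = weights @ np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / mad) ** 2)
        oracle = grid[np.argmax(dens)]
        assert abs(est.beta - oracle) < 0.02
        assert abs(est.beta - 0.5) < 0.1

    def test_seeded_bootstrap_reproducible(self, three_instruments):
        a = weighted_mode(three_instruments, n_boot=200, seed=4)
        b = weighted_mode(three_instruments, n_boot=200, seed=4)
        assert a.se == b.se


class TestEstimateAll:
    def test_method_availability_by_instrument_count(self, three_instruments):
        single = estimate_all(three_instruments.iloc[[0]], seed=0)
        assert set(single) == {"wald_ratio", "ivw_fixed"}
        pair = estimate_all(three_instruments.iloc[:2], seed=0)
        assert set(pair) == {"ivw_fixed", "ivw_random"}
        full = estimate_all(three_instruments, n_boot=50, seed=0)
        assert {"egger", "weighted_median", "weighted_mode"} <= set(full)

    def test_ci_brackets_estimate(self, three_instruments):
        for est in estimate_all(three_instruments, n_boot=50, seed=0).values():
            assert est.ci_low <= est.beta <= est.ci_high
            if est.odds_ratio is not None:
                assert est.odds_ratio == pytest.approx(math.exp(est.beta))
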