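import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsedyn.turnover_kinetics import (
    correct_rate_for_recycling,
    estimate_recycling_factor,
    fit_turnover_rate,
    half_life_from_rate,
    incorporation_fraction,
    ratio_from_fraction,
    select_reliable_fits,
)


def grid_minimizer(times, ratios, width=4001):
    """Independent oracle: brute-force grid scan of the fit loss
    sum((ln(r+1) - k t)^2) followed by the exact parabola vertex through the
    three grid points around the argmin (the loss is exactly quadratic in k,
    so the vertex of any bracketing triple is the minimizer)."""
    t = np.asarray(times, dtype=float)
    y = np.log1p(np.asarray(ratios, dtype=float))
    lo, hi = 0.0, max(np.max(y / t), 1e-12) * 1.5
    ks = np.linspace(lo, hi, width)
    loss = ((y[None, :] - ks[:, None] * t[None, :]) ** 2).sum(axis=1)
    best = int(np.clip(np.argmin(loss), 1, width - 2))
    l1, l2, l3 = loss[best - 1], loss[best], loss[best + 1]
    d = ks[1] - ks[0]
    return ks[best] + 0.5 * d * (l1 - l3) / (l1 - 2 * l2 + l3)


class TestIncorporationFraction:
    def test_symmetry_point(self):
        assert incorporation_fraction(1.0) == 0.5

    def test_persistence_endpoint_regime(self):
        # fraction 8.64% corresponds to ratio 0.0864/(1-0.0864) = 0.09457
        assert incorporation_fraction(0.09457) == pytest.approx(0.0864, abs=5e-5)

    def test_resuscitation_saturation_regime(self):
        # fraction 94.6% corresponds to ratio 0.946/0.054 = 17.52
        assert incorporation_fraction(17.52) == pytest.approx(0.946, abs=5e-5)

    @pytest.mark.parametrize("bad", [-0.1, math.inf, math.nan])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            incorporation_fraction(bad)

    @given(st.floats(min_value=0.0, max_value=0.999999))
    def test_inverse_of_ratio(self, frac):
        assert incorporation_fraction(ratio_from_fraction(frac)) == pytest.approx(
            frac, abs=1e-12
        )

    def test_strictly_increasing(self):
        rs = np.linspace(0, 50, 200)
        fs = [incorporation_fraction(r) for r in rs]
        assert all(b > a for a, b in zip(fs, fs[1:]))


class TestFitTurnoverRate:
    def test_exact_exponential_recovery(self):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        ratios = np.exp(0.1 * times) - 1
        fit = fit_turnover_rate(times, ratios)
        assert fit.k == pytest.approx(0.1, rel=1e-14)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-14)

    def test_single_point_formula(self):
        fit = fit_turnover_rate([10.0], [1.0])
        assert fit.k == pytest.approx(math.log(2) * 10 / 100, rel=1e-12)
        assert fit.k == pytest.approx(0.0693147, rel=1e-5)

    def test_zero_signal(self):
        fit = fit_turnover_rate([1.0, 2.0, 3.0, 4.0, 5.0], [0.0] * 5)
        assert fit.k == 0.0
        assert math.isnan(fit.r_squared)
        assert fit.reliable is False
        assert math.isinf(fit.half_life_h)

    def test_zero_ratio_cells_kept(self):
        fit = fit_turnover_rate([1.0, 2.0], [0.0, math.e - 1])
        assert fit.n_points == 2
        assert fit.k == pytest.approx(2 / 5)  # (0*1 + 1*2) / (1 + 4)

    @pytest.mark.parametrize(
        "times,ratios,err",
        [
            ([], [], "empty"),
            ([0.0, 1.0], [0.1, 0.2], "> 0"),
            ([1.0], [-0.1], ">= 0"),
            ([1.0, 2.0], [0.1], "equal length"),
        ],
    )
    def test_input_errors(self, times, ratios, err):
        with pytest.raises(ValueError, match=err):
            fit_turnover_rate(times, ratios)

    def test_matches_grid_oracle_on_random_inputs(self, rng):
        for _ in range(25):
            m = rng.integers(3, 12)
            times = np.sort(rng.uniform(0.2, 30.0, size=m))
            k_true = rng.uniform(0.01, 0.8)
            noise = rng.lognormal(0, 0.2, size=m)
            ratios = (np.exp(k_true * times) - 1) * noise
            fit = fit_turnover_rate(times, ratios)
            k_oracle = grid_minimizer(times, ratios)
            assert fit.k == pytest.approx(k_oracle, rel=1e-10)

    def test_scale_consistency(self):
        k = 0.25
        times = np.linspace(0.5, 12, 9)
        fit1 = fit_turnover_rate(times, np.exp(k * times) - 1)
        doubled = 2 * times
        fit2 = fit_turnover_rate(doubled, np.exp(k / 2 * doubled) - 1)
        assert fit2.k == pytest.approx(fit1.k / 2, rel=1e-12)

    @settings(max_examples=30, deadline=None)
    @given(k=st.floats(min_value=1e-4, max_value=1.0))
    def test_noiseless_machine_precision(self, k):
        times = np.linspace(0.25, 24.0, 17)
        fit = fit_turnover_rate(times, np.expm1(k * times))
        assert fit.k == pytest.approx(k, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


class TestHalfLife:
    def test_identity(self):
        assert half_life_from_rate(math.log(2)) == pytest.approx(1.0)

    def test_persistence_median_regime(self):
        assert half_life_from_rate(math.log(2) / 250.0) == pytest.approx(250.0, rel=1e-12)

    def test_zero_rate_sentinel(self):
        assert math.isinf(half_life_from_rate(0.0))

    def test_negative_rate_error(self):
        with pytest.raises(ValueError):
            half_life_from_rate(-0.1)

    @given(st.floats(min_value=1e-8, max_value=1e4))
    def test_product_is_ln2(self, k):
        assert half_life_from_rate(k) * k == pytest.approx(math.log(2), rel=1e-12)


class TestSelectReliableFits:
    def make_fit(self, n, r2):
        times = np.linspace(1, 10, n)
        fit = fit_turnover_rate(times, np.expm1(0.1 * times))
        fit.n_points, fit.r_squared = n, r2
        return fit

    def test_four_points_excluded(self):
        assert select_reliable_fits([self.make_fit(4, 0.99)]) == []

    def test_low_r2_excluded(self):
        assert select_reliable_fits([self.make_fit(6, 0.69)]) == []

    def test_good_fit_retained(self):
        out = select_reliable_fits([self.make_fit(5, 0.95)])
        assert len(out) == 1 and out[0].reliable

    def test_boundary_r2_excluded(self):
        # the threshold is strict: R^2 must exceed 0.70
        assert select_reliable_fits([self.make_fit(6, 0.70)]) == []


class TestRecycling:
    def test_worked_example(self):
        est = estimate_recycling_factor((64, 32))
        assert est.pool_purity == pytest.approx(0.8)

    def test_matches_binomial_likelihood_oracle(self):
        # oracle: grid-maximize the likelihood of the observed label classes,
        # HH w.p. p^2 and HL w.p. 2p(1-p), normalized over the two observable
        # classes (unlabeled LL peptides are not in the newly synthesized pool)
        n_hh, n_hl = 64, 32
        ps = np.linspace(1e-6, 1 - 1e-6, 2_000_001)
        ll = (
            n_hh * 2 * np.log(ps)
            + n_hl * (np.log(2) + np.log(ps) + np.log1p(-ps))
            - (n_hh + n_hl) * np.log(ps**2 + 2 * ps * (1 - ps))
        )
        p_oracle = ps[np.argmax(ll)]
        assert estimate_recycling_factor((n_hh, n_hl)).pool_purity == pytest.approx(
            p_oracle, abs=1e-6
        )

    def test_pure_pool(self):
        assert estimate_recycling_factor((10, 0)).pool_purity == 1.0

    def test_fully_mixed(self):
        assert estimate_recycling_factor((0, 10)).pool_purity == 0.0

    def test_both_zero_error(self):
        with pytest.raises(ValueError):
            estimate_recycling_factor((0, 0))

    def test_rate_correction(self):
        est = estimate_recycling_factor((64, 32))
        assert correct_rate_for_recycling(0.04, est) == pytest.approx(0.05)
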