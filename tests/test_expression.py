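"""Stochastic expression: noise conventions, buffering, and curve fitting."""

import numpy as np
import pytest

from dupfate.expression import (
    CopySpec,
    DOUBLING_DUPLICATE,
    NoiseParams,
    SHARING_DUPLICATE,
    SINGLETON,
    curve_deviation_test,
    deterministic_response,
    expression_cv,
    hill_slope_at_x0,
    median_dose_response,
    sample_expression,
    stochastic_response,
)
from dupfate.fitness import DEFAULT_PARAMS

X0 = DEFAULT_PARAMS.x0


class TestDeterministic:
    def test_hill_midpoint(self):
        assert deterministic_response(X0) == pytest.approx(0.5)

    def test_no_lactose_no_expression(self):
        for copies in (SINGLETON, SHARING_DUPLICATE, DOUBLING_DUPLICATE):
            assert deterministic_response(0.0, copies=copies) == 0.0

    def test_double_dose(self):
        assert deterministic_response(2 * X0) == pytest.approx(16 / 17)

    def test_total_scales_with_copies(self):
        y1 = deterministic_response(X0, copies=SINGLETON)
        y2 = deterministic_response(X0, copies=DOUBLING_DUPLICATE)
        assert y2 == pytest.approx(2 * y1)


class TestStochastic:
    def test_zero_noise_is_deterministic(self, rng):
        y, draw = stochastic_response(0.2, noise=NoiseParams(), rng=rng)
        assert y == pytest.approx(deterministic_response(0.2))
        assert draw.z0 == 1.0 and all(z == 1.0 for z in draw.z)

    def test_extrinsic_only_duplicate_matches_singleton(self, rng):
        """With z1 = z2 = 1 a shared z0 makes the dosage-sharing duplicate
        bit-identical to the singleton: no gain from extrinsic noise."""
        z0 = np.exp(rng.normal(0, 0.5, 1000))
        x = np.full(1000, 0.2)
        noise = NoiseParams(0.0, 0.5)
        y_s = sample_expression(x, copies=SINGLETON, noise=noise, rng=rng, z0=z0)
        y_d = sample_expression(x, copies=SHARING_DUPLICATE, noise=noise, rng=rng, z0=z0)
        np.testing.assert_array_equal(y_s, y_d)

    def test_mean_at_midpoint_symmetric_noise(self, rng):
        """y(u) + y(1/u) = 1 at x = x0, so symmetric log-noise keeps mean 0.5."""
        y = sample_expression(X0, 20_000, noise=NoiseParams(0.5, 0.0), rng=rng)
        assert y.mean() == pytest.approx(0.5, abs=0.01)

    def test_bounded_and_monotone(self, rng):
        y = sample_expression(X0, 5_000, copies=SHARING_DUPLICATE,
                              noise=NoiseParams(1.0, 1.0), rng=rng)
        assert np.all((y >= 0) & (y <= 1.0))

    def test_variance_halving_intrinsic_only(self, rng):
        """Averaging two independent half-responses halves the variance."""
        n = 100_000
        noise = NoiseParams(0.5, 0.0)
        y_s = sample_expression(X0, n, copies=SINGLETON, noise=noise, rng=rng)
        y_d = sample_expression(X0, n, copies=SHARING_DUPLICATE, noise=noise, rng=rng)
        assert y_d.var() / y_s.var() == pytest.approx(0.5, abs=0.02)

    def test_variance_reduction_mixed_noise_linear_theory(self, rng):
        """With both noise sources the reduction approaches half the
        intrinsic variance share, 0.5*s_in^2/(s_in^2+s_ex^2)."""
        n = 100_000
        noise = NoiseParams(0.3, 0.3)
        y_s = sample_expression(X0, n, copies=SINGLETON, noise=noise, rng=rng)
        y_d = sample_expression(X0, n, copies=SHARING_DUPLICATE, noise=noise, rng=rng)
        reduction = 1.0 - y_d.var() / y_s.var()
        assert reduction == pytest.approx(0.25, abs=0.05)


class TestCV:
    def test_zero_noise(self, rng):
        assert expression_cv(X0, noise=NoiseParams(), rng=rng) == 0.0

    @pytest.mark.parametrize("eta, cv", [(0.1, 0.26), (0.5, 0.72)])
    def test_printed_band(self, eta, cv, rng):
        est = expression_cv(
            X0, noise=NoiseParams(eta, eta), n_samples=100_000, rng=rng
        )
        assert est == pytest.approx(cv, abs=0.01)

    def test_zero_dose_undefined(self, rng):
        assert np.isnan(expression_cv(0.0, noise=NoiseParams(0.5, 0.0), rng=rng))


class TestMedianCurve:
    def doses(self):
        return np.logspace(np.log10(X0 / 30), np.log10(X0 * 30), 40)

    def test_zero_noise_equals_deterministic(self):
        cur = median_dose_response(self.doses(), noise=NoiseParams())
        np.testing.assert_allclose(
            cur["y_median"], deterministic_response(self.doses()), rtol=1e-12
        )

    def test_singleton_median_preserved_at_midpoint(self, rng):
        cur = median_dose_response(
            np.array([X0]), noise=NoiseParams(0.5, 0.0), n_samples=20_000, rng=rng
        )
        assert cur["y_median"].iloc[0] == pytest.approx(0.5, abs=0.01)

    def test_hill_fit_deterministic(self):
        cur = median_dose_response(self.doses(), noise=NoiseParams())
        n_eff, slope = hill_slope_at_x0(cur)
        assert n_eff == pytest.approx(4.0, abs=1e-6)
        assert slope == pytest.approx(1.0, abs=1e-6)

    def test_hill_fit_scaling_linearity(self):
        cur = median_dose_response(self.doses(), noise=NoiseParams())
        cur2 = cur.assign(y_median=2 * cur["y_median"])
        n1, s1 = hill_slope_at_x0(cur)
        n2, s2 = hill_slope_at_x0(cur2)
        assert n2 == pytest.approx(n1, rel=1e-6)
        assert s2 == pytest.approx(2 * s1, rel=1e-6)

    def test_duplicate_median_curve_flattened(self, rng):
        """Dosage-sharing duplication smooths the median response to an
        effective Hill coefficient near 3 (slope ~ 0.75)."""
        cur = median_dose_response(
            self.doses(), copies=SHARING_DUPLICATE,
            noise=NoiseParams(0.5, 0.0), n_samples=4_000, rng=rng,
        )
        n_eff, slope = hill_slope_at_x0(cur)
        assert n_eff == pytest.approx(3.0, abs=0.4)
        assert slope == pytest.approx(0.75, abs=0.08)

    def test_short_curve_rejected(self):
        cur = median_dose_response(np.array([0.1, 0.12, 0.14]), noise=NoiseParams())
        with pytest.raises(ValueError):
            hill_slope_at_x0(cur)


class TestCurveDeviation:
    def test_wild_type_ec50_is_near_optimal(self, rng):
        p = curve_deviation_test(m=1000, rng=rng)
        assert 0.0 <= p < 0.15

    def test_degenerate_range_all_tie(self, rng):
        p = curve_deviation_test(x0_range=(0.13, 0.13), m=100, rng=rng)
        assert p == 1.0


class TestValidation:
    def test_copyspec_rejects_empty_and_nonpositive(self):
        with pytest.raises(ValueError):
            CopySpec(())
        with pytest.raises(ValueError):
            CopySpec((0.5, 0.0))

    def test_noise_rejects_negative(self):
        with pytest.raises(ValueError):
            NoiseParams(-0.1, 0.0)
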