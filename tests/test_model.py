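"""The model core: baseline, excitation kernel, intensity, effect curves.

Frozen expected values were computed with 40-digit mpmath evaluations of
the printed closed forms, independent of the package's numpy/log-gamma
implementation path.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hawkespd import (
    PARAM_RANGES,
    TRUE_PARAMS,
    BaselineParams,
    EventSchedule,
    HawkesParams,
    KernelParams,
    baseline_mu,
    cumulative_effect_curve,
    dose_response,
    excitation_kernel,
    intensity,
)

# mpmath (40 dps) evaluations of the printed formulas
BASELINE_AT_0 = 74.54648713412840847698  # 70 + 5 sin(2)
KERNEL_LAG2_VERBATIM = 28.931784672278764078  # Table-1 truth, lag 2, dose 25
KERNEL_LAG2_NORMALIZED = 3.0337175044519377322e-3
FITTED_VECTOR = (75.0, 1.21, 0.13, 1.39, 0.30, 2.08, 0.80, -0.47, 0.0022, 2.77, 0.12)
FITTED_INTENSITY_AT_10 = 1757.2142209331030912  # one event at t=0, dose 25


def kernel_param_strategy():
    return st.builds(
        KernelParams,
        a1=st.floats(*PARAM_RANGES["a1"]),
        b1=st.floats(*PARAM_RANGES["b1"]),
        kappa1=st.floats(*PARAM_RANGES["kappa1"]),
        m1=st.floats(*PARAM_RANGES["m1"]),
        a2=st.floats(*PARAM_RANGES["a2"]),
        kappa2=st.floats(*PARAM_RANGES["kappa2"]),
        b2=st.floats(*PARAM_RANGES["b2"]),
    )


class TestBaseline:
    def test_zero_amplitude_gives_level(self):
        p = BaselineParams(70.0, 0.0, 1.0, 2.0)
        assert baseline_mu(123.4, p) == 70.0

    def test_frozen_value(self):
        assert baseline_mu(0.0, TRUE_PARAMS.baseline) == pytest.approx(
            BASELINE_AT_0, rel=1e-14
        )

    def test_periodicity(self):
        p = TRUE_PARAMS.baseline
        t = np.linspace(0, 20, 7)
        np.testing.assert_allclose(
            baseline_mu(t, p), baseline_mu(t + 2 * np.pi / p.alpha0, p), rtol=1e-12
        )

    def test_strict_mode_rejects_nonpositive_mu(self):
        p = BaselineParams(1.0, 10.0, 1.0, 2.0)  # admissible box allows mu <= 0
        with pytest.raises(ValueError):
            baseline_mu(np.linspace(0, 10, 50), p, strict=True)
        with pytest.warns(RuntimeWarning):
            baseline_mu(np.linspace(0, 10, 50), p)

    def test_non_finite_time_rejected(self):
        with pytest.raises(ValueError):
            baseline_mu(np.inf, TRUE_PARAMS.baseline)

    def test_zero_frequency_rejected(self):
        with pytest.raises(ValueError):
            BaselineParams(70.0, 5.0, 0.0, 2.0)


class TestKernel:
    def test_zero_at_lag_zero(self):
        assert excitation_kernel(0.0, 25.0, TRUE_PARAMS.kernel) == 0.0

    def test_decays_to_zero(self):
        assert excitation_kernel(1e4, 25.0, TRUE_PARAMS.kernel) < 1e-300

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            excitation_kernel(-0.1, 25.0, TRUE_PARAMS.kernel)

    def test_frozen_value_verbatim(self):
        assert excitation_kernel(2.0, 25.0, TRUE_PARAMS.kernel) == pytest.approx(
            KERNEL_LAG2_VERBATIM, rel=1e-12
        )

    def test_frozen_value_normalized(self):
        assert excitation_kernel(
            2.0, 25.0, TRUE_PARAMS.kernel, normalized=True
        ) == pytest.approx(KERNEL_LAG2_NORMALIZED, rel=1e-12)

    def test_normalization_ratio_is_b2_power(self):
        p = TRUE_PARAMS.kernel
        ratio = excitation_kernel(3.0, 25.0, p) / excitation_kernel(3.0, 25.0, p, normalized=True)
        assert ratio == pytest.approx(p.b2 ** (-2 * p.kappa2), rel=1e-10)

    @given(kernel_param_strategy(), st.floats(0.0, 500.0), st.floats(0.1, 100.0))
    def test_non_negative_over_admissible_box(self, p, lag, dose):
        assert excitation_kernel(lag, dose, p) >= 0.0

    @given(kernel_param_strategy(), st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    def test_dose_response_monotone_and_bounded(self, p, d1, d2):
        lo, hi = sorted([d1, d2])
        r_lo, r_hi = dose_response(lo, p), dose_response(hi, p)
        assert r_lo <= r_hi * (1 + 1e-12)  # kappa1 * a2 > 0 in the box
        assert 0.0 < r_hi <= 1.0 / p.a1 + 1e-12

    def test_large_kappa2_no_overflow(self):
        p = KernelParams(1.0, 1.0, 0.3, -20.0, 3.0, 22.0, 0.01)
        assert np.isfinite(excitation_kernel(5.0, 25.0, p))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(1.0, 1.0, 0.3, -20.0, 3.0, 1.0, 0.4)  # kappa2 <= 1
        with pytest.raises(ValueError):
            KernelParams(0.0, 1.0, 0.3, -20.0, 3.0, 5.0, 0.4)  # a1 <= 0
        with pytest.raises(ValueError):
            KernelParams(1.0, 1.0, 0.3, -20.0, 3.0, 5.0, 0.0)  # b2 <= 0


class TestIntensity:
    def test_empty_schedule_equals_baseline(self):
        t = np.linspace(0, 100, 17)
        np.testing.assert_array_equal(
            intensity(t, EventSchedule(), TRUE_PARAMS),
            baseline_mu(t, TRUE_PARAMS.baseline),
        )

    def test_additivity_of_events(self):
        t = np.linspace(0, 60, 31)
        s1 = EventSchedule.from_arrays([5.0], [25.0])
        s2 = EventSchedule.from_arrays([20.0], [30.0])
        both = EventSchedule.from_arrays([5.0, 20.0], [25.0, 30.0])
        mu = baseline_mu(t, TRUE_PARAMS.baseline)
        np.testing.assert_allclose(
            intensity(t, both, TRUE_PARAMS) - mu,
            (intensity(t, s1, TRUE_PARAMS) - mu) + (intensity(t, s2, TRUE_PARAMS) - mu),
            rtol=1e-12,
        )

    def test_causality_future_events_ignored(self):
        t = 15.0
        past = EventSchedule.from_arrays([5.0], [25.0])
        with_future = EventSchedule.from_arrays([5.0, 15.0, 40.0], [25.0, 25.0, 25.0])
        assert intensity(t, past, TRUE_PARAMS) == intensity(t, with_future, TRUE_PARAMS)

    def test_frozen_fitted_vector_value(self):
        theta = HawkesParams.from_vector(FITTED_VECTOR)
        schedule = EventSchedule.from_arrays([0.0], [25.0])
        assert intensity(10.0, schedule, theta) == pytest.approx(
            FITTED_INTENSITY_AT_10, rel=1e-12
        )


class TestEffectCurve:
    def test_no_events_zero_curve(self):
        total, components = cumulative_effect_curve(
            np.arange(10.0), EventSchedule(), TRUE_PARAMS.kernel
        )
        assert not total.any() and components.shape == (0, 10)

    def test_total_is_sum_of_components(self, rng):
        grid = np.arange(0.0, 200.0)
        schedule = EventSchedule.from_arrays(np.sort(rng.uniform(0, 150, 8)), np.full(8, 25.0))
        total, components = cumulative_effect_curve(grid, schedule, TRUE_PARAMS.kernel)
        np.testing.assert_allclose(total, components.sum(axis=0), rtol=1e-12)

    def test_single_event_curve_unimodal_with_peak_at_gamma_mode(self):
        # dense-grid oracle: the Gamma factor peaks at (kappa2 - 1) / b2
        p = TRUE_PARAMS.kernel
        grid = np.linspace(0.0, 60.0, 6001)
        total, _ = cumulative_effect_curve(grid, EventSchedule.from_arrays([0.0], [25.0]), p)
        peak = grid[np.argmax(total)]
        assert peak == pytest.approx((p.kappa2 - 1) / p.b2, abs=0.02)
        rising = np.diff(total[(grid > 0) & (grid <= peak)])
        falling = np.diff(total[grid >= peak])
        assert (rising >= -1e-12).all() and (falling <= 1e-12).all()


class TestParameterVector:
    def test_flattening_order(self):
        np.testing.assert_array_equal(
            TRUE_PARAMS.to_vector(), [70, 5, 1, 2, 1, 1, 0.3, -20, 3, 5, 0.4]
        )

    def test_vector_round_trip(self):
        assert HawkesParams.from_vector(TRUE_PARAMS.to_vector()) == TRUE_PARAMS

    def test_dict_round_trip(self):
        assert HawkesParams.from_dict(TRUE_PARAMS.to_dict()) == TRUE_PARAMS

    def test_replace_single_parameter(self):
        changed = TRUE_PARAMS.replace(kappa1=0.5)
        assert changed.kernel.kappa1 == 0.5
        assert changed.replace(kappa1=0.3) == TRUE_PARAMS
        with pytest.raises(KeyError):
            TRUE_PARAMS.replace(nonsense=1.0)
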