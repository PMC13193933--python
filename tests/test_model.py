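"""Core interference equation: point predictions, tables, linear variant."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rfdmodel import (
    DurationError,
    ExtrapolationWarning,
    InterferenceParams,
    ParameterError,
    percent_loss,
    predict_linear,
    predict_rfd,
    predict_table,
    results_to_frame,
)

from conftest import TABLE_DURATIONS, TABLE_RFD_ROUNDED


params_strategy = st.builds(
    InterferenceParams,
    rfd0=st.floats(100.0, 50000.0),
    kappa=st.floats(0.0, 1.0),
    alpha=st.floats(0.0, 2.0),
    d0=st.floats(0.0, 10.0),
    d_max=st.just(60.0),
)


class TestPredictRfd:
    @pytest.mark.parametrize(
        "d, expected_1dp",
        [
            (0, 15000.0),
            (2, 15000.0),  # exactly at the onset delay: no loss yet
            (5, 7878.8),
            (10, 4088.6),
            (20, 3054.2),
            (30, 3002.7),
            (60, 3000.0),
        ],
    )
    def test_default_predictions(self, d, expected_1dp, defaults):
        assert round(predict_rfd(d, defaults), 1) == expected_1dp

    def test_worked_example_rounds_to_4089(self, defaults):
        assert round(predict_rfd(10, defaults)) == 4089

    @pytest.mark.parametrize(
        "rfd0, expected_1dp", [(16652, 4538.9), (7663, 2088.7)]
    )
    def test_athlete_baselines_at_ten_minutes(self, rfd0, expected_1dp, defaults):
        assert round(predict_rfd(10, defaults.replace(rfd0=rfd0)), 1) == expected_1dp

    def test_large_duration_approaches_floor(self, defaults):
        with pytest.warns(ExtrapolationWarning):
            value = predict_rfd(1000, defaults)
        assert value == pytest.approx(defaults.rfd_floor, rel=1e-12)
        assert value >= defaults.rfd_floor

    def test_continuous_at_onset_delay(self, defaults):
        eps = 1e-9
        assert predict_rfd(defaults.d0, defaults) == defaults.rfd0
        assert predict_rfd(defaults.d0 + eps, defaults) == pytest.approx(
            defaults.rfd0, rel=1e-9
        )

    def test_array_input_matches_scalar(self, defaults):
        grid = np.array([0.0, 5.0, 10.0, 30.0])
        vec = predict_rfd(grid, defaults)
        assert isinstance(vec, np.ndarray)
        assert vec.tolist() == [predict_rfd(float(d), defaults) for d in grid]

    def test_negative_duration_rejected(self, defaults):
        with pytest.raises(DurationError):
            predict_rfd(-1.0, defaults)

    def test_beyond_domain_warns_but_evaluates(self, defaults):
        with pytest.warns(ExtrapolationWarning):
            value = predict_rfd(90, defaults)
        assert defaults.rfd_floor <= value < defaults.rfd0


class TestPercentLoss:
    @pytest.mark.parametrize(
        "d, expected_1dp",
        [(0, 0.0), (2, 0.0), (9, 70.2), (10, 72.7), (20, 79.6)],
    )
    def test_default_percent_loss(self, d, expected_1dp, defaults):
        assert round(percent_loss(d, defaults), 1) == expected_1dp

    def test_closed_form(self, defaults):
        # 100 * kappa * (1 - exp(-alpha * (d - d0)))
        d = 10.0
        expected = 100 * 0.8 * (1 - math.exp(-0.3 * 8))
        assert percent_loss(d, defaults) == pytest.approx(expected, rel=1e-14)

    def test_independent_of_rfd0(self, defaults):
        for rfd0 in (1.0, 7663.0, 16652.0):
            assert percent_loss(10, defaults.replace(rfd0=rfd0)) == percent_loss(
                10, defaults
            )


class TestPredictLinear:
    def test_anchors_and_midpoint(self, defaults):
        assert predict_linear(defaults.d0, defaults) == 15000.0
        assert predict_linear(60, defaults) == 3000.0
        # midpoint of the (2, 60) segment: arithmetic mean of the endpoints
        assert predict_linear(31, defaults) == pytest.approx(9000.0, rel=1e-12)

    def test_value_on_chord(self, defaults):
        # chord through (2, 15000) and (60, 3000) evaluated at d=10
        expected = 15000 - 12000 * (10 - 2) / (60 - 2)
        assert predict_linear(10, defaults) == pytest.approx(expected, rel=1e-12)
        assert round(predict_linear(10, defaults), 1) == 13344.8

    def test_clamped_beyond_domain(self, defaults):
        with pytest.warns(ExtrapolationWarning):
            assert predict_linear(120, defaults) == pytest.approx(
                defaults.rfd_floor, rel=1e-12
            )


class TestPredictTable:
    def test_reproduces_tabulated_grid(self, defaults):
        results = predict_table(TABLE_DURATIONS, defaults)
        assert [r.predicted_rfd_rounded for r in results] == TABLE_RFD_ROUNDED
        assert [r.duration for r in results] == [float(d) for d in TABLE_DURATIONS]

    def test_elementwise_consistency_and_losses(self, defaults):
        results = predict_table([10.0, 5.0, 0.0], defaults)  # order preserved
        for r in results:
            assert r.predicted_rfd == predict_rfd(r.duration, defaults)
            assert r.percent_loss == percent_loss(r.duration, defaults)
            assert r.predicted_rfd + r.absolute_loss == pytest.approx(
                defaults.rfd0, rel=1e-14
            )
        assert [r.duration for r in results] == [10.0, 5.0, 0.0]

    def test_empty_input_rejected(self, defaults):
        with pytest.raises(DurationError):
            predict_table([], defaults)

    def test_negative_duration_identified(self, defaults):
        with pytest.raises(DurationError, match="-5"):
            predict_table([0, 10, -5], defaults)

    def test_frame_carries_full_and_rounded(self, defaults):
        frame = results_to_frame(predict_table([10], defaults))
        row = frame.iloc[0]
        assert row["predicted_rfd"] == pytest.approx(4088.6154394729483)
        assert row["predicted_rfd_rounded"] == 4089
        assert row["percent_loss_rounded"] == 73


class TestParameterValidation:
    @pytest.mark.parametrize(
        "field, bad",
        [
            ("rfd0", 0.0),
            ("rfd0", -100.0),
            ("kappa", -0.1),
            ("kappa", 1.5),
            ("alpha", -0.3),
            ("d0", -1.0),
        ],
    )
    def test_invalid_field_named_in_error(self, field, bad):
        with pytest.raises(ParameterError, match=field):
            InterferenceParams(**{field: bad})

    def test_d0_above_d_max_rejected(self):
        with pytest.raises(ParameterError, match="d0"):
            InterferenceParams(d0=70, d_max=60)

    def test_defaults_match_weightlifter_settings(self, defaults):
        assert (defaults.rfd0, defaults.kappa, defaults.alpha, defaults.d0, defaults.d_max) == (
            15000.0, 0.8, 0.3, 2.0, 60.0
        )


class TestProperties:
    @given(params=params_strategy, d=st.floats(0.0, 10.0))
    def test_identity_region_below_onset(self, params, d):
        d = min(d, params.d0)
        assert predict_rfd(d, params) == params.rfd0
        assert percent_loss(d, params) == 0.0

    @given(params=params_strategy)
    def test_monotone_nonincreasing_and_floored(self, params):
        grid = np.linspace(0.0, params.d_max, 121)
        vals = predict_rfd(grid, params)
        assert np.all(np.diff(vals) <= 1e-9 * params.rfd0)
        assert np.all(vals >= params.rfd_floor - 1e-9 * params.rfd0)
        assert np.all(vals <= params.rfd0)

    @given(params=params_strategy, c=st.floats(0.01, 100.0), d=st.floats(0.0, 60.0))
    def test_homogeneity_in_rfd0(self, params, c, d):
        scaled = params.replace(rfd0=params.rfd0 * c)
        assert predict_rfd(d, scaled) == pytest.approx(
            c * predict_rfd(d, params), rel=1e-12
        )
        assert percent_loss(d, scaled) == percent_loss(d, params)

    @given(params=params_strategy, d=st.floats(0.0, 60.0))
    def test_no_interference_when_kappa_or_alpha_zero(self, params, d):
        assert predict_rfd(d, params.replace(kappa=0.0)) == params.rfd0
        assert predict_rfd(d, params.replace(alpha=0.0)) == params.rfd0

    @given(params=params_strategy)
    def test_strict_decrease_beyond_onset(self, params):
        if params.alpha < 1e-3 or params.kappa < 1e-3:
            return  # degenerate: interference numerically absent
        d1 = params.d0 + 1.0
        d2 = params.d0 + 5.0
        assert predict_rfd(d2, params) < predict_rfd(d1, params) < params.rfd0

    @given(params=params_strategy, d=st.floats(0.0, 60.0))
    def test_nonlinear_never_above_linear_chord(self, params, d):
        # the linear variant's d_max anchor sits at the asymptotic floor,
        # below the exponential's value there by exactly this terminal gap
        gap = params.rfd0 * params.kappa * math.exp(
            -params.alpha * (params.d_max - params.d0)
        )
        assert predict_rfd(d, params) <= (
            predict_linear(d, params) + gap + 1e-9 * params.rfd0
        )
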