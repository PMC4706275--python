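"""Structural model: warped phase, circadian values, covariates, Box-Cox."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import circamix as cm
from circamix.structural import boxcox_eta_inv, semesters_from_season


class TestSeasons:
    @pytest.mark.parametrize(
        "date,season,sem1,sem2",
        [
            ("2014-01-15", "winter", 1, 1),
            ("2014-03-19", "winter", 1, 1),
            ("2014-03-20", "spring", 1, 0),  # boundary belongs to spring
            ("2014-06-19", "spring", 1, 0),
            ("2014-06-20", "summer", 0, 0),
            ("2014-08-01", "summer", 0, 0),
            ("2014-09-21", "summer", 0, 0),
            ("2014-09-22", "fall", 0, 1),
            ("2014-12-20", "fall", 0, 1),
            ("2014-12-21", "winter", 1, 1),
            ("2014-12-31", "winter", 1, 1),
        ],
    )
    def test_boundaries(self, date, season, sem1, sem2):
        assert cm.classify_season(date) == (season, sem1, sem2)

    def test_invalid_date(self):
        with pytest.raises(ValueError):
            cm.classify_season("not-a-date")
        with pytest.raises(ValueError):
            cm.classify_season(42)

    def test_semesters_consistent_with_classification(self):
        for season in ("winter", "spring", "summer", "fall"):
            s1, s2 = semesters_from_season(season)
            assert s1 == int(season in ("winter", "spring"))
            assert s2 == int(season in ("fall", "winter"))


class TestStretchTau:
    def test_anchor_points(self, ref_params):
        p = ref_params
        assert cm.stretch_tau(p.t_max, p.t_max, p.t_min) == pytest.approx(0.0)
        assert cm.stretch_tau(p.t_min, p.t_max, p.t_min) == pytest.approx(12.0)

    def test_peak_to_nadir_interval(self, ref_params):
        # 9:22 -> 14:02 gives L1 = 4h40m; the rhythm's decline lasts ~5 h
        assert ref_params.L1 == pytest.approx(4.6667, abs=1e-4)
        assert round(ref_params.L1) == 5

    def test_symmetric_case_is_identity_warp(self):
        t = np.arange(0.0, 24.0, 0.01)
        tau = cm.stretch_tau(t, 7.0, 19.0)
        assert np.allclose(tau, np.mod(t - 7.0, 24.0), atol=1e-12)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ValueError):
            cm.stretch_tau(5.0, 9.0, 9.0)

    @given(
        t_max=st.floats(0.0, 23.99),
        L1=st.floats(0.5, 23.5),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_and_continuous(self, t_max, L1):
        t_min = (t_max + L1) % 24.0
        t24 = np.linspace(0.0, 23.99, 2000)
        tau = cm.stretch_tau(t_max + t24, t_max, t_min)
        assert np.all(np.diff(tau) > 0)
        assert np.max(np.diff(tau)) < 24.0 / min(L1, 24 - L1) * 0.013


class TestCircadianValue:
    def test_extremes_attained(self, ref_params):
        p = ref_params
        assert cm.circadian_value(p.t_max, p.amplitude, p.t_max, p.t_min) == \
            pytest.approx(p.amplitude)
        assert cm.circadian_value(p.t_min, p.amplitude, p.t_max, p.t_min) == \
            pytest.approx(-p.amplitude)

    def test_noon_value_matches_scalar_oracle(self, ref_params):
        # independent scalar evaluation: tau = 12/L1*(12-t_max) = 6.7714,
        # cos(2*pi*6.7714/24) = -0.20060 -> -6.439 ng/dL
        p = ref_params
        L1 = (p.t_min - p.t_max) % 24
        tau = 12.0 / L1 * (12.0 - p.t_max)
        expected = p.amplitude * np.cos(2 * np.pi * tau / 24)
        assert expected == pytest.approx(-6.439, abs=5e-3)
        got = cm.circadian_value(12.0, p.amplitude, p.t_max, p.t_min)
        assert got == pytest.approx(expected, abs=1e-12)

    @given(
        t_max=st.floats(0.0, 23.9),
        L1=st.floats(1.0, 23.0),
        amp=st.floats(1.0, 100.0),
        t=st.floats(-48.0, 48.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_periodicity(self, t_max, L1, amp, t):
        t_min = (t_max + L1) % 24.0
        a = cm.circadian_value(t, amp, t_max, t_min)
        b = cm.circadian_value(t + 24.0, amp, t_max, t_min)
        assert a == pytest.approx(b, abs=1e-9)

    def test_grid_extremum_oracle(self, ref_params):
        """Dense grid search: global max/min sit at t_max/t_min at ±amplitude."""
        p = ref_params
        grid = np.arange(0.0, 24.0, 0.001)
        vals = cm.circadian_value(grid, p.amplitude, p.t_max, p.t_min)
        assert grid[np.argmax(vals)] == pytest.approx(p.t_max, abs=0.002)
        assert grid[np.argmin(vals)] == pytest.approx(p.t_min, abs=0.002)
        assert vals.max() == pytest.approx(p.amplitude, abs=1e-4)
        assert vals.min() == pytest.approx(-p.amplitude, abs=1e-4)

    def test_collapses_to_standard_when_symmetric(self):
        t = np.arange(0.0, 24.0, 0.01)
        stretched = cm.circadian_value(t, 30.0, 9.0, 21.0)
        standard = cm.standard_circadian(t, 30.0, 9.0)
        assert np.max(np.abs(stretched - standard)) < 1e-12


class TestComparators:
    def test_standard_examples(self):
        assert cm.standard_circadian(9.0, 32.1, 9.0) == pytest.approx(32.1)
        assert cm.standard_circadian(15.0, 32.1, 9.0) == pytest.approx(0.0, abs=1e-12)
        # scalar oracle: 32.1*cos(2*pi*2.6333/24) = 24.769
        assert cm.standard_circadian(12.0, 32.1, 9.3667) == pytest.approx(24.769, abs=1e-3)

    def test_double_cosine_examples(self):
        t = np.linspace(0, 24, 97)
        assert np.allclose(cm.double_cosine(t, 30.0, 9.0, 0.0, 3.0),
                           cm.standard_circadian(t, 30.0, 9.0))
        assert cm.double_cosine(9.0, 30.0, 9.0, 10.0, 9.0) == pytest.approx(40.0)
        # 30*cos(pi/2) + 10*cos(2*pi) = 10
        assert cm.double_cosine(15.0, 30.0, 9.0, 10.0, 3.0) == pytest.approx(10.0, abs=1e-12)


class TestTypicalBase:
    def test_centering_identity(self, ref_params):
        cov = cm.SubjectCovariates(age=ref_params.age_ref, season="summer")
        assert cm.typical_base(ref_params, cov) == pytest.approx(ref_params.base)

    def test_age_decrement_per_decade(self, ref_params):
        cov = cm.SubjectCovariates(age=ref_params.age_ref + 10, season="summer")
        decrement = ref_params.base - cm.typical_base(ref_params, cov)
        assert decrement == pytest.approx(5.74, abs=5e-3)

    def test_winter_spring_increment(self, ref_params):
        cov = cm.SubjectCovariates(age=ref_params.age_ref, season="winter")
        increment = cm.typical_base(ref_params, cov) - ref_params.base
        assert increment == pytest.approx(19.3, abs=0.05)

    def test_additive_form_differs_only_second_order(self, ref_params):
        cov = cm.SubjectCovariates(age=60.0, season="winter")
        mult = cm.typical_base(ref_params, cov, form="multiplicative")
        add = cm.typical_base(ref_params, cov, form="additive")
        assert mult != add
        assert mult == pytest.approx(add, rel=0.01)

    def test_nonpositive_result_raises(self):
        p = cm.CircadianParams(base=100.0, amplitude=10.0, t_max=9.0, t_min=14.0,
                               theta_age=-0.5)
        cov = cm.SubjectCovariates(age=95.0, season="summer")
        with pytest.raises(ValueError):
            cm.typical_base(p, cov)


class TestBoxCox:
    def test_fixes_zero(self):
        for theta in (-2.0, -0.5, 0.0, 1.3):
            assert cm.boxcox_eta(0.0, theta) == pytest.approx(0.0)

    def test_theta_to_zero_limit(self):
        eta = np.linspace(-3, 3, 601)
        assert np.max(np.abs(cm.boxcox_eta(eta, 1e-8) - eta)) < 1e-6
        assert cm.boxcox_eta(0.7, 1e-10) == pytest.approx(0.7, abs=1e-6)

    def test_reference_value_scalar_oracle(self):
        # (exp(-1.93*0.5) - 1)/(-1.93) evaluated independently
        expected = (np.expm1(-1.93 * 0.5)) / (-1.93)
        assert expected == pytest.approx(0.3207, abs=5e-5)
        assert cm.boxcox_eta(0.5, -1.93) == pytest.approx(expected, rel=1e-12)

    @given(theta=st.floats(-3.0, 3.0), a=st.floats(-2.0, 2.0), b=st.floats(-2.0, 2.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone(self, theta, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert cm.boxcox_eta(lo, theta) < cm.boxcox_eta(hi, theta)

    @given(theta=st.floats(-2.5, 2.5), eta=st.floats(-1.5, 1.5))
    @settings(max_examples=100, deadline=None)
    def test_inverse_roundtrip(self, theta, eta):
        star = cm.boxcox_eta(eta, theta)
        back = boxcox_eta_inv(star, theta)
        assert back == pytest.approx(eta, abs=1e-9)


class TestIndividualParams:
    def test_zero_eta_gives_typicals(self, ref_params):
        cov = cm.SubjectCovariates(age=ref_params.age_ref, season="summer")
        ind = cm.individual_params(ref_params, np.zeros(4), cov)
        assert ind["base"] == pytest.approx(ref_params.base)
        assert ind["amplitude"] == pytest.approx(ref_params.amplitude)
        assert ind["t_max"] == pytest.approx(ref_params.t_max)
        assert ind["t_min"] == pytest.approx(ref_params.t_min)

    def test_lognormal_scaling_of_amplitude(self, ref_params):
        ind = cm.individual_params(ref_params, [0, 0, np.log(2), 0])
        assert ind["amplitude"] == pytest.approx(2 * ref_params.amplitude)

    def test_boxcox_composition_on_base(self, ref_params):
        ind = cm.individual_params(ref_params, [0, 0, 0, 0.5])
        assert ind["base"] == pytest.approx(239.0 * np.exp(0.32073), abs=0.05)
        assert ind["base"] == pytest.approx(329.4, abs=0.2)

    def test_times_wrap(self, ref_params):
        ind = cm.individual_params(ref_params, [1.2, 1.0, 0, 0])
        assert 0 <= ind["t_max"] < 24 and 0 <= ind["t_min"] < 24

    def test_predicted_curve_peak_below_threshold(self, ref_params):
        # typical hypogonadal patient stays below 300 ng/dL even at peak
        peak = ref_params.base + ref_params.amplitude
        assert peak == pytest.approx(271.1, abs=1e-9)
        assert peak < 300.0
        grid = np.arange(0, 24, 0.01)
        curve = cm.predict_concentration(grid, ref_params)
        assert curve.max() <= peak + 1e-9


class TestParamInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(base=-1.0, amplitude=5.0, t_max=9.0, t_min=14.0),
            dict(base=100.0, amplitude=-1.0, t_max=9.0, t_min=14.0),
            dict(base=100.0, amplitude=150.0, t_max=9.0, t_min=14.0),
            dict(base=100.0, amplitude=10.0, t_max=9.0, t_min=9.0),
            dict(base=100.0, amplitude=10.0, t_max=9.0, t_min=33.0),
        ],
    )
    def test_invalid_params_raise(self, kwargs):
        with pytest.raises(ValueError):
            cm.CircadianParams(**kwargs)

    def test_subject_covariates_validation(self):
        with pytest.raises(ValueError):
            cm.SubjectCovariates(age=150.0, season="summer")
        with pytest.raises(ValueError):
            cm.SubjectCovariates(age=50.0, season="summer", semester1=1)
        c = cm.SubjectCovariates(age=50.0, season="fall")
        assert (c.semester1, c.semester2) == (0, 1)
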