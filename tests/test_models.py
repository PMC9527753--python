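"""Closed-form 1:1 model functions and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinsense as ks
from kinsense.errors import InvalidParameterError, OutOfWindowError
from kinsense.models import evaluate_piecewise

PH = ks.PhaseMarkers(t_a=10.0, t_d=40.0, t_end=100.0)


class TestObservedRate:
    def test_zero_concentration_limit_is_kd(self):
        assert ks.observed_rate(6.98e5, 0.0, 0.358).k_obs == 0.358

    def test_hand_arithmetic(self):
        assert ks.observed_rate(6.98e5, 1e-6, 0.358).k_obs == pytest.approx(1.056)

    def test_linearity_in_concentration(self):
        k_d = 0.2
        d1 = ks.observed_rate(1e5, 1e-6, k_d).k_obs - k_d
        d2 = ks.observed_rate(1e5, 2e-6, k_d).k_obs - k_d
        assert d2 == pytest.approx(2 * d1)

    @pytest.mark.parametrize(
        "k_a,c,k_d",
        [(-1.0, 1e-6, 0.1), (1e5, -1e-6, 0.1), (1e5, 1e-6, 0.0),
         (float("nan"), 1e-6, 0.1), (1e5, float("inf"), 0.1)],
    )
    def test_invalid_inputs_rejected(self, k_a, c, k_d):
        with pytest.raises(InvalidParameterError):
            ks.observed_rate(k_a, c, k_d)


class TestAssociationSignal:
    def test_rise_starts_at_baseline(self):
        p = ks.RateParameters(k_a=1e5, k_d=0.3, A=10.0, y0=2.0)
        assert ks.association_signal(PH.t_a, p, 1e-6, PH) == pytest.approx(2.0)

    def test_plateau_identity(self):
        # k_obs*(t - t_a) >> 1 on the association window
        p = ks.RateParameters(k_a=1e7, k_d=5.0, A=10.0, y0=2.0)
        assert ks.association_signal(PH.t_d, p, 1e-5, PH) == pytest.approx(12.0)

    def test_closed_form_value(self):
        # k_obs = 1.5e6*1e-6 + 0.359 = 1.859 s^-1, one second into the rise
        ph = ks.PhaseMarkers(t_a=0.0, t_d=40.0, t_end=100.0)
        p = ks.RateParameters(k_a=1.5e6, k_d=0.359, A=10.0, y0=0.0)
        assert ks.association_signal(1.0, p, 1e-6, ph) == pytest.approx(
            8.4417, abs=1e-3
        )

    def test_outside_window_rejected(self):
        p = ks.RateParameters(k_a=1e5, k_d=0.3, A=10.0, y0=0.0)
        for t in (PH.t_a - 1.0, PH.t_d + 1.0):
            with pytest.raises(OutOfWindowError):
                ks.association_signal(t, p, 1e-6, PH)

    @given(scale=st.floats(0.1, 10.0))
    @settings(deadline=None, derandomize=True)
    def test_depends_only_on_kobs_times_elapsed(self, scale):
        """Dimensional consistency: F is a function of k_obs*(t - t_a) only,
        so scaling k_obs up and elapsed time down leaves it unchanged."""
        ph = ks.PhaseMarkers(t_a=0.0, t_d=1e6, t_end=2e6)
        k_d, c, t = 0.01, 2e-6, 3.0
        p1 = ks.RateParameters(k_a=1e5, k_d=k_d, A=7.0, y0=1.0)
        k_obs = ks.observed_rate(p1.k_a, c, p1.k_d).k_obs
        # second parameter set with k_obs' = scale*k_obs, evaluated at t/scale
        p2 = ks.RateParameters(
            k_a=(scale * k_obs - k_d) / c if scale * k_obs > k_d else p1.k_a,
            k_d=k_d, A=7.0, y0=1.0,
        )
        k_obs2 = ks.observed_rate(p2.k_a, c, p2.k_d).k_obs
        v1 = ks.association_signal(t, p1, c, ph)
        v2 = ks.association_signal(t * k_obs / k_obs2, p2, c, ph)
        assert v1 == pytest.approx(v2, rel=1e-9)


class TestDissociationSignal:
    P = ks.RateParameters(k_a=1e5, k_d=0.359, A=10.0, y0=0.0, f_res=0.0)

    def test_decay_starts_at_full_amplitude(self):
        p = ks.RateParameters(k_a=1e5, k_d=0.359, A=10.0, y0=1.5)
        assert ks.dissociation_signal(PH.t_d, p, PH, A_d=10.0) == pytest.approx(11.5)

    def test_fully_nondissociating_limit_is_constant(self):
        p = ks.RateParameters(k_a=1e5, k_d=0.359, A=10.0, y0=1.0, f_res=1.0)
        t = np.linspace(PH.t_d, PH.t_end, 20)
        np.testing.assert_allclose(
            ks.dissociation_signal(t, p, PH, A_d=10.0), 11.0
        )

    def test_half_life_identity(self):
        t = PH.t_d + math.log(2) / 0.359
        assert ks.dissociation_signal(t, self.P, PH, A_d=10.0) == pytest.approx(5.0)

    def test_residual_plateau(self):
        p = ks.RateParameters(k_a=1e5, k_d=0.359, A=10.0, y0=0.0, f_res=0.2)
        far = PH.t_d + 1000.0
        ph = ks.PhaseMarkers(PH.t_a, PH.t_d, far + 1)
        assert ks.dissociation_signal(far, p, ph, A_d=10.0) == pytest.approx(2.0)

    def test_before_window_rejected(self):
        with pytest.raises(OutOfWindowError):
            ks.dissociation_signal(PH.t_d - 0.1, self.P, PH, A_d=10.0)

    def test_invalid_f_res_rejected(self):
        with pytest.raises(InvalidParameterError):
            ks.RateParameters(k_a=1e5, k_d=0.359, f_res=1.2)


class TestEquilibriumConstants:
    @pytest.mark.parametrize(
        "k_a,k_d,K_A,K_D",
        [
            (6.98e5, 0.358, 1.95e6, 5.13e-7),   # fast intercalator, 25 C
            (15.4, 1.19e-2, 1.29e3, 7.73e-4),   # slow sulfonamide, 37 C
        ],
    )
    def test_reference_values_at_three_sig_figs(self, k_a, k_d, K_A, K_D):
        c = ks.equilibrium_constants(k_a, k_d)
        assert float(f"{c.K_A:.3g}") == pytest.approx(K_A)
        assert float(f"{c.K_D:.3g}") == pytest.approx(K_D)

    def test_unit_ratio(self):
        assert ks.equilibrium_constants(0.42, 0.42).K_A == 1.0

    def test_zero_or_negative_rates_rejected(self):
        for k_a, k_d in ((0.0, 1.0), (1.0, -2.0)):
            with pytest.raises(InvalidParameterError):
                ks.equilibrium_constants(k_a, k_d)

    @given(
        k_a=st.floats(1e-3, 1e9), k_d=st.floats(1e-6, 1e3)
    )
    @settings(deadline=None, derandomize=True)
    def test_product_is_one_to_machine_precision(self, k_a, k_d):
        c = ks.equilibrium_constants(k_a, k_d)
        assert c.K_A * c.K_D == pytest.approx(1.0, rel=1e-14)


class TestModelTrace:
    P = ks.RateParameters(k_a=6.98e5, k_d=0.358, A=10.0, y0=2.0)

    def test_blank_is_flat_at_baseline(self):
        tr = ks.model_trace(self.P, 0.0, PH, sampling_rate=5.0)
        np.testing.assert_allclose(tr.signal, 2.0)

    def test_continuity_at_dissociation_start(self):
        tr = ks.model_trace(self.P, 1e-6, PH, sampling_rate=50.0)
        i = np.searchsorted(tr.time, PH.t_d)
        assert abs(tr.signal[i] - tr.signal[i - 1]) < 0.02 * self.P.A

    def test_long_association_dissociation_amplitude_reaches_A(self):
        ph = ks.PhaseMarkers(t_a=0.0, t_d=500.0, t_end=501.0)
        tr = ks.model_trace(self.P, 1e-6, ph, sampling_rate=1.0)
        i = np.searchsorted(tr.time, ph.t_d)
        assert tr.signal[i] == pytest.approx(self.P.y0 + self.P.A, rel=1e-12)

    def test_phase_monotonicity(self):
        tr = ks.model_trace(self.P, 1e-6, PH, sampling_rate=10.0)
        assoc = (tr.time >= PH.t_a) & (tr.time < PH.t_d)
        dissoc = tr.time >= PH.t_d
        assert np.all(np.diff(tr.signal[assoc]) > 0)
        assert np.all(np.diff(tr.signal[dissoc]) < 0)

    def test_zero_residual_fraction_matches_complete_model(self):
        t = np.linspace(0, PH.t_end, 300)
        v0 = evaluate_piecewise(t, self.P, 1e-6, PH)
        p_inc = ks.RateParameters(
            k_a=self.P.k_a, k_d=self.P.k_d, A=self.P.A, y0=self.P.y0, f_res=0.0
        )
        np.testing.assert_array_equal(v0, evaluate_piecewise(t, p_inc, 1e-6, PH))

    def test_invalid_sampling_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            ks.model_trace(self.P, 1e-6, PH, sampling_rate=0.0)
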