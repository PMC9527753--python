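"""Global fitting: guesses, recovery, model selection, uncertainty,
replicate aggregation."""

import numpy as np
import pytest

import kinsense as ks
from kinsense.errors import (
    AggregationMismatchError,
    ConvergenceError,
    GuessFailureError,
    IdentifiabilityError,
)
from kinsense.fitting import ModelSpec, TraceSignal


def _make_fit_result(k_a, k_d, f_res=0.0, meta=None, converged=True):
    """Hand-assembled FitResult for aggregation tests."""
    params = ks.RateParameters(k_a=k_a, k_d=k_d, A=10.0, y0=0.0, f_res=f_res)
    return ks.FitResult(
        params=params,
        per_trace=[TraceSignal("t0", 1e-6, 10.0, 0.0)],
        constants=ks.equilibrium_constants(k_a, k_d),
        standard_errors=None,
        covariance=None,
        shared_names=("k_a", "k_d"),
        residual_sum_squares=0.0,
        n_points=100,
        information_criterion=0.0,
        model=ModelSpec(),
        converged=converged,
        meta=meta or {"system": "X", "temperature": 25.0, "mode": "static_standard"},
    )


class TestInitialGuess:
    def test_noisefree_dissociation_rate_exact(self):
        # fully decayed single-exponential tail -> log-linear regression exact
        truth = ks.RateParameters(k_a=1e5, k_d=0.5, A=20.0, y0=1.0)
        ph = ks.PhaseMarkers(t_a=5.0, t_d=45.0, t_end=145.0)
        design = ks.SeriesDesign(
            concentrations=(2e-5, 1e-5), association_duration=40.0,
            dissociation_duration=100.0, sampling_rate=10.0, baseline_duration=5.0,
        )
        series = ks.simulate_series(truth, design, ks.NoiseSpec(0.0, seed=0))
        guess = ks.initial_guess(series)
        assert guess.k_d == pytest.approx(0.5, rel=1e-9)

    def test_noisefree_two_point_ka_exact(self):
        truth = ks.RateParameters(k_a=1e5, k_d=0.5, A=20.0, y0=1.0)
        design = ks.SeriesDesign(
            concentrations=(2e-5, 1e-5), association_duration=40.0,
            dissociation_duration=100.0, sampling_rate=10.0, baseline_duration=5.0,
        )
        series = ks.simulate_series(truth, design, ks.NoiseSpec(0.0, seed=0))
        guess = ks.initial_guess(series)
        assert guess.k_a == pytest.approx(1e5, rel=1e-6)

    def test_blanks_do_not_affect_guess(self, eb_series_noisefree):
        with_blanks = ks.initial_guess(eb_series_noisefree)
        without = ks.initial_guess(
            [tr for tr in eb_series_noisefree if not tr.is_blank]
        )
        assert with_blanks == without

    def test_flat_series_fails_with_diagnostics(self):
        ph = ks.PhaseMarkers(t_a=5.0, t_d=35.0, t_end=95.0)
        t = np.arange(0.0, 95.0, 0.5)
        flat = ks.SensorgramTrace(
            time=t, signal=np.full(t.size, 2.0), concentration=1e-6, phases=ph
        )
        with pytest.raises(GuessFailureError) as err:
            ks.initial_guess([flat])
        assert err.value.diagnostics  # carries what failed


class TestFitGlobal:
    def test_noisefree_recovery(self, eb_truth, eb_series_noisefree):
        fit = ks.fit_global(eb_series_noisefree, ModelSpec(), seed=0)
        assert fit.converged
        assert fit.k_a == pytest.approx(eb_truth.k_a, rel=1e-6)
        assert fit.k_d == pytest.approx(eb_truth.k_d, rel=1e-6)

    def test_constants_consistent_with_rates(self, eb_series_noisy):
        fit = ks.fit_global(eb_series_noisy, ModelSpec(), seed=0)
        assert fit.constants.K_A == fit.k_a / fit.k_d
        assert fit.constants.K_A * fit.constants.K_D == pytest.approx(1.0, rel=1e-14)

    def test_single_concentration_not_identifiable(self, eb_series_noisefree):
        one = [tr for tr in eb_series_noisefree if tr.concentration == 1e-6]
        with pytest.raises(IdentifiabilityError):
            ks.fit_global(one, ModelSpec(), seed=0)

    def test_incomplete_model_on_complete_data(self, eb_series_noisefree):
        fit = ks.fit_global(
            eb_series_noisefree,
            ModelSpec(dissociation_model="incomplete"),
            seed=0,
        )
        assert fit.f_res <= 1e-3

    def test_trace_order_permutation_invariance(self, eb_series_noisy):
        fit1 = ks.fit_global(eb_series_noisy, ModelSpec(), seed=0)
        fit2 = ks.fit_global(list(reversed(eb_series_noisy)), ModelSpec(), seed=0)
        assert fit2.k_a == pytest.approx(fit1.k_a, rel=1e-7)
        assert fit2.k_d == pytest.approx(fit1.k_d, rel=1e-7)

    def test_duplicated_trace_uniform_weighting_invariance(
        self, eb_series_noisefree
    ):
        # at the zero-residual optimum a duplicated trace adds no pull on
        # the shared parameters (the duplicate gets its own A and y0)
        fit1 = ks.fit_global(eb_series_noisefree, ModelSpec(), seed=0)
        dup = list(eb_series_noisefree) + [eb_series_noisefree[2]]
        fit2 = ks.fit_global(dup, ModelSpec(), seed=0)
        assert fit2.k_a == pytest.approx(fit1.k_a, rel=1e-8)
        assert fit2.k_d == pytest.approx(fit1.k_d, rel=1e-8)

    def test_short_association_window_warns(self):
        truth = ks.RateParameters(k_a=10.0, k_d=1e-3, A=20.0, y0=0.0)
        design = ks.SeriesDesign(
            concentrations=(2e-4, 1e-4), association_duration=30.0,
            dissociation_duration=60.0, sampling_rate=2.0,
        )
        series = ks.simulate_series(truth, design, ks.NoiseSpec(0.0, seed=0))
        with pytest.warns(UserWarning, match="plateau"):
            ks.fit_global(series, ModelSpec(), seed=0)


class TestModelSelection:
    def test_complete_data_selects_complete(self, eb_series_noisy):
        spec, _ = ks.select_dissociation_model(eb_series_noisy, seed=0)
        assert spec.dissociation_model == ks.DissociationModel.COMPLETE

    def test_incomplete_data_selects_incomplete(self, slow_truth, slow_series_noisy):
        spec, fit = ks.select_dissociation_model(slow_series_noisy, seed=0)
        assert spec.dissociation_model == ks.DissociationModel.INCOMPLETE
        assert fit.f_res == pytest.approx(slow_truth.f_res, abs=0.05)


class TestUncertainty:
    def test_noisefree_curvature_errors_vanish(self, eb_truth, eb_series_noisefree):
        fit = ks.fit_global(eb_series_noisefree, ModelSpec(), seed=0)
        fit = ks.estimate_uncertainty(fit, eb_series_noisefree, method="curvature")
        assert fit.standard_errors["k_a"] <= 1e-6 * eb_truth.k_a
        assert fit.standard_errors["k_d"] <= 1e-6 * eb_truth.k_d

    def test_bootstrap_deterministic_given_seed(self, small_design, eb_truth):
        series = ks.simulate_series(eb_truth, small_design, ks.NoiseSpec(1.0, seed=2))
        fit = ks.fit_global(series, ModelSpec(), seed=0)
        se1 = ks.estimate_uncertainty(
            fit, series, method="bootstrap", n_boot=10, seed=5
        ).standard_errors
        se2 = ks.estimate_uncertainty(
            fit, series, method="bootstrap", n_boot=10, seed=5
        ).standard_errors
        assert se1 == se2
        assert all(v > 0 for v in se1.values())

    def test_more_noise_never_shrinks_errors(self, small_design, eb_truth):
        """Curvature SEs averaged over seeds grow with the noise level."""

        def mean_se(sigma):
            ses = []
            for seed in (0, 1, 2):
                series = ks.simulate_series(
                    eb_truth, small_design, ks.NoiseSpec(sigma, seed=seed)
                )
                fit = ks.fit_global(series, ModelSpec(), seed=0)
                ses.append(fit.standard_errors["k_a"])
            return np.mean(ses)

        assert mean_se(2.0) > mean_se(0.2)

    def test_requires_convergence(self, eb_series_noisy):
        bad = _make_fit_result(1e5, 0.3, converged=False)
        with pytest.raises(ConvergenceError):
            ks.estimate_uncertainty(bad, eb_series_noisy)


class TestAggregateReplicates:
    def test_identical_replicates_zero_sd(self):
        results = [_make_fit_result(2e6, 0.4) for _ in range(3)]
        summary = ks.aggregate_replicates(results)
        assert summary.stats["k_a"] == (2e6, 0.0)
        assert summary.n_replicates == 3

    def test_hand_arithmetic(self):
        results = [_make_fit_result(k, 0.4) for k in (1e6, 2e6, 3e6)]
        summary = ks.aggregate_replicates(results)
        mean, sd = summary.stats["k_a"]
        assert mean == pytest.approx(2e6)
        assert sd == pytest.approx(1e6)

    def test_constants_summarized_per_replicate_not_ratio_of_means(self):
        # Jensen gap: mean of ratios differs from ratio of means
        results = [_make_fit_result(1e6, 0.2), _make_fit_result(1e6, 0.8)]
        summary = ks.aggregate_replicates(results)
        mean_KA = summary.stats["K_A"][0]
        per_replicate = np.mean([1e6 / 0.2, 1e6 / 0.8])
        ratio_of_means = 1e6 / np.mean([0.2, 0.8])
        assert mean_KA == pytest.approx(per_replicate)
        assert mean_KA != pytest.approx(ratio_of_means, rel=1e-3)

    def test_mixed_systems_rejected(self):
        a = _make_fit_result(1e6, 0.4, meta={"system": "A", "temperature": 25.0,
                                             "mode": "static_standard"})
        b = _make_fit_result(1e6, 0.4, meta={"system": "B", "temperature": 25.0,
                                             "mode": "static_standard"})
        with pytest.raises(AggregationMismatchError):
            ks.aggregate_replicates([a, b])

    def test_single_result_rejected(self):
        with pytest.raises(AggregationMismatchError):
            ks.aggregate_replicates([_make_fit_result(1e6, 0.4)])
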