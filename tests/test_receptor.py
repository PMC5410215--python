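import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from tnbc_subtyper import (
    ExpressionMatrix,
    MixtureFit,
    ProbeMarkerMap,
    ReceptorCalls,
    ReceptorMixture,
    SimConfig,
    call_receptor_status,
    confirm_against_positive_controls,
    fit_two_component_gmm,
    generate_cohort,
    posterior_high,
)
from _oracles import gmm_grid_search_mle


def _symmetric_fit(mu_low=5.0, mu_high=10.0, sd=1.0):
    return MixtureFit(
        mu_low=mu_low, sd_low=sd, weight_low=0.5,
        mu_high=mu_high, sd_high=sd, weight_high=0.5,
        log_likelihood=0.0, converged=True, n_iter=1,
    )


class TestFitTwoComponentGmm:
    def test_separated_point_masses(self):
        x = np.concatenate([np.full(100, 2.0), np.full(100, 8.0)])
        fit = fit_two_component_gmm(x, seed=0)
        assert abs(fit.mu_low - 2.0) < 0.01
        assert abs(fit.mu_high - 8.0) < 0.01
        assert abs(fit.weight_low - 0.5) < 0.01
        assert abs(fit.weight_high - 0.5) < 0.01

    def test_matches_grid_search_mle_oracle(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(6, 1, 1000), rng.normal(11, 1, 1000)])
        fit = fit_two_component_gmm(x, seed=0)
        oracle_low, oracle_high = gmm_grid_search_mle(x)
        assert abs(fit.mu_low - oracle_low) < 0.2
        assert abs(fit.mu_high - oracle_high) < 0.2

    def test_parameter_recovery_over_seeds(self):
        """Mean absolute error of recovered means < 0.1 at separation 5."""
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.concatenate([rng.normal(6, 1, 500), rng.normal(11, 1, 500)])
            fit = fit_two_component_gmm(x, seed=seed)
            errors += [abs(fit.mu_low - 6.0), abs(fit.mu_high - 11.0)]
        assert np.mean(errors) < 0.1

    def test_label_swap_invariance(self):
        """Canonical mean-sorting makes restarts/initialization irrelevant."""
        rng = np.random.default_rng(3)
        x = np.concatenate([rng.normal(6, 1, 400), rng.normal(11, 1, 400)])
        fits = [fit_two_component_gmm(x, seed=s, n_starts=7) for s in (1, 99)]
        assert fits[0].mu_low < fits[0].mu_high
        assert abs(fits[0].mu_low - fits[1].mu_low) < 1e-3
        assert abs(fits[0].mu_high - fits[1].mu_high) < 1e-3

    def test_too_few_values_is_an_error(self):
        with pytest.raises(ValueError, match="10"):
            fit_two_component_gmm(np.arange(9.0))

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            fit_two_component_gmm(np.full(50, 4.0))


class TestPosteriorHigh:
    def test_midpoint_of_symmetric_fit_is_exactly_half(self):
        fit = _symmetric_fit()
        assert posterior_high(7.5, fit) == pytest.approx(0.5, abs=1e-12)

    def test_closed_form_at_high_mean(self):
        fit = _symmetric_fit(5.0, 10.0, 1.0)
        expected = (0.5 * norm.pdf(10, 10, 1)) / (
            0.5 * norm.pdf(10, 5, 1) + 0.5 * norm.pdf(10, 10, 1)
        )
        assert posterior_high(10.0, fit) == pytest.approx(expected, rel=1e-12)

    def test_lower_tail_limit_is_zero(self):
        fit = _symmetric_fit()
        assert posterior_high(-1e3, fit) == pytest.approx(0.0, abs=1e-12)
        assert posterior_high(1e3, fit) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_when_sds_equal(self):
        fit = _symmetric_fit()
        grid = posterior_high(np.linspace(-5, 20, 200), fit)
        assert (np.diff(grid) >= 0).all()

    def test_posterior_calibration_under_the_fitted_model(self):
        """P(posterior_high > 0.5) approaches weight_high on model draws."""
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(6, 1, 1200), rng.normal(11, 1, 800)])
        fit = fit_two_component_gmm(x, seed=0)
        n = 2000
        comp = rng.random(n) < fit.weight_high
        draws = np.where(
            comp,
            rng.normal(fit.mu_high, fit.sd_high, n),
            rng.normal(fit.mu_low, fit.sd_low, n),
        )
        frac = (posterior_high(draws, fit) > 0.5).mean()
        three_sd = 3 * np.sqrt(fit.weight_high * (1 - fit.weight_high) / n)
        assert abs(frac - fit.weight_high) < three_sd


class TestCallReceptorStatus:
    def test_agrees_with_truth_at_separation_four_sd(self):
        mix = {m: ReceptorMixture(mu_neg=6, sd_neg=1, mu_pos=10, sd_pos=1,
                                  positive_fraction=0.35)
               for m in ("ER", "PR", "HER2")}
        config = SimConfig(n_datasets=1, samples_per_dataset=600, n_probes=60,
                           receptor_mixture=mix, batch_shift_sd=0.0, seed=4)
        matrix, truth = generate_cohort(config)
        calls = call_receptor_status(matrix, seed=0)
        agreement = (calls.tnbc == truth.tnbc).mean()
        assert agreement >= 0.97
        # TNBC flag is exactly the conjunction of the three negative calls
        assert (calls.tnbc == calls.negative.all(axis=1)).all()

    def test_clear_positives_and_negatives_get_the_right_call(self, mixed_cohort):
        matrix, truth = mixed_cohort
        calls = call_receptor_status(matrix, seed=0)
        post = calls.posterior_high
        # posterior-rule semantics: negative iff posterior of the high mode < cutoff
        assert (calls.negative == (post < 0.5)).all().all()

    def test_missing_probe_names_the_marker(self, small_matrix):
        with pytest.raises(Exception, match="ER"):
            call_receptor_status(small_matrix, ProbeMarkerMap(er="nope_at"))


def _handmade_calls_and_matrix():
    """3 receptor probes x 8 samples: c0..c4 positive controls, t0..t2 TNBC."""
    samples = [f"c{i}" for i in range(5)] + ["t0", "t1", "t2"]
    probes = ProbeMarkerMap()
    control_values = np.array([10.0, 10.5, 11.0, 11.5, 12.0])
    rows = {}
    for probe in probes.as_dict().values():
        # t0 far below all controls, t1 at the control median, t2 below q10
        rows[probe] = np.concatenate([control_values, [2.0, 11.0, 9.0]])
    values = pd.DataFrame(rows, index=samples).T
    matrix = ExpressionMatrix(values)
    negative = pd.DataFrame(False, index=samples, columns=["ER", "PR", "HER2"])
    negative.loc[["t0", "t1", "t2"]] = True
    calls = ReceptorCalls(
        posterior_high=pd.DataFrame(0.0, index=samples, columns=["ER", "PR", "HER2"]),
        negative=negative,
        tnbc=negative.all(axis=1),
        fits={},
        demoted=pd.Series(False, index=samples),
    )
    return matrix, calls


class TestPositiveControlConfirmation:
    def test_quantile_rule_matches_bruteforce(self):
        matrix, calls = _handmade_calls_and_matrix()
        controls = [f"c{i}" for i in range(5)]
        out = confirm_against_positive_controls(matrix, calls, controls, quantile=0.10)
        threshold = np.quantile([10.0, 10.5, 11.0, 11.5, 12.0], 0.10)
        for sample in ("t0", "t1", "t2"):
            expected_demoted = any(
                matrix.values.loc[probe, sample] >= threshold
                for probe in ProbeMarkerMap().as_dict().values()
            )
            assert out.demoted[sample] == expected_demoted
        # candidate below all control minima is retained
        assert not out.demoted["t0"] and out.tnbc_final["t0"]
        # candidate at the control median is demoted but not deleted
        assert out.demoted["t1"] and out.tnbc["t1"] and not out.tnbc_final["t1"]

    def test_empty_control_set_is_an_error(self):
        matrix, calls = _handmade_calls_and_matrix()
        with pytest.raises(ValueError, match="empty"):
            confirm_against_positive_controls(matrix, calls, [])

    def test_tnbc_called_control_is_rejected(self):
        matrix, calls = _handmade_calls_and_matrix()
        with pytest.raises(ValueError, match="t0"):
            confirm_against_positive_controls(matrix, calls, ["t0"])
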