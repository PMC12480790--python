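"""Synthetic vignette data, choice simulation, and parameter recovery."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from biowean import (
    CRITERIA,
    CoefficientSet,
    EstimationError,
    SeparationError,
    ValidationError,
    VignetteDesign,
    fit_choice_model,
    fit_time_baseline,
    generate_profiles,
    simulate_choices,
)


def _oracle_logit_mle(x, y):
    """Independent logit MLE: direct minimization of the hand-written
    negative log-likelihood (no statsmodels)."""
    exog = np.column_stack([np.ones(len(y)), x])

    def nll(theta):
        eta = exog @ theta
        # log(1+e^eta) via logaddexp for stability
        return float(np.sum(np.logaddexp(0.0, eta)) - y @ eta)

    result = minimize(nll, np.zeros(exog.shape[1]), method="BFGS")
    assert result.success or np.linalg.norm(result.jac) < 1e-3
    return result.x


class TestGenerateProfiles:
    def test_zero_prevalence_gives_all_zero_flags(self):
        profiles = generate_profiles(100, prevalence={}, seed=7)
        assert len(profiles) == 100
        assert all(sum(p.flags.values()) == 0 for p in profiles)

    def test_empirical_prevalence_matches_target(self):
        n, rate = 10_000, 0.3
        profiles = generate_profiles(
            n, prevalence={"flare_history": rate}, seed=11
        )
        observed = sum(p.flare_history for p in profiles) / n
        se = math.sqrt(rate * (1 - rate) / n)
        assert abs(observed - rate) < 3 * se

    def test_same_seed_is_deterministic(self):
        a = generate_profiles(50, prevalence={"rf_positive": 0.5}, seed=3)
        b = generate_profiles(50, prevalence={"rf_positive": 0.5}, seed=3)
        assert a == b

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValidationError):
            generate_profiles(10, prevalence={"rf_positive": 1.5}, seed=0)
        with pytest.raises(ValidationError):
            generate_profiles(10, prevalence={"elbow": 0.2}, seed=0)

    def test_cid_range_must_stay_in_domain(self):
        with pytest.raises(ValidationError):
            generate_profiles(10, prevalence={}, cid_range=(2, 12), seed=0)


class TestSimulateChoices:
    def test_saturated_utility_forces_continue(self, coeffs):
        forced = CoefficientSet(
            intercept=50.0,
            betas=coeffs.betas,
            baseline_intercept=coeffs.baseline_intercept,
            baseline_slope=coeffs.baseline_slope,
        )
        design = VignetteDesign.full_factorial(replicates=3, seed=0)
        data = simulate_choices(design, forced)
        assert data.table["chose_continue"].eq(1).all()

    def test_choice_frequency_matches_logistic(self, coeffs):
        # all-zero vignette: P(continue) = logistic(-1.61)
        design = VignetteDesign(
            profiles=generate_profiles(1, prevalence={}, seed=0),
            replicates=10_000,
            seed=5,
        )
        data = simulate_choices(design, coeffs)
        p = 1.0 / (1.0 + math.exp(1.61))
        observed = data.table["chose_continue"].mean()
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(observed - p) < 3 * se

    def test_same_seed_gives_identical_datasets(self, coeffs):
        design = VignetteDesign.full_factorial(replicates=2, seed=9)
        a = simulate_choices(design, coeffs)
        b = simulate_choices(design, coeffs)
        assert a.table.equals(b.table)

    def test_frequency_error_shrinks_with_sample_size(self, coeffs):
        # Kolmogorov-style max deviation between empirical continue rates
        # and logistic(U) across vignettes shrinks as raters grow
        deviations = {}
        for replicates in (20, 2000):
            design = VignetteDesign.random_subset(
                32, replicates=replicates, seed=13
            )
            data = simulate_choices(design, coeffs)
            x = design.design_matrix()
            beta = np.array([coeffs.betas[c] for c in CRITERIA])
            p = 1.0 / (1.0 + np.exp(-(coeffs.intercept + x @ beta)))
            freq = (
                data.table.groupby("vignette")["chose_continue"].mean().to_numpy()
            )
            deviations[replicates] = np.max(np.abs(freq - p))
        assert deviations[2000] < deviations[20]

    def test_csv_round_trip(self, coeffs):
        from biowean import ChoiceDataset

        design = VignetteDesign.full_factorial(replicates=1, seed=2)
        data = simulate_choices(design, coeffs)
        again = ChoiceDataset.from_csv(data.to_csv())
        assert again.table.shape == data.table.shape
        assert (
            again.table["chose_continue"].to_numpy()
            == data.table["chose_continue"].to_numpy()
        ).all()


class TestFitChoiceModel:
    def test_matches_independent_mle_oracle(self, coeffs):
        design = VignetteDesign.full_factorial(replicates=10, seed=21)
        data = simulate_choices(design, coeffs)
        fit = fit_choice_model(data, baseline_from=coeffs)
        x = data.table[list(CRITERIA)].to_numpy(dtype=float)
        y = data.table["chose_continue"].to_numpy(dtype=float)
        oracle = _oracle_logit_mle(x, y)
        assert fit.coeffs.intercept == pytest.approx(oracle[0], abs=1e-4)
        for i, name in enumerate(CRITERIA):
            assert fit.coeffs.betas[name] == pytest.approx(oracle[1 + i], abs=1e-4)

    def test_recovery_bias_shrinks_with_raters(self, coeffs):
        errors = {}
        for replicates in (5, 80):
            design = VignetteDesign.full_factorial(replicates=replicates, seed=17)
            fit = fit_choice_model(
                simulate_choices(design, coeffs), baseline_from=coeffs
            )
            errors[replicates] = np.mean(
                [abs(fit.coeffs.betas[n] - coeffs.betas[n]) for n in CRITERIA]
            )
        assert errors[80] < errors[5]

    def test_identical_choices_raise_separation_error(self, coeffs):
        forced = CoefficientSet(
            intercept=50.0,
            betas=coeffs.betas,
            baseline_intercept=coeffs.baseline_intercept,
            baseline_slope=coeffs.baseline_slope,
        )
        design = VignetteDesign.full_factorial(replicates=2, seed=0)
        with pytest.raises(SeparationError):
            fit_choice_model(simulate_choices(design, forced))

    def test_rank_deficient_design_rejected(self, coeffs):
        design = VignetteDesign(
            profiles=generate_profiles(1, prevalence={}, seed=0),
            replicates=40,
            seed=4,
        )
        with pytest.raises(EstimationError):
            fit_choice_model(simulate_choices(design, coeffs))

    def test_refit_log_likelihood_is_stable(self, coeffs):
        design = VignetteDesign.full_factorial(replicates=20, seed=29)
        first = fit_choice_model(simulate_choices(design, coeffs), baseline_from=coeffs)
        redesign = VignetteDesign.full_factorial(replicates=20, seed=31)
        second = fit_choice_model(
            simulate_choices(redesign, first.coeffs), baseline_from=coeffs
        )
        # per-observation log-likelihoods agree within sampling noise
        per_obs_first = first.log_likelihood / first.n_observations
        per_obs_second = second.log_likelihood / second.n_observations
        assert abs(per_obs_first - per_obs_second) < 0.05


class TestFitTimeBaseline:
    def test_noise_free_recovery_of_published_parameters(self):
        truth = (-1.2861, 0.7557)
        fractions = {
            m: truth[0] + truth[1] * math.log(m) for m in (6, 9, 12, 18, 24)
        }
        with pytest.warns(UserWarning):  # exact curve exceeds 1 at 24 months
            a, b = fit_time_baseline(fractions)
        assert a == pytest.approx(truth[0], abs=1e-9)
        assert b == pytest.approx(truth[1], abs=1e-9)

    def test_constant_fractions_give_zero_slope(self):
        a, b = fit_time_baseline({6: 0.4, 12: 0.4, 24: 0.4})
        assert b == pytest.approx(0.0, abs=1e-12)
        assert a == pytest.approx(0.4, abs=1e-12)

    def test_single_time_point_rejected(self):
        with pytest.raises(EstimationError):
            fit_time_baseline({12: 0.5})

    def test_noisy_recovery_is_unbiased(self):
        import warnings

        truth = (-1.2861, 0.7557)
        months = np.array([6.0, 9.0, 12.0, 15.0, 18.0])
        rng = np.random.default_rng(2026)
        slopes = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # rare noise dips below 0
            for _ in range(500):
                noisy = truth[0] + truth[1] * np.log(months) + rng.normal(0, 0.02, 5)
                _, b = fit_time_baseline(dict(zip(months, noisy)))
                slopes.append(b)
        slopes = np.asarray(slopes)
        se_mean = slopes.std(ddof=1) / math.sqrt(len(slopes))
        assert abs(slopes.mean() - truth[1]) < 3 * se_mean
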