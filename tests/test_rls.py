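"""Recursive least squares core: update law, equivalences, decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsrls.hrf import block_paradigm_train, expected_hr
from nirsrls.physio import PhysioFrequencies, fixed_frequencies
from nirsrls.rls import (
    RLSEState,
    RLSInit,
    batch_ols,
    build_regressor,
    rlse_update,
    run_filter,
    run_filter_no_ss,
)

FS = 1.81
FREQS = PhysioFrequencies(0.13, 0.26, 0.8)


def _exp(n):
    """Expected HR sized to n: the full block paradigm when it fits,
    otherwise a single short block."""
    from nirsrls.hrf import StimulusTrain

    if n >= 579:
        return expected_hr(block_paradigm_train(), FS, n)
    train = StimulusTrain(onsets=np.array([5.0]), durations=np.array([5.0]))
    return expected_hr(train, FS, n)


class TestBuildRegressor:
    def test_length_is_eight_with_ss_and_three_sinusoids(self):
        exp = _exp(100)
        phi = build_regressor(exp, 0.5, FREQS, 10, FS)
        assert phi.size == 8

    def test_time_zero_sinusoids_vanish_and_baseline_is_unity(self):
        exp = _exp(100)
        phi = build_regressor(exp, 0.0, FREQS, 0, FS)
        np.testing.assert_array_equal(phi[4:7], 0.0)
        assert phi[-1] == 1.0

    def test_sinusoid_entries_match_direct_evaluation(self):
        exp = _exp(100)
        idx = 37
        phi = build_regressor(exp, 0.0, FREQS, idx, FS)
        t = idx / FS
        expected = [np.sin(2 * np.pi * f * t) for f in FREQS.frequencies]
        np.testing.assert_allclose(phi[4:7], expected, atol=1e-15)

    def test_non_finite_ss_value_rejected(self):
        exp = _exp(100)
        with pytest.raises(ValueError, match="sample 5"):
            build_regressor(exp, np.nan, FREQS, 5, FS)


class TestRlseUpdate:
    def test_zero_innovation_leaves_coefficients_unchanged(self):
        state = RLSEState(beta=np.array([2.0, -1.0]), P=np.eye(2), lam=0.99)
        phi = np.array([1.0, 3.0])
        y = phi @ state.beta
        new = rlse_update(state, phi, y)
        np.testing.assert_array_equal(new.beta, state.beta)

    def test_scalar_regression_converges_to_ols_slope(self):
        state = RLSEState(beta=np.zeros(1), P=np.array([[1e6]]), lam=1.0)
        for phi, y in [(1.0, 2.0), (2.0, 4.0), (3.0, 6.0)]:
            state = rlse_update(state, np.array([phi]), y)
        assert abs(state.beta[0] - 2.0) < 1e-4  # closed-form slope = 2

    def test_batch_equivalence_at_lambda_one(self):
        rng = np.random.default_rng(0)
        n, p = 200, 8
        Phi = rng.normal(size=(n, p))
        y = Phi @ rng.normal(size=p) + 0.1 * rng.normal(size=n)
        state = RLSEState(beta=np.zeros(p), P=1e6 * np.eye(p), lam=1.0)
        for i in range(n):
            state = rlse_update(state, Phi[i], y[i])
        ols = batch_ols(Phi, y)
        assert np.max(np.abs(state.beta - ols)) / np.max(np.abs(ols)) < 1e-6

    @given(st.integers(0, 1000))
    @settings(max_examples=15)
    def test_batch_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 4
        Phi = rng.normal(size=(n, p))
        y = rng.normal(size=n)
        state = RLSEState(beta=np.zeros(p), P=1e7 * np.eye(p), lam=1.0)
        for i in range(n):
            state = rlse_update(state, Phi[i], y[i])
        ols = batch_ols(Phi, y)
        np.testing.assert_allclose(state.beta, ols, rtol=1e-5, atol=1e-7)

    def test_covariance_stays_symmetric_positive_definite(self):
        rng = np.random.default_rng(1)
        state = RLSEState(beta=np.zeros(5), P=1e4 * np.eye(5), lam=1.0)
        for _ in range(100):
            state = rlse_update(state, rng.normal(size=5), rng.normal())
        np.testing.assert_array_equal(state.P, state.P.T)
        assert np.linalg.eigvalsh(state.P).min() > 0

    def test_non_finite_observation_rejected(self):
        state = RLSEState(beta=np.zeros(2), P=np.eye(2), lam=1.0)
        with pytest.raises(ValueError, match="non-finite"):
            rlse_update(state, np.array([1.0, np.nan]), 0.0)

    def test_invalid_forgetting_factor_rejected(self):
        with pytest.raises(ValueError, match="forgetting"):
            RLSEState(beta=np.zeros(2), P=np.eye(2), lam=0.0)


class TestRunFilter:
    def _generative(self, freqs, coeffs, n=579):
        exp = _exp(n)
        t = np.arange(n) / FS
        Phi = np.column_stack(
            [exp.u, exp.du, exp.d2u]
            + [np.sin(2 * np.pi * f * t) for f in freqs.frequencies]
            + [np.ones(n)]
        )
        return exp, Phi @ coeffs

    def test_noise_free_generative_recovery(self):
        """Constant-coefficient, noise-free data: coefficients recovered to
        well under 1% with a tiny residual after convergence."""
        true = np.array([1.2, 0.3, -0.2, 0.5, 0.3, 0.4, 0.05])
        exp, y = self._generative(FREQS, true)
        res = run_filter_no_ss(y, exp, FREQS, lam=1.0)
        rel = np.abs(res.final_coefficients - true) / np.abs(true)
        assert rel.max() < 0.01
        half = y.size // 2
        assert np.sqrt(np.mean(res.residual[half:] ** 2)) < 1e-6

    def test_coefficient_error_decreases_after_burn_in(self):
        true = np.array([1.2, 0.3, -0.2, 0.5, 0.3, 0.4, 0.05])
        exp, y = self._generative(FREQS, true)
        res = run_filter_no_ss(y, exp, FREQS, lam=1.0)
        err = np.linalg.norm(res.coefficients - true, axis=1)
        burn = 80
        checkpoints = err[burn::100]
        assert np.all(np.diff(checkpoints) <= 1e-12)

    def test_mixture_hr_recovery(self, validation_mixture, block_expected_hr):
        components, mixture, _ = validation_mixture
        freqs = PhysioFrequencies(0.13, 0.26, 0.9)
        res = run_filter_no_ss(mixture, block_expected_hr, freqs)
        half = mixture.size // 2
        r = np.corrcoef(res.extracted_hr[half:], components["hr"][half:])[0, 1]
        assert r > 0.9

    def test_null_signal_extracts_nothing(self):
        n = 400
        exp = _exp(n)
        res = run_filter_no_ss(np.zeros(n), exp, FREQS)
        assert np.max(np.abs(res.coefficients[-1])) < 1e-10
        assert np.max(np.abs(res.extracted_hr)) < 1e-10

    def test_components_sum_to_fitted_and_residual_closes(self):
        rng = np.random.default_rng(3)
        n = 300
        exp = _exp(n)
        y = rng.normal(size=n)
        ss = rng.normal(size=n)
        res = run_filter(y, ss, exp, FREQS)
        total = np.zeros(n)
        for name in res.regressor_names:
            total = total + res.components[name]
        np.testing.assert_array_equal(total, res.fitted)
        np.testing.assert_array_equal(res.residual, y - res.fitted)

    def test_no_ss_variant_has_seven_regressors(self):
        n = 200
        res = run_filter_no_ss(np.zeros(n), _exp(n), FREQS)
        assert len(res.regressor_names) == 7

    def test_no_ss_equals_full_model_with_null_ss_channel(self):
        components, mixture, _ = (
            __import__("nirsrls").make_oscillator_mixture(
                __import__("nirsrls").validation_mixture_config(2)
            )
        )
        exp = _exp(mixture.size)
        full = run_filter(mixture, np.zeros(mixture.size), exp, FREQS)
        no_ss = run_filter_no_ss(mixture, exp, FREQS)
        np.testing.assert_allclose(
            full.extracted_hr, no_ss.extracted_hr, atol=1e-8
        )

    def test_estimated_frequencies_beat_fixed_on_mismatched_tones(self):
        """When the true tones sit at 0.13/0.26/0.9 Hz, filtering with the
        estimated frequencies tracks the HR at least as well as the nominal
        fixed set in a majority of seeds."""
        from nirsrls import estimate_frequencies, make_oscillator_mixture
        from nirsrls import validation_mixture_config

        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            comps, mix, _ = make_oscillator_mixture(validation_mixture_config(seed))
            exp = _exp(mix.size)
            est = estimate_frequencies(mix[: int(20 * FS)], FS)
            fix = fixed_frequencies(FS)
            half = mix.size // 2
            r_est = np.corrcoef(
                run_filter_no_ss(mix, exp, est).extracted_hr[half:],
                comps["hr"][half:],
            )[0, 1]
            r_fix = np.corrcoef(
                run_filter_no_ss(mix, exp, fix).extracted_hr[half:],
                comps["hr"][half:],
            )[0, 1]
            wins += r_est >= r_fix
        assert wins > n_seeds / 2

    def test_forgetting_tracks_step_change_faster_for_smaller_lambda(self):
        """After a mid-run jump in the HR coefficient, smaller forgetting
        factors re-converge faster (errors ordered in lambda)."""
        n = 579
        exp = _exp(n)
        t = np.arange(n) / FS
        Phi = np.column_stack(
            [exp.u, exp.du, exp.d2u]
            + [np.sin(2 * np.pi * f * t) for f in FREQS.frequencies]
            + [np.ones(n)]
        )
        coeffs = np.tile([1.0, 0.3, -0.2, 0.5, 0.3, 0.4, 0.05], (n, 1))
        t0 = n // 2
        coeffs[t0:, 0] = 3.0  # step change in the HR amplitude
        y = np.einsum("ij,ij->i", Phi, coeffs)
        errs = []
        for lam in (0.90, 0.95, 0.99):
            res = run_filter_no_ss(y, exp, FREQS, lam=lam)
            k = t0 + 40
            errs.append(abs(res.coefficients[k, 0] - 3.0))
        assert errs[0] <= errs[1] <= errs[2]

    def test_length_mismatch_rejected(self):
        exp = _exp(100)
        with pytest.raises(ValueError, match="equal length"):
            run_filter(np.zeros(100), np.zeros(99), exp, FREQS)

    def test_nan_input_names_sample(self):
        exp = _exp(50)
        y = np.zeros(50)
        y[17] = np.nan
        with pytest.raises(ValueError, match="17"):
            run_filter_no_ss(y, exp, FREQS)


class TestBatchOls:
    def test_identity_design_returns_observations(self):
        y = np.array([3.0, -1.0, 2.0])
        np.testing.assert_allclose(batch_ols(np.eye(3), y), y)

    def test_orthogonal_design_gives_projections(self):
        rng = np.random.default_rng(4)
        q, _ = np.linalg.qr(rng.normal(size=(30, 3)))
        y = rng.normal(size=30)
        np.testing.assert_allclose(batch_ols(q, y), q.T @ y, atol=1e-12)

    def test_rank_deficiency_rejected(self):
        design = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            batch_ols(design, np.zeros(10))
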