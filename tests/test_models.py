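import numpy as np
import pytest

from condesign import (
    CueSet,
    KRWParams,
    RWParams,
    RWPHParams,
    Stage,
    StageWiseDesign,
    log_likelihood,
    simulate_dataset,
)
from condesign.experiments import ExperimentRealization
from condesign.models import (
    Dataset,
    _run_trace,
    emit_response,
    encode,
    krw_step,
    response_means,
    rw_step,
    rwph_step,
)


def _manual_realization(cue_set, labels, outcomes):
    pres = cue_set.presentable
    idx = np.array([pres.index(lab) for lab in labels])
    return ExperimentRealization(pres, idx, np.array(outcomes))


class TestEncoding:
    def test_compound_row(self, ab_cue_set):
        real = _manual_realization(ab_cue_set, ["AB", "A"], [1, 0])
        stim = encode(real, ab_cue_set)
        np.testing.assert_array_equal(stim.X, [[1, 1], [1, 0]])
        np.testing.assert_array_equal(stim.r, [1, 0])

    def test_unknown_label_raises(self, ab_cue_set):
        real = ExperimentRealization(("A", "C"), np.array([1]), np.array([0]))
        with pytest.raises(ValueError, match="unknown stimulus"):
            encode(real, ab_cue_set)


class TestSteps:
    def test_rw_hand_iteration(self):
        w = np.zeros(1)
        x = np.ones(1)
        w, delta = rw_step(w, x, 1.0, 0.2)
        assert delta == 1.0 and w[0] == pytest.approx(0.2)
        w, delta = rw_step(w, x, 1.0, 0.2)
        assert delta == pytest.approx(0.8) and w[0] == pytest.approx(0.36)

    def test_rw_zero_rate_freezes_weights(self):
        w = np.array([0.4, -0.2])
        w2, _ = rw_step(w, np.array([1.0, 1.0]), 1.0, 0.0)
        np.testing.assert_array_equal(w, w2)

    def test_rw_absent_cue_unchanged(self):
        w = np.array([0.0, 0.7])
        w2, _ = rw_step(w, np.array([1.0, 0.0]), 1.0, 0.3)
        assert w2[1] == 0.7

    def test_krw_scalar_kalman(self):
        params = KRWParams(w0_var=1.0, q_diffusion=0.0, r_noise_var=1.0,
                           sigma_obs=0.1)
        w, S, gain = krw_step(np.zeros(1), np.eye(1), np.ones(1), 1.0, params)
        assert gain[0] == pytest.approx(0.5)
        assert w[0] == pytest.approx(0.5)
        assert S[0, 0] == pytest.approx(0.5)

    def test_krw_zero_uncertainty_no_update(self):
        params = KRWParams(w0_var=0.0, q_diffusion=0.0, r_noise_var=0.5,
                           sigma_obs=0.1)
        w, S, _ = krw_step(np.zeros(2), np.zeros((2, 2)),
                           np.array([1.0, 0.0]), 1.0, params)
        np.testing.assert_array_equal(w, 0.0)
        np.testing.assert_array_equal(S, 0.0)

    def test_krw_rejects_non_psd(self):
        params = KRWParams(1.0, 0.0, 1.0, 0.1)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="semidefinite"):
            krw_step(np.zeros(2), bad, np.array([1.0, 0.0]), 1.0, params)

    def test_rwph_hand_evaluation(self):
        params = RWPHParams(kappa=0.4, eta=0.2, alpha0=0.5, sigma_obs=0.1)
        V, assoc, delta = rwph_step(np.zeros(1), np.array([0.5]), np.ones(1),
                                    1.0, params)
        assert delta == 1.0
        assert V[0] == pytest.approx(0.2)
        assert assoc[0] == pytest.approx(0.6)

    def test_rwph_eta_one_tracks_abs_delta(self):
        params = RWPHParams(kappa=0.1, eta=1.0, alpha0=0.3, sigma_obs=0.1)
        V = np.array([0.4])
        _, assoc, _ = rwph_step(V, np.array([0.3]), np.ones(1), 1.0, params)
        assert assoc[0] == pytest.approx(0.6)  # |1 - 0.4|

    def test_rwph_eta_zero_reduces_to_rw(self):
        """With frozen associabilities the hybrid is the delta rule at rate
        kappa*alpha0."""
        params = RWPHParams(kappa=0.4, eta=0.0, alpha0=0.5, sigma_obs=0.1)
        rng = np.random.default_rng(0)
        V = np.zeros(2)
        assoc = np.full(2, 0.5)
        w = np.zeros(2)
        for _ in range(25):
            x = rng.integers(0, 2, 2).astype(float)
            r = float(rng.integers(0, 2))
            V, assoc, _ = rwph_step(V, assoc, x, r, params)
            w, _ = rw_step(w, x, r, 0.4 * 0.5)
        np.testing.assert_allclose(V, w, atol=1e-12)
        np.testing.assert_array_equal(assoc, 0.5)


class TestResponses:
    def test_mixture_mean(self):
        latents = {"V": np.array([0.4]), "assoc": np.array([0.8])}
        x = np.ones(1)
        assert emit_response(latents, "V_plus_alpha", x, 0.0,
                             np.random.default_rng(0), omega=0.5) == pytest.approx(0.6)

    def test_omega_zero_equals_v_mapping(self):
        latents = {"V": np.array([0.4]), "assoc": np.array([0.8])}
        x = np.ones(1)
        rng = np.random.default_rng(0)
        assert emit_response(latents, "V_plus_alpha", x, 0.0, rng, omega=0.0) \
            == emit_response(latents, "V", x, 0.0, rng)

    def test_noiseless_response_is_mean(self):
        latents = {"V": np.array([0.37])}
        assert emit_response(latents, "V", np.ones(1), 0.0,
                             np.random.default_rng(5)) == 0.37


class TestSimulation:
    def test_rw_closed_form_learning_curve(self, always_reinforced):
        """Noise-free RW under certain reinforcement: CR_t = 1 - (1-alpha)^t."""
        ds, _ = simulate_dataset(always_reinforced, "rw",
                                 {"alpha": 0.2, "sigma_obs": 0.0}, seed=0)
        t = np.arange(ds.n_trials)
        np.testing.assert_allclose(ds.responses, 1.0 - 0.8**t, atol=1e-12)

    def test_unknown_model_rejected(self, always_reinforced):
        with pytest.raises(ValueError, match="unknown model_id"):
            simulate_dataset(always_reinforced, "qlearn", {}, seed=0)

    def test_seed_reproducibility(self, backward_blocking_design):
        p = {"w0_var": 1.0, "q_diffusion": 0.01, "r_noise_var": 0.25,
             "sigma_obs": 0.5}
        a, _ = simulate_dataset(backward_blocking_design, "krw", p, seed=9)
        b, _ = simulate_dataset(backward_blocking_design, "krw", p, seed=9)
        np.testing.assert_array_equal(a.responses, b.responses)
        np.testing.assert_array_equal(a.realization.outcomes,
                                      b.realization.outcomes)

    def test_kernel_matches_reference_trace(self, backward_blocking_design):
        """JIT likelihood kernels agree with the single-step reference loop."""
        cases = [
            ("rw", {"alpha": 0.3, "sigma_obs": 0.5}),
            ("krw", {"w0_var": 1.0, "q_diffusion": 0.01, "r_noise_var": 0.25,
                     "sigma_obs": 0.5}),
            ("rwph_v", {"kappa": 0.5, "eta": 0.7, "alpha0": 0.7,
                        "sigma_obs": 0.5}),
            ("rwph_alpha", {"kappa": 0.5, "eta": 0.7, "alpha0": 0.7,
                            "sigma_obs": 0.5}),
            ("rwph_valpha", {"kappa": 0.5, "eta": 0.7, "alpha0": 0.7,
                             "omega": 0.4, "sigma_obs": 0.5}),
        ]
        ds, _ = simulate_dataset(backward_blocking_design, "rw",
                                 {"alpha": 0.3, "sigma_obs": 0.5}, seed=4)
        stim = ds.encoded()
        for model_id, params in cases:
            fast = response_means(model_id, params, stim)
            slow, _ = _run_trace(model_id, params, stim)
            np.testing.assert_allclose(fast, slow, atol=1e-12)


class TestLikelihood:
    def test_zero_residuals_value(self, always_reinforced):
        ds, _ = simulate_dataset(always_reinforced, "rw",
                                 {"alpha": 0.2, "sigma_obs": 0.0}, seed=0)
        ll = log_likelihood("rw", {"alpha": 0.2, "sigma_obs": 1.0}, ds)
        assert ll == pytest.approx(-ds.n_trials / 2 * np.log(2 * np.pi))

    def test_unit_residual_costs_half(self, always_reinforced):
        ds, _ = simulate_dataset(always_reinforced, "rw",
                                 {"alpha": 0.2, "sigma_obs": 0.0}, seed=0)
        bumped = Dataset(ds.realization,
                         ds.responses + np.eye(1, ds.n_trials, 3).ravel(),
                         ds.cue_set)
        base = log_likelihood("rw", {"alpha": 0.2, "sigma_obs": 1.0}, ds)
        assert log_likelihood("rw", {"alpha": 0.2, "sigma_obs": 1.0}, bumped) \
            == pytest.approx(base - 0.5)

    def test_matches_naive_per_trial_oracle(self, single_cue_set):
        """Brute-force per-trial Gaussian densities on a 5-trial dataset."""
        design = StageWiseDesign(single_cue_set,
                                 (Stage(5, {"CS": 1.0}, {"CS": 0.6}),))
        params = {"alpha": 0.35, "sigma_obs": 0.2}
        ds, _ = simulate_dataset(design, "rw", params, seed=21)
        w = 0.0
        ll = 0.0
        for t in range(5):
            m = w
            resid = ds.responses[t] - m
            ll += -0.5 * np.log(2 * np.pi * 0.2**2) - resid**2 / (2 * 0.2**2)
            w += 0.35 * (ds.realization.outcomes[t] - w)
        assert log_likelihood("rw", params, ds) == pytest.approx(ll, abs=1e-10)

    def test_nonpositive_sigma_rejected(self, always_reinforced):
        ds, _ = simulate_dataset(always_reinforced, "rw",
                                 {"alpha": 0.2, "sigma_obs": 0.1}, seed=0)
        with pytest.raises(ValueError, match="sigma"):
            log_likelihood("rw", {"alpha": 0.2, "sigma_obs": 0.0}, ds)


class TestModelProperties:
    @pytest.mark.parametrize("p", [0.25, 0.5, 0.75])
    def test_rw_asymptote_tracks_reinforcement_rate(self, single_cue_set, p):
        design = StageWiseDesign(single_cue_set,
                                 (Stage(2000, {"CS": 1.0}, {"CS": p}),))
        ds, trace = simulate_dataset(design, "rw",
                                     {"alpha": 0.15, "sigma_obs": 0.0}, seed=8)
        tail = trace.V[-400:, 0]
        assert abs(tail.mean() - p) < 0.05

    def test_nesting_likelihood_identity(self, backward_blocking_design):
        """RWPH(V) with eta=0 and kappa*alpha0=alpha is exactly RW."""
        ds, _ = simulate_dataset(backward_blocking_design, "rw",
                                 {"alpha": 0.3, "sigma_obs": 0.5}, seed=13)
        ll_rw = log_likelihood("rw", {"alpha": 0.28, "sigma_obs": 0.4}, ds)
        ll_ph = log_likelihood(
            "rwph_v",
            {"kappa": 0.7, "eta": 0.0, "alpha0": 0.4, "sigma_obs": 0.4}, ds,
        )  # kappa*alpha0 = 0.28
        assert ll_ph == pytest.approx(ll_rw, abs=1e-9)

    def test_krw_covariance_stays_psd_under_fuzz(self):
        """Random stimuli/outcomes for 10,000 steps keep Sigma symmetric PSD."""
        rng = np.random.default_rng(99)
        params = KRWParams(w0_var=1.0, q_diffusion=0.05, r_noise_var=0.2,
                           sigma_obs=0.1)
        w = np.zeros(3)
        S = np.eye(3)
        for i in range(10_000):
            x = rng.integers(0, 2, 3).astype(float)
            if not x.any():
                x[rng.integers(3)] = 1.0
            w, S, _ = krw_step(w, S, x, float(rng.integers(0, 2)), params)
            if i % 500 == 0:
                assert np.linalg.eigvalsh(S).min() >= -1e-10
        np.testing.assert_allclose(S, S.T, atol=1e-12)
        assert np.linalg.eigvalsh(S).min() >= -1e-10

    def test_backward_blocking_krw_vs_rw(self, ab_cue_set):
        """AB+ then A+ training: KRW revalues the absent cue B downward
        (negative weight covariance); RW leaves it untouched."""
        labels = ["AB"] * 20 + ["A"] * 20
        real = _manual_realization(ab_cue_set, labels, [1] * 40)
        stim = encode(real, ab_cue_set)
        b = 1  # element index of cue B

        _, krw_trace = _run_trace(
            "krw", {"w0_var": 1.0, "q_diffusion": 0.01, "r_noise_var": 0.25,
                    "sigma_obs": 0.0}, stim)
        wb_end_stage1 = krw_trace.V[20, b]
        # negative weight correlation learned during compound training
        assert krw_trace.Sigma[20, 0, 1] < 0
        final_wb_krw = krw_trace.V[-1, b] + 0  # pre-trial value at last trial
        assert final_wb_krw < wb_end_stage1

        _, rw_trace = _run_trace("rw", {"alpha": 0.3, "sigma_obs": 0.0}, stim)
        assert rw_trace.V[-1, b] == pytest.approx(rw_trace.V[20, b])
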