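import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cuelearn.models import (
    LatentState,
    ModelSpec,
    Params,
    effective_expectation,
    initialize_state,
    is_congruent,
    log_likelihood,
    model_catalogue,
    predict_outcome,
    prediction_error,
    run_model,
    stimulus_value,
    update_state,
    fill_ratings,
)
from conftest import toy_trials


def _iterate_m2a(E0, alpha, omega, cues, levels, obs_O):
    """Independent spreadsheet-style iteration of the delta rule (oracle)."""
    E = dict(E0)
    rows = []
    for cue, lvl, O in zip(cues, levels, obs_O):
        Et = E[cue]
        Ohat = omega * Et + (1 - omega) * {1: 0.25, 2: 0.5, 3: 0.75}[lvl]
        d = O - Et
        rows.append((Et, Ohat, d))
        E[cue] = min(1.0, max(0.0, Et + alpha * d))
    return rows


class TestPrimitives:
    @pytest.mark.parametrize("level,value", [(1, 0.25), (2, 0.50), (3, 0.75)])
    def test_stimulus_anchors(self, level, value):
        assert stimulus_value(level) == value

    def test_stimulus_level_out_of_range(self):
        with pytest.raises(ValueError):
            stimulus_value(4)

    @pytest.mark.parametrize(
        "omega,Etilde,level,expect",
        [(0.0, 0.8, 2, 0.5), (1.0, 0.8, 2, 0.8), (0.25, 0.8, 2, 0.575)],
    )
    def test_predict_outcome(self, omega, Etilde, level, expect):
        assert predict_outcome(Etilde, level, omega) == pytest.approx(expect)

    @pytest.mark.parametrize("O,E,d", [(0.6, 0.4, 0.2), (0.4, 0.4, 0.0), (0.2, 0.4, -0.2)])
    def test_prediction_error(self, O, E, d):
        assert prediction_error(O, E) == pytest.approx(d)

    @pytest.mark.parametrize(
        "cue,delta,expect",
        [("high", 0.1, True), ("low", -0.1, True), ("high", -0.1, False),
         ("low", 0.1, False), ("high", 0.0, False)],
    )
    def test_congruency_rule(self, cue, delta, expect):
        assert is_congruent(cue, delta) is expect


class TestEffectiveExpectation:
    def test_perceptual_carryover_limits(self):
        spec = ModelSpec("M2c")
        st8 = LatentState(E_low=0.3, E_high=0.6, prev_O=0.9)
        p0 = Params.for_model(spec, alpha=0.3, omega=0.2, beta_O=0.0)
        p1 = Params.for_model(spec, alpha=0.3, omega=0.2, beta_O=1.0)
        assert effective_expectation(st8, p0, "high", spec) == 0.6
        assert effective_expectation(st8, p1, "high", spec) == pytest.approx(0.9)

    def test_expectation_carryover_mixture(self):
        spec = ModelSpec("M2b")
        st8 = LatentState(E_low=0.4, E_high=0.4, prev_Etilde=0.8)
        p = Params.for_model(spec, alpha=0.3, omega=0.2, beta_E=0.5)
        assert effective_expectation(st8, p, "low", spec) == pytest.approx(0.6)

    def test_first_trial_falls_back_to_learned_value(self):
        spec = ModelSpec("M2c")
        st8 = LatentState(E_low=0.3, E_high=0.6)  # prev_O None
        p = Params.for_model(spec, alpha=0.3, omega=0.2, beta_O=0.7)
        assert effective_expectation(st8, p, "low", spec) == 0.3

    def test_tracker_offsets(self):
        spec = ModelSpec("M2d")
        st8 = LatentState(G=0.5)
        p = Params.for_model(spec, alpha=0.3, omega=0.2, b_low=-0.2, b_high=0.3)
        assert effective_expectation(st8, p, "low", spec) == pytest.approx(0.3)
        assert effective_expectation(st8, p, "high", spec) == pytest.approx(0.8)


class TestUpdate:
    def test_congruent_update_arithmetic(self):
        spec = ModelSpec("M3a")
        p = Params.for_model(spec, alpha_c=0.5, alpha_i=0.1, omega=0.2)
        s = LatentState(E_low=0.2, E_high=0.40)
        update_state(s, "high", +0.20, p, spec)  # congruent: rate 0.5
        assert s.E_high == pytest.approx(0.50) and s.E_low == 0.2

    def test_incongruent_update_uses_slower_rate(self):
        spec = ModelSpec("M3a")
        p = Params.for_model(spec, alpha_c=0.5, alpha_i=0.1, omega=0.2)
        s = LatentState(E_low=0.2, E_high=0.40)
        update_state(s, "high", -0.20, p, spec)
        assert s.E_high == pytest.approx(0.38) and s.E_low == 0.2

    def test_zero_delta_is_fixed_point(self):
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.7, omega=0.2)
        s = LatentState(E_low=0.31, E_high=0.62)
        update_state(s, "low", 0.0, p, spec)
        assert (s.E_low, s.E_high) == (0.31, 0.62)

    def test_m1_has_no_update(self):
        spec = ModelSpec("M1")
        p = Params.for_model(spec, omega=0.2, E_low_fix=0.3, E_high_fix=0.7)
        with pytest.raises(ValueError):
            update_state(LatentState(), "high", 0.1, p, spec)


class TestInitialization:
    def test_seeded_from_first_cue_display(self):
        df = toy_trials(["high", "low"], cue_display=[117 / 180, 0.3])
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.3, omega=0.2)
        s = initialize_state(spec, p, df)
        assert s.E_high == pytest.approx(0.65) and s.E_low == pytest.approx(0.3)

    def test_absent_cue_type_falls_back(self):
        df = toy_trials(["low", "low"], cue_display=[0.3, 0.3])
        s = initialize_state(ModelSpec("M2a"), Params.for_model(ModelSpec("M2a"), alpha=0.3, omega=0.2), df)
        assert s.E_high == 0.5

    def test_m1_uses_free_fixed_expectancies(self):
        df = toy_trials(["low", "high"])
        spec = ModelSpec("M1")
        p = Params.for_model(spec, omega=0.2, E_low_fix=0.3, E_high_fix=0.9)
        s = initialize_state(spec, p, df)
        assert (s.E_low, s.E_high) == (0.3, 0.9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            initialize_state(ModelSpec("M2a"),
                             Params.for_model(ModelSpec("M2a"), alpha=0.3, omega=0.2),
                             toy_trials([]))


class TestRunModel:
    def test_delta_rule_matches_hand_iteration(self):
        df = toy_trials(["high"] * 3, O=[0.9, 0.9, 0.9], cue_display=[0.5] * 3)
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.5, omega=0.2)
        traj = run_model(spec, p, df)
        assert np.allclose(traj.Etilde, [0.5, 0.7, 0.8], atol=1e-12)

    def test_conditioned_matches_oracle_on_random_table(self):
        rng = np.random.default_rng(3)
        n = 20
        cues = rng.choice(["low", "high"], n).tolist()
        levels = rng.integers(1, 4, n).tolist()
        O = rng.uniform(0.1, 0.9, n)
        df = toy_trials(cues, levels=levels, O=O, cue_display=[0.62 if c == "high" else 0.37 for c in cues])
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.34, omega=0.27)
        traj = run_model(spec, p, df)
        oracle = _iterate_m2a({"low": 0.37, "high": 0.62}, 0.34, 0.27, cues, levels, O)
        for t, (Et, Ohat, d) in enumerate(oracle):
            assert traj.Etilde[t] == pytest.approx(Et, abs=1e-10)
            assert traj.O_hat[t] == pytest.approx(Ohat, abs=1e-10)
            assert traj.delta[t] == pytest.approx(d, abs=1e-10)

    def test_noiseless_omega0_percepts_are_anchors(self):
        df = toy_trials(["high", "low"] * 6, levels=[1, 2, 3] * 4)
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.4, omega=0.0, sigma2_E=1e-12, sigma2_O=1e-12)
        traj = run_model(spec, p, df, mode="generative", rng=0)
        anchors = np.array([0.25, 0.5, 0.75])[df["stimulus_level"].to_numpy() - 1]
        assert np.allclose(traj.sim_perception, anchors, atol=1e-5)

    def test_m1_noiseless_expectations_constant_per_cue(self):
        df = toy_trials(["high", "low"] * 10)
        spec = ModelSpec("M1")
        p = Params.for_model(spec, omega=0.2, E_low_fix=0.3, E_high_fix=0.7,
                             sigma2_E=1e-12, sigma2_O=1e-12)
        traj = run_model(spec, p, df, mode="generative", rng=1)
        sim = traj.sim_expectation
        assert np.allclose(sim[::2], 0.7, atol=1e-5) and np.allclose(sim[1::2], 0.3, atol=1e-5)

    def test_generative_reproducible_and_conditioned_consistent(self):
        df = toy_trials(["high", "low", "high", "low"] * 6, levels=[1, 2, 3] * 8)
        spec = ModelSpec("M3c")
        p = Params.for_model(spec, alpha_c=0.5, alpha_i=0.1, omega=0.3, beta_O=0.4)
        t1 = run_model(spec, p, df, mode="generative", rng=7)
        t2 = run_model(spec, p, df, mode="generative", rng=7)
        assert np.array_equal(t1.sim_perception, t2.sim_perception)
        # recompute latents conditioned on the emitted table
        emitted = fill_ratings(df, t1)
        t3 = run_model(spec, p, emitted, mode="conditioned")
        assert np.allclose(t1.Etilde, t3.Etilde, atol=1e-12)
        assert np.allclose(t1.delta, t3.delta, atol=1e-12)

    @pytest.mark.parametrize(
        "full,reduced,kw",
        [
            ("M3a", "M2a", {}),
            ("M3c", "M2c", {"beta_O": 0.35}),
            ("M3b", "M2b", {"beta_E": 0.35}),
        ],
    )
    def test_reduction_chain_dual_equals_single(self, full, reduced, kw):
        df = toy_trials(["high", "low", "low", "high"] * 8, levels=[1, 2, 3, 2] * 8,
                        O=list(np.linspace(0.2, 0.8, 32)))
        pf = Params.for_model(ModelSpec(full), alpha_c=0.3, alpha_i=0.3, omega=0.25, **kw)
        pr = Params.for_model(ModelSpec(reduced), alpha=0.3, omega=0.25, **kw)
        tf = run_model(ModelSpec(full), pf, df)
        tr = run_model(ModelSpec(reduced), pr, df)
        assert np.allclose(tf.Etilde, tr.Etilde, atol=1e-12)

    @pytest.mark.parametrize("mid,kw", [("M2c", {"beta_O": 0.0}), ("M2b", {"beta_E": 0.0})])
    def test_reduction_chain_zero_carryover_equals_plain(self, mid, kw):
        df = toy_trials(["high", "low"] * 16, O=list(np.linspace(0.2, 0.8, 32)))
        pc = Params.for_model(ModelSpec(mid), alpha=0.4, omega=0.25, **kw)
        pa = Params.for_model(ModelSpec("M2a"), alpha=0.4, omega=0.25)
        assert np.allclose(
            run_model(ModelSpec(mid), pc, df).Etilde,
            run_model(ModelSpec("M2a"), pa, df).Etilde,
            atol=1e-12,
        )

    def test_single_cue_update_locality(self):
        df = toy_trials(["high"] * 10, O=list(np.linspace(0.9, 0.5, 10)),
                        cue_display=[0.6] * 10)
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.5, omega=0.2)
        traj = run_model(spec, p, df)
        assert np.all(traj.E_low == 0.5)  # fallback init, never touched

    def test_missing_perceptual_rating_freezes_learning(self):
        O = [0.9, np.nan, 0.9]
        df = toy_trials(["high"] * 3, O=O, cue_display=[0.5] * 3)
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.5, omega=0.2)
        traj = run_model(spec, p, df)
        assert traj.Etilde[1] == pytest.approx(0.7)
        assert traj.Etilde[2] == pytest.approx(0.7)  # no update on the missed trial


class TestConvergenceFixedPoints:
    """Long-run behavior encoding the central theoretical claim: a single
    learning rate extinguishes cue effects; a confirmation bias preserves
    them."""

    def _long_df(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        cues = rng.permutation(["high", "low"] * (n // 2)).tolist()
        levels = rng.permutation([1, 2, 3] * (n // 3 + 1))[:n].tolist()
        return toy_trials(cues, levels=levels,
                          cue_display=[0.67 if c == "high" else 0.33 for c in cues])

    def test_single_rate_expectancies_converge_to_mean_stimulus(self):
        # expectancies fluctuate around the mean anchor (discrete stimulus
        # levels keep perturbing them), so convergence is a statement about
        # the time-averaged cue gap, not a single endpoint
        spec = ModelSpec("M2a")
        p = Params.for_model(spec, alpha=0.3, omega=0.2, sigma2_E=1e-8, sigma2_O=1e-8)
        gaps, means = [], []
        for seed in range(3):
            df = self._long_df(seed=seed)
            traj = run_model(spec, p, df, mode="generative", rng=seed)
            tail = slice(-1000, None)
            gaps.append((traj.E_high[tail] - traj.E_low[tail]).mean())
            means.append(traj.E_high[tail].mean())
        assert abs(np.mean(gaps)) < 0.01
        assert abs(np.mean(means) - 0.5) < 0.05

    def test_dual_rate_gap_stays_positive(self):
        df = self._long_df()
        spec = ModelSpec("M3a")
        p = Params.for_model(spec, alpha_c=0.5, alpha_i=0.05, omega=0.3,
                             sigma2_E=0.02**2, sigma2_O=0.02**2)
        traj = run_model(spec, p, df, mode="generative", rng=5)
        tail = slice(-200, None)
        assert (traj.E_high[tail] - traj.E_low[tail]).mean() > 0.05


class TestLikelihood:
    def test_gaussian_at_mean(self):
        df = toy_trials(["high"], E=[0.65], O=[None])
        # observed ratings exactly at the model's predictions, unit variances
        spec = ModelSpec("M1")
        p = Params.for_model(spec, omega=0.4, E_low_fix=0.35, E_high_fix=0.65,
                             sigma2_E=1.0, sigma2_O=1.0)
        df.loc[0, "perceptual_rating"] = 0.4 * 0.65 + 0.6 * 0.5
        ll = log_likelihood(spec, p, df)
        assert ll == pytest.approx(2 * (-0.5 * math.log(2 * math.pi)))

    def test_matches_brute_force_density_sum(self):
        rng = np.random.default_rng(9)
        n = 10
        cues = rng.choice(["low", "high"], n).tolist()
        levels = rng.integers(1, 4, n).tolist()
        df = toy_trials(cues, levels=levels, E=rng.uniform(0.2, 0.8, n),
                        O=rng.uniform(0.2, 0.8, n))
        spec = ModelSpec("M2c")
        p = Params.for_model(spec, alpha=0.4, omega=0.3, beta_O=0.25,
                             sigma2_E=0.01, sigma2_O=0.02)
        traj = run_model(spec, p, df)
        from scipy.stats import norm
        brute = (
            norm.logpdf(df["expectation_rating"], traj.Etilde, np.sqrt(0.01)).sum()
            + norm.logpdf(df["perceptual_rating"], traj.O_hat, np.sqrt(0.02)).sum()
        )
        assert log_likelihood(spec, p, df) == pytest.approx(brute, abs=1e-9)

    def test_sharper_noise_increases_ll_at_perfect_fit(self):
        df = toy_trials(["high"], E=[0.65], O=[0.56])
        spec = ModelSpec("M1")
        kw = dict(omega=0.4, E_low_fix=0.35, E_high_fix=0.65)
        df.loc[0, "perceptual_rating"] = 0.4 * 0.65 + 0.6 * 0.5
        ll1 = log_likelihood(spec, Params.for_model(spec, sigma2_O=1.0, sigma2_E=1.0, **kw), df)
        ll2 = log_likelihood(spec, Params.for_model(spec, sigma2_O=0.5, sigma2_E=1.0, **kw), df)
        assert ll2 > ll1

    def test_nonpositive_variance_rejected(self):
        df = toy_trials(["high"])
        spec = ModelSpec("M2a")
        with pytest.raises(ValueError):
            Params.for_model(spec, alpha=0.3, omega=0.2, sigma2_E=0.0)


@given(
    alpha=st.floats(0.05, 0.95), omega=st.floats(0.0, 1.0),
    seed=st.integers(0, 10_000),
)
@settings(max_examples=25, deadline=None)
def test_latents_always_in_unit_interval(alpha, omega, seed):
    rng = np.random.default_rng(seed)
    n = 30
    cues = rng.choice(["low", "high"], n).tolist()
    df = toy_trials(cues, levels=rng.integers(1, 4, n).tolist(),
                    O=rng.uniform(0, 1, n))
    spec = ModelSpec("M2a")
    p = Params.for_model(spec, alpha=alpha, omega=omega)
    traj = run_model(spec, p, df)
    assert np.all((traj.E_low >= 0) & (traj.E_low <= 1))
    assert np.all((traj.E_high >= 0) & (traj.E_high <= 1))


def test_model_catalogue_lists_nine_models():
    cat = model_catalogue()
    assert len(cat) == 9
    assert cat.set_index("model_id").loc["M3c", "n_params"] == 6
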