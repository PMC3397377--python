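"""Trial-to-trial priming, threshold dynamics and the session simulator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import seqddm
from seqddm import (
    AdaptiveModelParams,
    ModelState,
    ScaledDDMParams,
    conditional_mean_dts,
    error_rate,
    initial_condition,
    initial_state,
    simulate_session,
    simulate_trial,
    update_memory,
    update_threshold,
)
from seqddm.mechanisms import prepare_session, run_prepared_session


def pure_ddm_params(mu_tilde=19.3312, t_nd=0.3359, z=0.15):
    """Adaptive parameter set with both mechanisms switched off."""
    return AdaptiveModelParams(mu_tilde=mu_tilde, t_nd=t_nd, k=0.0,
                               x_offset=0.0, delta=0.5, z_down=0.0,
                               z_up=0.0, z_max=z)


class TestParams:
    def test_empty_threshold_range_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            AdaptiveModelParams(mu_tilde=10, t_nd=0.3, k=0.4, x_offset=0.01,
                                delta=0.5, z_down=0.01, z_up=0.05, z_max=0.1)

    def test_delta_bounds(self):
        for bad in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                AdaptiveModelParams(mu_tilde=10, t_nd=0.3, k=0.1,
                                    x_offset=0.005, delta=bad, z_down=0.005,
                                    z_up=0.05, z_max=0.3)

    def test_table_defaults_are_valid(self):
        assert seqddm.EXPERIMENT1_FIT.z_max >= seqddm.EXPERIMENT1_FIT.z_floor
        assert seqddm.EXPERIMENT2_FIT.z_max >= seqddm.EXPERIMENT2_FIT.z_floor


class TestMemoryUpdate:
    def test_repetition_example(self):
        assert update_memory(0.5, "R", 0.686) == pytest.approx(0.657, abs=1e-12)

    def test_all_repetition_fixed_point(self):
        for delta in (0.3, 0.5, 0.686):
            assert update_memory(1.0, "R", delta) == pytest.approx(1.0)

    def test_four_alternations_from_full_memory(self):
        m = 1.0
        for _ in range(4):
            m = update_memory(m, "A", 0.5)
        assert m == 0.0625

    @given(m=st.floats(0.0, 1.0), delta=st.floats(0.01, 0.99),
           rep=st.booleans())
    def test_stays_in_unit_interval(self, m, delta, rep):
        out = update_memory(m, "R" if rep else "A", delta)
        assert 0.0 <= out <= 1.0


class TestInitialCondition:
    def test_unbiased_memory_no_offset(self):
        assert initial_condition(0.5, "R", k=0.3, x_offset=0.0) == 0.0

    def test_repetition_example(self):
        x = initial_condition(0.75, "R", k=0.1181, x_offset=0.0034)
        assert x == pytest.approx(0.032925, abs=1e-12)

    def test_alternation_flips_sign(self):
        xr = initial_condition(0.75, "R", k=0.1181, x_offset=0.0034)
        xa = initial_condition(0.75, "A", k=0.1181, x_offset=0.0034)
        assert xa == pytest.approx(-xr)

    def test_undefined_transition_is_unprimed(self):
        assert initial_condition(0.9, None, k=0.1, x_offset=0.01) == 0.0

    @given(m=st.floats(0.0, 1.0), rep=st.booleans())
    def test_magnitude_bounded_by_threshold_floor(self, m, rep):
        k, x_off = 0.1181, 0.0034
        x = initial_condition(m, "R" if rep else "A", k, x_off)
        assert abs(x) <= 0.5 * k + x_off + 1e-15


class TestThresholdUpdate:
    def test_upper_clamp_on_error(self, exp2_params):
        assert update_threshold(exp2_params.z_max, False, exp2_params) == \
            exp2_params.z_max

    def test_correct_decrement(self, exp2_params):
        z = update_threshold(0.2062, True, exp2_params)
        assert z == pytest.approx(0.2028, abs=1e-12)

    def test_lower_clamp_on_correct(self, exp2_params):
        z = update_threshold(exp2_params.z_floor, True, exp2_params)
        assert z == exp2_params.z_floor

    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_bounds_hold_along_any_outcome_stream(self, outcomes):
        params = seqddm.EXPERIMENT2_FIT
        z = params.z_max
        for ok in outcomes:
            z = update_threshold(z, ok, params)
            assert params.z_floor <= z <= params.z_max


class TestSimulateTrial:
    def test_deterministic_given_seed(self, exp2_params):
        state = initial_state(exp2_params)
        r1, s1 = simulate_trial(state, None, 1, exp2_params,
                                np.random.default_rng(7))
        r2, s2 = simulate_trial(state, None, 1, exp2_params,
                                np.random.default_rng(7))
        assert r1 == r2 and s1 == s2

    def test_degenerate_params_reduce_to_pure_ddm(self):
        params = pure_ddm_params()
        p = ScaledDDMParams(params.mu_tilde, params.z_max)
        dtc, dte = conditional_mean_dts(p)
        er = error_rate(p)
        state = initial_state(params)
        rng = np.random.default_rng(0)
        transition = None
        stim = 1
        rts = set()
        for i in range(200):
            res, state = simulate_trial(state, transition, stim, params, rng)
            assert res.er == pytest.approx(er, rel=1e-12)
            expected_rt = params.t_nd + (dtc if res.correct else dte)
            assert res.rt == pytest.approx(expected_rt, rel=1e-12)
            rts.add(round(res.rt, 15))
            transition = "R"
        assert len(rts) <= 2  # one RT per correctness outcome

    def test_error_fraction_matches_closed_form_er(self):
        # biased-coin sampling against the analytic error probability
        params = pure_ddm_params(mu_tilde=12.0, z=0.08)
        er = error_rate(ScaledDDMParams(12.0, 0.08))
        state = initial_state(params)
        rng = np.random.default_rng(123)
        n, errors = 10_000, 0
        transition = None
        for i in range(n):
            res, _ = simulate_trial(state, transition, 1, params, rng)
            errors += not res.correct
        se = np.sqrt(er * (1 - er) / n)
        assert abs(errors / n - er) < 3 * se

    def test_response_encodes_correctness(self, exp2_params):
        state = initial_state(exp2_params)
        res, _ = simulate_trial(state, None, 2, exp2_params,
                                np.random.default_rng(1))
        assert res.response == (2 if res.correct else 1)


class TestSimulateSession:
    def test_row_count_and_determinism(self, exp2_params):
        stim = [np.random.default_rng(0).integers(1, 3, 200)]
        df1 = simulate_session(stim, exp2_params, n_passes=5, seed=9)
        df2 = simulate_session(stim, exp2_params, n_passes=5, seed=9)
        assert len(df1) == 1000
        pd.testing.assert_frame_equal(df1, df2)

    def test_empty_sequence_rejected(self, exp2_params):
        with pytest.raises(ValueError):
            simulate_session([], exp2_params, seed=0)
        with pytest.raises(ValueError):
            simulate_session([np.array([])], exp2_params, seed=0)

    def test_extra_passes_extend_without_reshuffling(self, exp2_params):
        stim = [np.random.default_rng(1).integers(1, 3, 120)] * 2
        short = simulate_session(stim, exp2_params, n_passes=2, seed=4)
        long = simulate_session(stim, exp2_params, n_passes=4, seed=4)
        pd.testing.assert_frame_equal(short, long.iloc[:len(short)]
                                      .reset_index(drop=True))

    def test_state_resets_at_block_boundaries(self, exp2_params):
        stim = [np.full(50, 1), np.full(50, 2)]
        df = simulate_session(stim, exp2_params, seed=2)
        firsts = df[df["trial"] == 1]
        assert (firsts["z"] == exp2_params.z_max).all()
        assert (firsts["memory"] == 0.5).all()
        assert firsts["transition"].isna().all()

    def test_first_two_trials_memory_held_and_offset_only(self, exp2_params):
        stim = [np.array([1, 1, 1, 1, 1])]
        df = simulate_session(stim, exp2_params, seed=3)
        assert df.loc[0, "x0"] == 0.0
        assert df.loc[1, "x0"] == pytest.approx(exp2_params.x_offset)
        assert df.loc[2, "x0"] == pytest.approx(exp2_params.x_offset)
        # from trial 4 the repetition memory has accumulated
        assert df.loc[3, "x0"] > exp2_params.x_offset

    def test_matches_step_by_step_reference(self, exp2_params):
        # the compiled session kernel against the pure-python trial loop,
        # replaying the identical uniform stream
        blocks = [np.random.default_rng(5).integers(1, 3, 40),
                  np.random.default_rng(6).integers(1, 3, 40)]
        df = simulate_session(blocks, exp2_params, n_passes=1, seed=17)
        rows = []
        for ib, stim in enumerate(blocks, start=1):
            rng = np.random.default_rng(np.random.SeedSequence([17, 1, ib]))
            state = initial_state(exp2_params)
            prev = None
            for s in stim:
                t = None if prev is None else ("R" if s == prev else "A")
                res, state = simulate_trial(state, t, int(s), exp2_params, rng)
                rows.append(res)
                prev = s
        assert np.allclose(df["rt"], [r.rt for r in rows])
        assert (df["correct"].to_numpy() ==
                [r.correct for r in rows]).all()
        assert np.allclose(df["x0"], [r.x0 for r in rows])
        assert np.allclose(df["z"], [r.z for r in rows])

    def test_priming_symmetry_under_transition_relabeling(self):
        # with no fixed bias, exchanging repetitions and alternations leaves
        # the (correctness, RT) stream invariant
        params = AdaptiveModelParams(mu_tilde=19.0, t_nd=0.3, k=0.12,
                                     x_offset=0.0, delta=0.7, z_down=0.003,
                                     z_up=0.16, z_max=0.2)
        rng = np.random.default_rng(8)
        stim = rng.integers(1, 3, 300)
        # flipped sequence: repetition wherever the original alternated
        flipped = np.empty_like(stim)
        flipped[0] = stim[0]
        for i in range(1, len(stim)):
            was_rep = stim[i] == stim[i - 1]
            flipped[i] = (3 - flipped[i - 1]) if was_rep else flipped[i - 1]
        a = simulate_session([stim], params, seed=21)
        b = simulate_session([flipped], params, seed=21)
        assert np.allclose(a["rt"], b["rt"])
        assert (a["correct"].to_numpy() == b["correct"].to_numpy()).all()

    def test_all_repetitions_speed_up_with_memory(self):
        # priming only: constant stimuli drive the memory toward 1 and the
        # primed starting point makes correct responses faster than trial 3's
        params = AdaptiveModelParams(mu_tilde=19.0, t_nd=0.3, k=0.12,
                                     x_offset=0.003, delta=0.7, z_down=0.0,
                                     z_up=0.0, z_max=0.2)
        df = simulate_session([np.full(60, 1)], params, seed=13)
        assert df["memory"].iloc[-1] > 0.95
        corr = df[df["correct"]]
        late = corr[corr["trial"] >= 20]["rt"].mean()
        assert late < corr[corr["trial"] == 3]["rt"].iloc[0]

    def test_carry_state_across_blocks_option(self, exp2_params):
        stim = [np.full(30, 1), np.full(30, 2)]
        carried = simulate_session(stim, exp2_params, seed=2,
                                   reset_per_block=False)
        # second block starts with the carried threshold, not the ceiling
        second = carried[carried["block"] == 2]
        assert second["z"].iloc[0] != exp2_params.z_max
        assert second["transition"].iloc[0] is not None

    def test_prepared_session_replay_is_consistent(self, exp2_params):
        stim = [np.random.default_rng(2).integers(1, 3, 100)]
        prep = prepare_session(stim, n_passes=3, seed=6, p_alt=0.5)
        sim = run_prepared_session(prep, exp2_params)
        df = simulate_session(stim, exp2_params, n_passes=3, seed=6,
                              p_alt=0.5)
        assert np.allclose(sim["rt"], df["rt"])
        assert (sim["correct"] == df["correct"].to_numpy()).all()
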