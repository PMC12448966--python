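"""Adaptive session engine: scheduling, φ re-estimation, bookkeeping."""

import math
from dataclasses import replace

import numpy as np
import pytest

from sofnet.cohort import SimulatedLearner
from sofnet.memory import EncodingHistory, ModelParams, activation, encode
from sofnet.phenotype import compute_sof
from sofnet.task import (
    SchedulerConfig,
    SchedulerState,
    TrialRecord,
    next_trial,
    run_session,
    update_phi,
)


class FixedResponder:
    """Always-correct responder with a constant latency."""

    def __init__(self, rt=0.5):
        self.rt = rt

    def respond(self, item, kind, onset):
        return True, self.rt

    def on_encode(self, item, t):
        pass


def make_state(config=SchedulerConfig(), n=5):
    return SchedulerState.fresh([f"item{i:02d}" for i in range(n)], config)


class TestTrialRecord:
    def test_rejects_bad_kind_and_rt(self):
        with pytest.raises(ValueError):
            TrialRecord("p", "i", 0.0, "quiz", True, 1.0)
        with pytest.raises(ValueError):
            TrialRecord("p", "i", 0.0, "test", True, 0.0)


class TestNextTrial:
    def test_fresh_state_introduces_first_item(self):
        item, kind = next_trial(make_state(), SchedulerConfig())
        assert (item, kind) == ("item00", "study")

    def test_forgotten_item_is_retested(self):
        config = SchedulerConfig()
        state = make_state(config)
        state.histories["item00"] = encode(state.histories["item00"], 0.0, 0.3)
        state.introduced.append("item00")
        state.clock = 300.0
        # A(315 s) ≈ −0.3·ln 315 ≈ −1.73 < −0.8 ⇒ test despite unseen items
        assert activation(state.histories["item00"], 315.0) < config.activation_threshold
        assert next_trial(state, config) == ("item00", "test")

    def test_fresh_items_take_precedence_over_active_memories(self):
        config = SchedulerConfig()
        state = make_state(config)
        state.histories["item00"] = encode(state.histories["item00"], 0.0, 0.3)
        state.introduced.append("item00")
        state.clock = 0.5  # A(15.5 s) ≈ −0.82... pick a closer clock
        state.clock = 0.0
        state.histories["item00"] = encode(
            state.histories["item00"], 1.0, 0.3
        )
        state.clock = 2.0
        # two recent traces keep A above threshold ⇒ introduce a new item
        assert next_trial(state, config)[1] == "study"

    def test_exhausted_pool_falls_back_to_lowest_activation(self):
        config = SchedulerConfig(n_items=2)
        state = make_state(config, n=2)
        for i, item in enumerate(state.items):
            state.histories[item] = encode(state.histories[item], float(i), 0.3)
            state.introduced.append(item)
        state.clock = 2.0
        item, kind = next_trial(state, config)
        assert kind == "test"
        assert item == "item00"  # older trace ⇒ lower activation

    def test_empty_pool_rejected(self):
        state = SchedulerState.fresh([], SchedulerConfig())
        with pytest.raises(ValueError):
            next_trial(state, SchedulerConfig())


class TestUpdatePhi:
    def test_no_test_trials_returns_current(self):
        assert update_phi([0.0], [], 0.33) == 0.33

    def test_noise_free_recovery_within_grid_step(self):
        """Latencies generated from the model at φ=0.35 re-fit to 0.35."""
        phi_true = 0.35
        config = SchedulerConfig()
        params = ModelParams()
        h = EncodingHistory("x")
        for t in (0.0, 12.0, 40.0):
            h = encode(h, t, phi_true, params)
        trials = []
        for onset in (11.0, 39.0, 90.0):
            mask = h.times < onset
            a = float(np.log(np.sum((onset - h.times[mask]) ** (-h.decays[mask]))))
            trials.append(
                TrialRecord("p", "x", onset, "test", True, params.t0 + math.exp(-a))
            )
        rec = update_phi(h.times.tolist(), trials, 0.3, params, config)
        assert rec == pytest.approx(phi_true, abs=config.phi_step + 1e-9)

    def test_single_incorrect_pushes_phi_up_under_cap_policy(self):
        config = replace(SchedulerConfig(), error_rt_policy="cap")
        trial = TrialRecord("p", "x", 30.0, "test", False, 2.0)
        rec = update_phi([0.0], [trial], 0.3, config=config)
        assert rec >= 0.3

    def test_zero_residual_keeps_incumbent(self):
        """Observed latencies exactly matching the incumbent φ's predictions
        leave φ unchanged (ties break toward smaller values)."""
        phi = 0.3
        config = SchedulerConfig()
        params = ModelParams()
        times = [0.0, 10.0]
        h = EncodingHistory("x")
        for t in times:
            h = encode(h, t, phi, params)
        onset = 25.0
        a = float(np.log(np.sum((onset - h.times) ** (-h.decays))))
        trial = TrialRecord("p", "x", onset, "test", True, params.t0 + math.exp(-a))
        assert update_phi(times, [trial], phi, params, config) == pytest.approx(phi)


class TestRunSession:
    def test_zero_length_session_is_empty(self):
        config = replace(SchedulerConfig(), session_length=0.0)
        log, state = run_session(FixedResponder(), config=config)
        assert log == []
        assert state.clock == 0.0

    def test_deterministic_correct_responder_bookkeeping(self):
        config = replace(SchedulerConfig(), session_length=120.0)
        log, state = run_session(FixedResponder(rt=0.5), config=config)
        assert all(t.correct for t in log)
        assert len(state.introduced) <= config.n_items
        onsets = [t.onset for t in log]
        assert onsets == sorted(onsets)
        assert all(b > a for a, b in zip(onsets, onsets[1:]))

    def test_never_tests_unstudied_item(self):
        config = replace(SchedulerConfig(), session_length=300.0)
        learner = SimulatedLearner(0.32, rng=3)
        log, _ = run_session(learner, config=config)
        studied = set()
        for t in log:
            if t.kind == "test":
                assert t.item in studied
            studied.add(t.item)

    def test_clock_bounded_by_session_budget(self):
        config = replace(SchedulerConfig(), session_length=200.0)
        log, state = run_session(SimulatedLearner(0.3, rng=1), config=config)
        last = log[-1]
        slack = last.rt + max(config.isi_correct, config.feedback_duration)
        assert state.clock <= config.session_length + slack

    def test_trial_count_in_observed_envelope(self):
        """A φ=0.305 learner fills a 12-minute session with a trial count
        inside the empirically observed 91–221 range."""
        log, _ = run_session(SimulatedLearner(0.305, rng=7))
        assert 91 <= len(log) <= 221

    def test_incorrect_reencoding_toggle_preserves_time_order(self):
        for toggle in (True, False):
            config = replace(
                SchedulerConfig(), session_length=150.0,
                reencode_on_incorrect=toggle,
            )
            _, state = run_session(SimulatedLearner(0.38, rng=5), config=config)
            for h in state.histories.values():
                times = h.times
                assert np.all(np.diff(times) > 0)

    def test_phi_estimates_stay_in_bounds(self):
        config = replace(SchedulerConfig(), session_length=300.0)
        _, state = run_session(SimulatedLearner(0.35, rng=11), config=config)
        for phi in state.phi.values():
            assert config.phi_min <= phi <= config.phi_max
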