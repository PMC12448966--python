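"""Adaptive paired-associate learning session engine.

The scheduler interleaves study and test trials over a pool of cue–target
items (25 vocabulary pairs in the reference design) for a fixed session
budget (12 minutes).  Items are re-tested just before the memory model
predicts they would be forgotten: at each step the engine looks a few seconds
ahead, and the introduced item whose predicted activation falls lowest below
a threshold is probed.  After every test response the item's decay intercept
φ is re-estimated from the full response record, so the schedule adapts to
the learner.

The φ estimator is a deterministic grid re-fit: candidate intercepts on
[0.10, 0.60] in steps of 0.001 are scored by the squared error between
observed response times (clamped at ``rt_cap``; an error counts as ``rt_cap``)
and the latencies the model predicts when the item's whole trace cascade is
rebuilt under that candidate.  Slow or incorrect answers therefore push φ up
and fast answers pull it down, with ties resolved toward the smaller φ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Protocol, Sequence

import numpy as np

from .memory import (
    EncodingHistory,
    ModelParams,
    activation,
    decay_rates_for_phi,
    encode,
)

__all__ = [
    "TrialRecord",
    "SchedulerConfig",
    "SchedulerState",
    "Responder",
    "next_trial",
    "update_phi",
    "run_session",
]

TrialKind = Literal["study", "test"]

#: Minimum spacing (s) between successive traces of one item; encodings
#: closer than this merge into the preceding trace.
TRACE_REFRACTORY = 0.25


@dataclass(frozen=True)
class TrialRecord:
    """One task event: who saw which item when, and how they responded."""

    participant: str
    item: str
    onset: float  # seconds since session start
    kind: TrialKind
    correct: bool
    rt: float  # first-keypress latency, seconds

    def __post_init__(self) -> None:
        if self.kind not in ("study", "test"):
            raise ValueError(f"kind must be 'study' or 'test', got {self.kind!r}")
        if not self.rt > 0:
            raise ValueError(f"rt must be > 0, got {self.rt}")


@dataclass(frozen=True)
class SchedulerConfig:
    """Tunable parameters of the adaptive session.

    ``n_items``, ``session_length``, ``isi_correct`` and ``rt_cap`` follow the
    reference task design; ``activation_threshold`` and ``lookahead`` are
    scheduling internals chosen so that a learner with φ ≈ 0.3 revisits items
    on an expanding schedule that fills a 12-minute session with roughly 140
    trials.  ``feedback_duration`` fixes the (participant-paced in the lab)
    corrective-feedback interval so simulated clocks are deterministic.
    """

    n_items: int = 25
    session_length: float = 720.0
    isi_correct: float = 0.6
    feedback_duration: float = 4.0
    activation_threshold: float = -0.8
    lookahead: float = 15.0
    phi_init: float = 0.3
    rt_cap: float = 8.0
    phi_min: float = 0.10
    phi_max: float = 0.60
    phi_step: float = 0.001
    reencode_on_incorrect: bool = True
    #: How an incorrect test trial enters the latency re-fit: "observed"
    #: scores its actual first-keypress latency (clamped at rt_cap);
    #: "cap" scores it as the rt_cap ceiling regardless of latency.
    error_rt_policy: Literal["observed", "cap"] = "observed"

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        for name in ("isi_correct", "feedback_duration", "lookahead", "rt_cap",
                     "phi_step"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.session_length < 0:
            raise ValueError("session_length must be >= 0")
        if not self.phi_min < self.phi_max:
            raise ValueError("phi_min must be < phi_max")

    @property
    def phi_grid(self) -> np.ndarray:
        n = int(round((self.phi_max - self.phi_min) / self.phi_step)) + 1
        # rounding keeps grid points exact at the printed precision, so an
        # incumbent φ that sits on the grid is reproduced bit-for-bit
        return np.round(np.linspace(self.phi_min, self.phi_max, n), 9)


@dataclass
class SchedulerState:
    """Mutable session bookkeeping: per-item histories, φ estimates, clock."""

    items: list[str]
    histories: dict[str, EncodingHistory] = field(default_factory=dict)
    phi: dict[str, float] = field(default_factory=dict)
    introduced: list[str] = field(default_factory=list)
    test_trials: dict[str, list[TrialRecord]] = field(default_factory=dict)
    clock: float = 0.0

    @classmethod
    def fresh(cls, items: Sequence[str], config: SchedulerConfig) -> "SchedulerState":
        items = list(items)
        return cls(
            items=items,
            histories={it: EncodingHistory(it) for it in items},
            phi={it: config.phi_init for it in items},
            test_trials={it: [] for it in items},
        )


class Responder(Protocol):
    """Behavior source for a simulated (or replayed) participant.

    ``respond`` is called at each trial onset and returns the response;
    ``on_encode`` notifies the responder that a memory trace was laid down for
    ``item`` at session time ``t`` (study, correct retrieval, or re-study
    during corrective feedback), letting model-based responders track their
    own ground-truth activation.
    """

    def respond(self, item: str, kind: TrialKind, onset: float) -> tuple[bool, float]:
        ...

    def on_encode(self, item: str, t: float) -> None:
        ...


def next_trial(
    state: SchedulerState,
    config: SchedulerConfig,
    params: ModelParams = ModelParams(),
) -> tuple[str, TrialKind]:
    """Choose the next item and trial type.

    The introduced item with the lowest predicted activation at
    ``clock + lookahead`` is tested if that activation is below the threshold;
    otherwise a new item is introduced as a study trial; once the pool is
    exhausted the lowest-activation item is tested regardless of threshold.
    """
    if not state.items:
        raise ValueError("empty item pool")
    t_probe = state.clock + config.lookahead
    scored = [
        (activation(state.histories[it], t_probe), it)
        for it in state.introduced
        if len(state.histories[it]) > 0
    ]
    if scored:
        a_min, item_min = min(scored)
        if a_min < config.activation_threshold:
            return item_min, "test"
    remaining = [it for it in state.items if it not in state.introduced]
    if remaining:
        return remaining[0], "study"
    if not scored:  # pool exists but nothing ever encoded: introduce anew
        return state.items[0], "study"
    return item_min, "test"


def update_phi(
    trace_times: Sequence[float],
    test_trials: Sequence[TrialRecord],
    current_phi: float,
    params: ModelParams = ModelParams(),
    config: SchedulerConfig = SchedulerConfig(),
) -> float:
    """Re-estimate an item's decay intercept from its test-trial record.

    For every candidate φ on the grid, the item's trace decay cascade is
    rebuilt from ``trace_times`` and each test trial's latency is predicted at
    its onset from the traces that precede it; the candidate minimizing the
    summed squared latency error is returned.  Observed latencies are clamped
    at ``rt_cap``; incorrect responses enter per ``config.error_rt_policy``
    (their observed latency by default, or the ``rt_cap`` ceiling).  With no
    test trials the current φ is returned unchanged.
    """
    trials = [tr for tr in test_trials if tr.kind == "test"]
    if not trials:
        return current_phi
    times = np.asarray(sorted(trace_times), dtype=float)
    grid = config.phi_grid
    d = decay_rates_for_phi(times, grid, params)  # (n_grid, n_traces)
    sse = np.zeros(len(grid))
    any_scored = False
    for tr in trials:
        mask = times < tr.onset
        if not mask.any():
            continue  # test before any encoding carries no latency information
        lags = tr.onset - times[mask]
        strength = np.sum(lags[None, :] ** (-d[:, mask]), axis=1)
        pred = params.t0 + params.F / strength  # t0 + F·exp(−A)
        if tr.correct or config.error_rt_policy == "observed":
            obs = min(tr.rt, config.rt_cap)
        else:
            obs = config.rt_cap
        sse += (obs - np.minimum(pred, config.rt_cap)) ** 2
        any_scored = True
    if not any_scored:
        return current_phi
    return float(grid[int(np.argmin(sse))])  # first minimum = smallest φ


def run_session(
    responder: Responder | Callable[[str, TrialKind, float], tuple[bool, float]],
    config: SchedulerConfig = SchedulerConfig(),
    params: ModelParams = ModelParams(),
    participant: str = "p00",
    items: Sequence[str] | None = None,
) -> tuple[list[TrialRecord], SchedulerState]:
    """Run one adaptive session against a responder; return its trial log.

    The session clock advances by ``rt + isi_correct`` after a correct
    response and by ``rt + feedback_duration`` after an incorrect one.  A
    trace is encoded at trial onset after every study trial and correct test
    trial; after an incorrect test trial a trace is encoded at feedback offset
    (re-study during corrective feedback), unless ``reencode_on_incorrect`` is
    off.  Every test response triggers a φ re-fit for its item.
    """
    if items is None:
        items = [f"item{i:02d}" for i in range(config.n_items)]
    respond = responder.respond if hasattr(responder, "respond") else responder
    notify = getattr(responder, "on_encode", lambda item, t: None)
    state = SchedulerState.fresh(items, config)
    log: list[TrialRecord] = []

    def lay_trace(item: str, t: float) -> None:
        # back-to-back events on one item (e.g. a correct retest at the exact
        # feedback offset) do not form distinct traces: sub-second lags would
        # make the power-law strength, and hence the next decay rate, explode
        if t - state.histories[item].last_time < TRACE_REFRACTORY:
            return
        state.histories[item] = encode(
            state.histories[item], t, state.phi[item], params
        )
        notify(item, t)

    while state.clock < config.session_length:
        item, kind = next_trial(state, config, params)
        onset = state.clock
        correct, rt = respond(item, kind, onset)
        if not rt > 0:
            raise ValueError(f"responder returned non-positive rt {rt}")
        if kind == "study":
            correct = True
        log.append(TrialRecord(participant, item, onset, kind, correct, rt))
        if item not in state.introduced:
            state.introduced.append(item)
        if correct:
            lay_trace(item, onset)
            state.clock = onset + rt + config.isi_correct
        else:
            state.clock = onset + rt + config.feedback_duration
            if config.reencode_on_incorrect:
                lay_trace(item, state.clock)
        if kind == "test":
            state.test_trials[item].append(log[-1])
            state.phi[item] = update_phi(
                [e.time for e in state.histories[item]],
                state.test_trials[item],
                state.phi[item],
                params,
                config,
            )
    return log, state
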