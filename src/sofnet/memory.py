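"""Trace-decay model of declarative memory.

Each studied item leaves a sequence of episodic traces; trace *i*, created at
time ``t_i``, decays as the power law ``(t - t_i)^(-d_i)``.  The activation of
the item is the log of the summed trace strengths,

    A(m, t) = log Σ_i (t - t_i)^(-d_i),

and the decay rate of a new trace depends on the activation at the moment of
its creation,

    d_i = c · exp(A(m, t_i)) + φ,

so that items rehearsed while still highly active decay faster (spacing
effect).  φ — the decay intercept — is the only free parameter and is the
*speed of forgetting* (SoF) when averaged over an individual's items.
Retrieval probability is the logistic of activation, and response latency is
``t0 + F·exp(-A)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "ModelParams",
    "EncodingHistory",
    "NoTraceError",
    "PHI_MIN",
    "PHI_MAX",
    "activation",
    "decay_rate",
    "encode",
    "retrieval_probability",
    "predicted_rt",
    "forgetting_curve",
    "decay_rates_for_phi",
]

#: Default admissible range for the decay intercept φ.  Chosen to bracket the
#: empirically observed adult range (~0.25–0.39) with margin while keeping the
#: activation sum numerically tame.
PHI_MIN = 0.10
PHI_MAX = 0.60


class NoTraceError(ValueError):
    """Raised when activation is requested for a never-encoded item."""


@dataclass(frozen=True)
class ModelParams:
    """Fixed (non-fitted) parameters of the memory model.

    Parameters
    ----------
    c : float
        Scaling of the activation-dependent part of the decay rate
        (dimensionless, default 0.25).
    t0 : float
        Non-memory latency offset in seconds — perceptual encoding plus motor
        response (default 0.3 s).
    F : float
        Latency scale factor (dimensionless, default 1.0).
    """

    c: float = 0.25
    t0: float = 0.3
    F: float = 1.0

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be >= 0, got {self.t0}")
        if not self.F > 0:
            raise ValueError(f"F must be > 0, got {self.F}")


class Trace(NamedTuple):
    time: float  # creation time, seconds since session start
    decay: float  # decay rate d_i (> 0)


@dataclass(frozen=True)
class EncodingHistory:
    """Immutable per-item record of trace creation times and decay rates."""

    item: str = ""
    events: tuple[Trace, ...] = ()

    def __post_init__(self) -> None:
        events = tuple(e if isinstance(e, Trace) else Trace(*e) for e in self.events)
        object.__setattr__(self, "events", events)
        times = [e.time for e in events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"trace times must be strictly increasing: {times}")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[Trace]:
        return iter(self.events)

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time for e in self.events], dtype=float)

    @property
    def decays(self) -> np.ndarray:
        return np.array([e.decay for e in self.events], dtype=float)

    @property
    def last_time(self) -> float:
        return self.events[-1].time if self.events else -math.inf


def activation(history: EncodingHistory, t: float) -> float:
    """Log-summed power-law trace strength of an item at time ``t``.

    Raises :class:`NoTraceError` on an empty history (callers treat the
    activation of a never-encoded item as −∞) and ``ValueError`` if ``t`` does
    not lie strictly after every trace.
    """
    if len(history) == 0:
        raise NoTraceError(f"item {history.item!r} has no traces")
    times = history.times
    if t <= times[-1]:
        raise ValueError(f"t={t} must exceed the last trace time {times[-1]}")
    return float(np.log(np.sum((t - times) ** (-history.decays))))


def decay_rate(
    history: EncodingHistory,
    t_new: float,
    phi: float,
    params: ModelParams = ModelParams(),
) -> float:
    """Decay rate ``c·exp(A(m, t_new)) + φ`` of a trace created at ``t_new``.

    Activation is evaluated on the history *before* the new trace is added;
    for an empty history the empty-sum limit exp(−∞) = 0 gives d = φ.
    """
    if len(history) == 0:
        return phi
    if t_new <= history.last_time:
        raise ValueError(
            f"t_new={t_new} must exceed the last trace time {history.last_time}"
        )
    return params.c * math.exp(activation(history, t_new)) + phi


def encode(
    history: EncodingHistory,
    t_new: float,
    phi: float,
    params: ModelParams = ModelParams(),
) -> EncodingHistory:
    """Return a new history with a trace appended at ``t_new`` (value semantics)."""
    d = decay_rate(history, t_new, phi, params)
    return EncodingHistory(history.item, history.events + (Trace(t_new, d),))


def retrieval_probability(a: float) -> float:
    """Logistic retrieval probability 1/(1+exp(−A)); 0 at A = −∞."""
    if a == -math.inf:
        return 0.0
    if a >= 0:
        return 1.0 / (1.0 + math.exp(-a))
    # rearranged for numerical stability at very negative A
    ea = math.exp(a)
    return ea / (1.0 + ea)


def predicted_rt(a: float, params: ModelParams = ModelParams()) -> float:
    """Model response latency ``t0 + F·exp(−A)`` in seconds."""
    return params.t0 + params.F * math.exp(-a)


def forgetting_curve(
    phi: float,
    horizon: float,
    step: float,
    params: ModelParams = ModelParams(),
    t_encode: float = 0.0,
) -> np.ndarray:
    """Activation/retrieval time-course of a single unrehearsed encoding.

    Returns a structured array with fields ``t``, ``A``, ``P`` sampled at
    ``t_encode + step, ..., t_encode + horizon``.  The first trace of an item
    has decay rate d = φ, so A(t) = −φ·log(t − t_encode).
    """
    if not horizon > step > 0:
        raise ValueError("require horizon > step > 0")
    hist = encode(EncodingHistory("probe"), t_encode, phi, params)
    ts = np.arange(t_encode + step, t_encode + horizon + step / 2, step)
    out = np.zeros(len(ts), dtype=[("t", float), ("A", float), ("P", float)])
    for i, t in enumerate(ts):
        a = activation(hist, float(t))
        out[i] = (t, a, retrieval_probability(a))
    return out


def decay_rates_for_phi(
    times: Sequence[float] | np.ndarray,
    phis: np.ndarray,
    params: ModelParams = ModelParams(),
) -> np.ndarray:
    """Trace decay rates under each candidate φ, vectorized over candidates.

    Rebuilds the decay sequence d_1 = φ, d_i = c·exp(A(t_i)) + φ for every φ in
    ``phis`` simultaneously.  Returns an array of shape ``(len(phis),
    len(times))``.  This is the workhorse of the grid re-fit φ estimator, where
    the whole trace cascade must be recomputed for ~500 candidate intercepts.
    """
    times = np.asarray(times, dtype=float)
    phis = np.asarray(phis, dtype=float)
    n = len(times)
    d = np.empty((len(phis), n), dtype=float)
    if n == 0:
        return d
    d[:, 0] = phis
    for i in range(1, n):
        lags = times[i] - times[:i]  # strictly positive by construction
        strength = np.sum(lags[None, :] ** (-d[:, :i]), axis=1)
        d[:, i] = params.c * strength + phis
    return d
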