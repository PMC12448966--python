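"""Participant-level speed of forgetting and model-fit diagnostics.

A participant's speed of forgetting (SoF) is the unweighted mean of the final
per-item decay intercepts φ, restricted to items presented at least three
times.  Model fit is assessed by replaying each session under the
participant-level SoF, predicting every test trial's latency, and comparing
binned observed vs. predicted response-time distributions with a KL
divergence (in bits) and a χ² test, after discarding latencies above 8 s as
outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .memory import EncodingHistory, ModelParams, encode, predicted_rt
from .task import SchedulerConfig, TrialRecord

__all__ = [
    "Phenotype",
    "RtHistogram",
    "InsufficientDataError",
    "compute_sof",
    "replay_encodings",
    "predicted_rts",
    "filter_outliers",
    "rt_histogram",
    "kl_divergence",
    "chi_square_fit",
    "accuracy_diagnostics",
]

RT_CAP = 8.0
N_BINS = 10
BIN_WIDTH = 0.8


class InsufficientDataError(ValueError):
    """No item reached the minimum presentation count."""


@dataclass(frozen=True)
class Phenotype:
    participant: str
    per_item_phi: dict[str, float]
    sof: float
    n_items_used: int


@dataclass(frozen=True)
class RtHistogram:
    """Counts of response times over ten 800-ms bins spanning 0–8 s."""

    counts: np.ndarray
    bin_edges: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, RT_CAP, N_BINS + 1)
    )

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts must have one entry per bin")
        if np.any(np.asarray(self.counts) < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.sum(self.counts))


def compute_sof(
    trials: Sequence[TrialRecord],
    final_phis: Mapping[str, float],
    min_presentations: int = 3,
) -> Phenotype:
    """Aggregate per-item φ into the participant SoF.

    Items presented (study + test) at least ``min_presentations`` times
    contribute their final φ; the SoF is their unweighted mean.
    """
    participants = {t.participant for t in trials}
    if len(participants) > 1:
        raise ValueError(f"trials span multiple participants: {participants}")
    counts: dict[str, int] = {}
    for t in trials:
        counts[t.item] = counts.get(t.item, 0) + 1
    used = {
        it: final_phis[it]
        for it, n in counts.items()
        if n >= min_presentations and it in final_phis
    }
    if not used:
        raise InsufficientDataError(
            f"no item reached {min_presentations} presentations"
        )
    return Phenotype(
        participant=participants.pop() if participants else "",
        per_item_phi=used,
        sof=float(np.mean(list(used.values()))),
        n_items_used=len(used),
    )


def replay_encodings(
    trials: Sequence[TrialRecord],
    phi: float,
    params: ModelParams = ModelParams(),
    config: SchedulerConfig = SchedulerConfig(),
) -> dict[str, EncodingHistory]:
    """Rebuild per-item trace histories from a trial log under a single φ.

    Mirrors the session engine's re-encoding policy: a trace at onset for
    study and correct test trials, and one at feedback offset for incorrect
    test trials (when enabled).
    """
    hists: dict[str, EncodingHistory] = {}
    for t in trials:
        h = hists.get(t.item, EncodingHistory(t.item))
        if t.correct:
            hists[t.item] = encode(h, t.onset, phi, params)
        elif config.reencode_on_incorrect:
            hists[t.item] = encode(
                h, t.onset + t.rt + config.feedback_duration, phi, params
            )
    return hists


def _test_activations(
    trials: Sequence[TrialRecord],
    sof: float,
    params: ModelParams,
    config: SchedulerConfig,
) -> list[tuple[TrialRecord, float]]:
    """Activation at onset of every test trial, with all decay rates rebuilt
    under the participant-level SoF."""
    out: list[tuple[TrialRecord, float]] = []
    hists: dict[str, EncodingHistory] = {}
    for t in sorted(trials, key=lambda r: r.onset):
        if t.kind == "test":
            h = hists.get(t.item)
            if h is None or len(h) == 0:
                raise ValueError(
                    f"test trial for {t.item!r} at {t.onset} precedes any study"
                )
            times, decays = h.times, h.decays
            a = float(np.log(np.sum((t.onset - times) ** (-decays))))
            out.append((t, a))
        h = hists.get(t.item, EncodingHistory(t.item))
        if t.correct:
            hists[t.item] = encode(h, t.onset, sof, params)
        elif config.reencode_on_incorrect:
            hists[t.item] = encode(
                h, t.onset + t.rt + config.feedback_duration, sof, params
            )
    return out


def predicted_rts(
    trials: Sequence[TrialRecord],
    phenotype: Phenotype,
    params: ModelParams = ModelParams(),
    config: SchedulerConfig = SchedulerConfig(),
) -> list[tuple[TrialRecord, float]]:
    """Model latency for every test trial under the participant-level SoF."""
    return [
        (t, predicted_rt(a, params))
        for t, a in _test_activations(trials, phenotype.sof, params, config)
    ]


def filter_outliers(rts: Sequence[float], cap: float = RT_CAP) -> list[float]:
    """Drop response times strictly greater than ``cap`` seconds."""
    return [rt for rt in rts if rt <= cap]


def rt_histogram(rts: Sequence[float], cap: float = RT_CAP) -> RtHistogram:
    """Bin retained response times into ten 800-ms bins on [0, 8] s."""
    edges = np.linspace(0.0, cap, N_BINS + 1)
    counts, _ = np.histogram(filter_outliers(rts, cap), bins=edges)
    return RtHistogram(counts=counts, bin_edges=edges)


def _check_edges(observed: RtHistogram, predicted: RtHistogram) -> None:
    if not np.allclose(observed.bin_edges, predicted.bin_edges):
        raise ValueError("histograms have mismatched bin edges")


def kl_divergence(
    observed: RtHistogram,
    predicted: RtHistogram,
    pseudocount: float = 0.5,
) -> float:
    """KL(observed ‖ predicted) over bin proportions, in bits.

    Interpretable as the mean number of bits lost when observed response
    times are replaced by the model's predictions.  An additive pseudocount
    (default 0.5 per bin, on both histograms) keeps the divergence finite on
    empty bins; pass 0 to disable.
    """
    _check_edges(observed, predicted)
    p = np.asarray(observed.counts, dtype=float) + pseudocount
    q = np.asarray(predicted.counts, dtype=float) + pseudocount
    p, q = p / p.sum(), q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def chi_square_fit(
    observed: RtHistogram,
    predicted: RtHistogram,
    min_expected: float = 1.0,
) -> tuple[float, int, float]:
    """Pearson χ² of observed counts against model-predicted proportions.

    Expected counts are the predicted proportions scaled to the observed
    total; adjacent bins are merged until every expected count is at least
    ``min_expected``.  Returns (statistic, dof, p) with dof = bins − 1.
    """
    _check_edges(observed, predicted)
    o = np.asarray(observed.counts, dtype=float)
    e = np.asarray(predicted.counts, dtype=float)
    if e.sum() <= 0:
        raise ValueError("predicted histogram is empty")
    e = e / e.sum() * o.sum()

    merged_o, merged_e = [], []
    acc_o = acc_e = 0.0
    for oi, ei in zip(o, e):
        acc_o, acc_e = acc_o + oi, acc_e + ei
        if acc_e >= min_expected:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 or acc_o > 0:  # fold the trailing remainder into the last bin
        if merged_e:
            merged_o[-1] += acc_o
            merged_e[-1] += acc_e
        else:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
    if len(merged_e) < 2:
        raise ValueError("fewer than 2 bins with adequate expected counts")
    o_arr, e_arr = np.asarray(merged_o), np.asarray(merged_e)
    statistic = float(np.sum((o_arr - e_arr) ** 2 / e_arr))
    dof = len(e_arr) - 1
    p = float(stats.chi2.sf(statistic, dof))
    return statistic, dof, p


def accuracy_diagnostics(
    trials: Sequence[TrialRecord],
    phenotype: Phenotype,
    params: ModelParams = ModelParams(),
    config: SchedulerConfig = SchedulerConfig(),
) -> np.ndarray:
    """2×2 confusion counts of predicted vs. observed test-trial accuracy.

    Predicted accuracy is 1 when retrieval probability exceeds 0.5 (A > 0)
    and 0 otherwise, with the boundary P = 0.5 assigned to "incorrect".
    Rows index the predicted label (0, 1); columns the observed label.
    """
    table = np.zeros((2, 2), dtype=int)
    for t, a in _test_activations(trials, phenotype.sof, params, config):
        pred = 1 if a > 0 else 0
        obs = 1 if t.correct else 0
        table[pred, obs] += 1
    return table
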