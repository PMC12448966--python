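"""Speed-of-forgetting aggregation and response-time fit diagnostics."""

import math

import numpy as np
import pytest

from sofnet.memory import ModelParams
from sofnet.phenotype import (
    InsufficientDataError,
    Phenotype,
    RtHistogram,
    accuracy_diagnostics,
    chi_square_fit,
    compute_sof,
    filter_outliers,
    kl_divergence,
    predicted_rts,
    rt_histogram,
)
from sofnet.task import TrialRecord


def trials_for(item, n, kind="study", participant="p", start=0.0):
    return [
        TrialRecord(participant, item, start + 10.0 * i, kind, True, 1.0)
        for i in range(n)
    ]


class TestComputeSof:
    def test_mean_of_qualifying_items(self):
        trials = trials_for("a", 5) + trials_for("b", 5, start=1.0)
        ph = compute_sof(trials, {"a": 0.28, "b": 0.32})
        assert ph.sof == pytest.approx(0.30)
        assert ph.n_items_used == 2

    def test_underexposed_item_excluded(self):
        trials = trials_for("a", 5) + trials_for("b", 2, start=1.0)
        ph = compute_sof(trials, {"a": 0.28, "b": 0.60})
        assert ph.sof == pytest.approx(0.28)
        assert "b" not in ph.per_item_phi

    def test_uniform_phi_gives_that_value(self):
        trials = trials_for("a", 3) + trials_for("b", 4, start=1.0)
        ph = compute_sof(trials, {"a": 0.305, "b": 0.305})
        assert ph.sof == pytest.approx(0.305)

    def test_no_qualifying_item_raises(self):
        with pytest.raises(InsufficientDataError):
            compute_sof(trials_for("a", 2), {"a": 0.3})

    def test_mixed_participants_rejected(self):
        trials = trials_for("a", 3, participant="p1") + trials_for(
            "a", 3, participant="p2", start=1.0
        )
        with pytest.raises(ValueError):
            compute_sof(trials, {"a": 0.3})


class TestPredictedRts:
    def test_single_study_then_test(self):
        """Test 10 s after one study at SoF 0.3: A = −0.3·ln10, T ≈ 2.30 s."""
        trials = [
            TrialRecord("p", "a", 0.0, "study", True, 1.0),
            TrialRecord("p", "a", 10.0, "test", True, 1.5),
        ]
        ph = Phenotype("p", {"a": 0.3}, 0.3, 1)
        [(_, rt)] = predicted_rts(trials, ph)
        assert rt == pytest.approx(0.3 + math.exp(0.3 * math.log(10)), rel=1e-9)
        assert rt == pytest.approx(2.30, abs=5e-3)

    def test_unit_lag_baseline(self):
        trials = [
            TrialRecord("p", "a", 0.0, "study", True, 1.0),
            TrialRecord("p", "a", 1.0, "test", True, 1.5),
        ]
        ph = Phenotype("p", {"a": 0.3}, 0.3, 1)
        [(_, rt)] = predicted_rts(trials, ph)
        assert rt == pytest.approx(1.3)

    def test_rehearsal_speeds_up_later_test(self):
        trials = [
            TrialRecord("p", "a", 0.0, "study", True, 1.0),
            TrialRecord("p", "a", 30.0, "test", True, 1.5),
            TrialRecord("p", "a", 60.0, "test", True, 1.5),
        ]
        ph = Phenotype("p", {"a": 0.3}, 0.3, 1)
        preds = predicted_rts(trials, ph)
        # the second test, 30 s after a rehearsal with two traces behind it,
        # is predicted faster than the first test at the same 30-s lag
        assert preds[1][1] < preds[0][1]

    def test_test_before_study_rejected(self):
        trials = [TrialRecord("p", "a", 5.0, "test", True, 1.0)]
        ph = Phenotype("p", {"a": 0.3}, 0.3, 1)
        with pytest.raises(ValueError):
            predicted_rts(trials, ph)


class TestFilterOutliers:
    def test_cap_is_inclusive(self):
        assert filter_outliers([0.5, 7.9, 8.0, 8.1]) == [0.5, 7.9, 8.0]

    def test_all_within_cap_unchanged(self):
        rts = [0.4, 1.0, 7.99]
        assert filter_outliers(rts) == rts


class TestKlDivergence:
    def test_identical_histograms_zero(self):
        h = rt_histogram([0.5, 1.2, 3.3, 7.0])
        assert kl_divergence(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_vs_uniform_closed_form(self):
        """All observations in bin 1 against a uniform prediction lose
        log₂ 10 bits (no smoothing)."""
        obs = RtHistogram(counts=np.array([10] + [0] * 9))
        pred = RtHistogram(counts=np.array([5] * 10))
        assert kl_divergence(obs, pred, pseudocount=0.0) == pytest.approx(
            math.log2(10), rel=1e-12
        )

    def test_asymmetric(self):
        a = RtHistogram(counts=np.array([8, 2] + [0] * 8))
        b = RtHistogram(counts=np.array([3, 7] + [0] * 8))
        assert kl_divergence(a, b) != pytest.approx(kl_divergence(b, a))

    def test_nonnegative_and_smoothing_keeps_finite(self, rng):
        for _ in range(20):
            a = RtHistogram(counts=rng.integers(0, 20, 10))
            b = RtHistogram(counts=rng.integers(0, 20, 10))
            d = kl_divergence(a, b)
            assert np.isfinite(d) and d >= 0

    def test_mismatched_edges_rejected(self):
        a = rt_histogram([1.0])
        b = RtHistogram(counts=np.zeros(5, int), bin_edges=np.linspace(0, 5, 6))
        with pytest.raises(ValueError):
            kl_divergence(a, b)


class TestChiSquareFit:
    def test_identical_histograms(self):
        h = RtHistogram(counts=np.array([5, 9, 3, 2, 1, 1, 1, 1, 1, 1]))
        stat, dof, p = chi_square_fit(h, h)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_bin_hand_arithmetic(self):
        """O=[10,0] vs E=[5,5] gives (10−5)²/5 + (0−5)²/5 = 10."""
        edges = np.array([0.0, 4.0, 8.0])
        obs = RtHistogram(counts=np.array([10, 0]), bin_edges=edges)
        pred = RtHistogram(counts=np.array([5, 5]), bin_edges=edges)
        stat, dof, _ = chi_square_fit(obs, pred)
        assert stat == pytest.approx(10.0)
        assert dof == 1

    def test_low_expected_bins_merged(self):
        obs = RtHistogram(counts=np.array([50, 50, 0, 0, 0, 0, 0, 0, 0, 1]))
        pred = RtHistogram(counts=np.array([50, 49, 1, 0, 0, 0, 0, 0, 0, 1]))
        stat, dof, p = chi_square_fit(obs, pred)
        assert np.isfinite(stat) and dof >= 1

    def test_degenerate_prediction_rejected(self):
        obs = rt_histogram([1.0, 2.0])
        pred = RtHistogram(counts=np.zeros(10, int))
        with pytest.raises(ValueError):
            chi_square_fit(obs, pred)


class TestAccuracyDiagnostics:
    def test_boundary_activation_predicts_incorrect(self):
        # test exactly 1 s after a single study ⇒ A = 0 ⇒ P = 0.5 ⇒ label 0
        trials = [
            TrialRecord("p", "a", 0.0, "study", True, 1.0),
            TrialRecord("p", "a", 1.0, "test", True, 1.5),
        ]
        ph = Phenotype("p", {"a": 0.3}, 0.3, 1)
        table = accuracy_diagnostics(trials, ph)
        assert table[0, 1] == 1  # predicted incorrect, observed correct
        assert table.sum() == 1

    def test_counts_sum_to_test_trials(self):
        trials = [TrialRecord("p", "a", 0.0, "study", True, 1.0)]
        onset = 2.0
        for i in range(6):
            trials.append(
                TrialRecord("p", "a", onset, "test", i % 2 == 0, 1.0)
            )
            onset += 20.0
        ph = Phenotype("p", {"a": 0.3}, 0.3, 1)
        assert accuracy_diagnostics(trials, ph).sum() == 6
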