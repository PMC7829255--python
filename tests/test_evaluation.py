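"""Evaluation metrics: errors, within-level fractions, confusion, chance."""

import numpy as np
import pytest

from fuseload.evaluation import (
    bin_to_nearest_label,
    chance_accuracy,
    confusion,
    error_histogram,
    evaluate,
    mean_abs_error,
    run_ablation,
    within_fraction,
)
from fuseload.labels import individual_label_values
from fuseload.segmentation import MultimodalSample, SampleSet
from fuseload.training import TrainConfig

SEVEN = individual_label_values()
GROUP = np.array([0.0, 0.33, 0.38, 0.65, 1.0])


class TestMeanAbsError:
    def test_examples(self):
        assert mean_abs_error([0.5], [0.0]) == 0.5
        assert mean_abs_error([0.1, 0.9], [0.0, 1.0]) == pytest.approx(0.1)
        assert mean_abs_error([0.3, 0.7], [0.3, 0.7]) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_abs_error([0.1], [0.1, 0.2])


class TestWithinFraction:
    def test_examples(self):
        assert within_fraction([0.5], [0.5], 0.0) == 1.0
        # errors 0.1 and 0.2 against one level = 0.1667
        assert within_fraction([0.1, 0.2], [0.0, 0.0], 1.0) == 0.5

    def test_monotone_in_tolerance_and_saturates(self):
        rng = np.random.default_rng(0)
        p, y = rng.uniform(0, 1, 50), rng.uniform(0, 1, 50)
        fracs = [within_fraction(p, y, t) for t in (0.5, 1.0, 1.5, 6.0)]
        assert fracs == sorted(fracs)
        assert fracs[-1] == 1.0


class TestNearestLabelBinning:
    def test_seven_label_example(self):
        assert bin_to_nearest_label(0.40, SEVEN) == 2  # 0.3333 is closest

    def test_exact_label(self):
        assert bin_to_nearest_label(0.5, SEVEN) == 3

    def test_group_labels_example(self):
        assert bin_to_nearest_label(0.50, GROUP) == 2  # 0.38 beats 0.65

    def test_midpoint_tie_goes_low(self):
        assert bin_to_nearest_label(1 / 12, np.array([0.0, 1 / 6])) == 0


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        y = np.repeat(SEVEN, 3)
        counts, props, acc, off1 = confusion(y, y, SEVEN)
        assert np.all(counts == 3 * np.eye(7, dtype=int))
        assert acc == 1.0 and off1 == 1.0

    def test_two_class_hand_count(self):
        y = [0.0, 0.0, 1.0, 1.0, 1.0]
        p = [0.1, 0.9, 0.8, 0.2, 0.95]
        counts, props, acc, _ = confusion(p, y, np.array([0.0, 1.0]))
        assert counts.tolist() == [[1, 1], [1, 2]]
        assert acc == pytest.approx(3 / 5)
        np.testing.assert_allclose(props.sum(axis=1), 1.0)

    def test_trace_equals_independent_accuracy(self):
        rng = np.random.default_rng(1)
        y = rng.choice(SEVEN, 100)
        p = np.clip(y + rng.normal(0, 0.15, 100), 0, 1)
        counts, _, acc, _ = confusion(p, y, SEVEN)
        binned = np.array([bin_to_nearest_label(x, SEVEN) for x in p])
        true_i = np.array([bin_to_nearest_label(x, SEVEN) for x in y])
        assert acc == pytest.approx(np.mean(binned == true_i))
        assert counts.sum() == 100

    def test_label_not_in_values_rejected(self):
        with pytest.raises(ValueError):
            confusion([0.5], [0.41], SEVEN)


class TestChanceAccuracy:
    def test_seven_class_zero_neighbourhood(self):
        assert chance_accuracy(7, 0) == pytest.approx(100 / 7)  # prints as 14%
        assert chance_accuracy(7, 0, "exact-edge-aware") == pytest.approx(100 / 7)

    def test_five_class(self):
        assert chance_accuracy(5, 0) == pytest.approx(20.0)

    def test_off_by_one_approximation_is_three_sevenths(self):
        assert chance_accuracy(7, 1) == pytest.approx(300 / 7)  # prints as 43%

    def test_off_by_one_exact_counts_edges(self):
        # full enumeration over 7x7 outcomes: 19 of 49 pairs within one
        assert chance_accuracy(7, 1, "exact-edge-aware") == pytest.approx(100 * 19 / 49)

    def test_exact_equals_uniform_at_zero_neighbourhood(self):
        for n in (2, 5, 7, 11):
            assert chance_accuracy(n, 0, "exact-edge-aware") == pytest.approx(100 / n)


class TestErrorHistogram:
    def test_perfect_predictions(self):
        edges, counts, mu, sd = error_histogram([0.5, 0.5], [0.5, 0.5])
        assert mu == 0.0 and sd == 0.0
        assert counts.sum() == 2

    def test_constant_bias_shifts_mean(self):
        y = np.linspace(0.2, 0.8, 20)
        edges, counts, mu, sd = error_histogram(y + 0.05, y)
        assert mu == pytest.approx(0.05)
        assert counts.sum() == 20

    def test_moments_match_direct_computation(self):
        rng = np.random.default_rng(2)
        p, y = rng.uniform(0, 1, 64), rng.uniform(0, 1, 64)
        _, counts, mu, sd = error_histogram(p, y)
        assert mu == pytest.approx(np.mean(p - y))
        assert sd == pytest.approx(np.std(p - y))
        assert counts.sum() == 64


class TestEvaluateReport:
    def test_invariants(self):
        rng = np.random.default_rng(3)
        y = rng.choice(SEVEN, 80)
        p = np.clip(y + rng.normal(0, 0.2, 80), 0, 1)
        rep = evaluate(p, y, SEVEN)
        assert 0 <= rep.within_1_level <= 1
        assert rep.within_1_5_levels >= rep.within_1_level
        assert rep.confusion_counts.sum() == 80
        assert rep.hist_counts.sum() == 80
        assert rep.low == pytest.approx(rep.mean_abs_error * 6)
        assert rep.chance_accuracy_pct == pytest.approx(100 / 7)


class TestAblation:
    TINY_SHAPES = {"GSR": (32, 1), "fNIRS": (8, 54)}

    def _set(self, n=24, seed=0):
        rng = np.random.default_rng(seed)
        samples = []
        for _ in range(n):
            label = float(rng.uniform(0, 1))
            samples.append(MultimodalSample(
                windows={"PPG": label + 0.05 * rng.normal(size=(2048, 1)),
                         "GSR": label + 0.05 * rng.normal(size=(2048, 1)),
                         "ET": rng.normal(size=(960, 4)),
                         "fNIRS": rng.normal(size=(80, 54))},
                label=label, participant_id="p", puzzle_id=0, marker_time=9.0))
        return SampleSet(samples=samples)

    def test_row_bookkeeping_and_reference_inclusion(self):
        ss = self._set()
        cfg = TrainConfig(epochs_per_fold=1, seed=0)
        rep = run_ablation(ss, ["S_MLP"], [("GSR",)], cfg, width_scale=0.02)
        # requested subset + always-included all-modality reference
        assert len(rep.rows) == 2
        mods = {r["modalities"] for r in rep.rows}
        assert ("PPG", "GSR", "ET", "fNIRS") in mods
        for r in rep.rows:
            assert r["low"] == pytest.approx(r["mean_abs_error"] * 6)

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            run_ablation(self._set(), ["S_MLP"], [()],
                         TrainConfig(epochs_per_fold=1), width_scale=0.02)
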