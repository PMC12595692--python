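"""Metric suite, chance baseline, and confusion-matrix reconstruction."""

import numpy as np
import pytest

from emgresp.harness import PredictionRecord
from emgresp.metrics import (
    ConfusionCounts,
    ReconstructionError,
    ais_breakdown,
    chance_baseline,
    confusion,
    mcc,
    metric_suite,
    participant_metrics,
    reconstruct_confusion,
    round_half_up,
)


def _rec(mid, pid, truth, pred):
    lab = {1: "responder", 0: "non_responder"}
    return PredictionRecord(
        muscle_id=mid,
        participant_id=pid,
        trial_votes=[lab[pred]],
        final_label=lab[pred],
        true_label=lab[truth],
    )


FIXTURE = [
    _rec("m1", "p1", 1, 1),
    _rec("m2", "p1", 1, 0),
    _rec("m3", "p1", 0, 0),
    _rec("m4", "p1", 0, 1),
    _rec("m5", "p2", 1, 1),
    _rec("m6", "p2", 0, 0),
    _rec("m7", "p2", 0, 0),
    _rec("m8", "p3", 0, 0),
    _rec("m9", "p3", 1, 0),
    _rec("m10", "p3", 0, 1),
]


class TestConfusion:
    def test_hand_built_fixture_tally(self):
        c = confusion(FIXTURE)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 2, 4)

    def test_all_correct_has_no_errors(self):
        c = confusion([_rec("a", "p", 1, 1), _rec("b", "p", 0, 0)])
        assert c.fp == 0 and c.fn == 0

    def test_swapping_predictions_swaps_cells(self):
        swapped = [
            _rec(r.muscle_id, r.participant_id,
                 1 - (r.true_label == "responder") + 0,
                 1 - (r.final_label == "responder") + 0)
            for r in FIXTURE
        ]
        # truth/prediction negation maps TP<->TN, FP<->FN
        c, cs = confusion(FIXTURE), confusion(swapped)
        assert (cs.tp, cs.fp, cs.fn, cs.tn) == (c.tn, c.fn, c.fp, c.tp)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            confusion([])


class TestMcc:
    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(1, 0, 0, 1)) == 1.0

    def test_printed_counts_give_headline_value(self):
        assert mcc(ConfusionCounts(18, 7, 25, 82)) == pytest.approx(0.41, abs=0.005)

    def test_single_class_predictions_give_zero(self):
        assert mcc(ConfusionCounts(0, 0, 5, 10)) == 0.0

    def test_class_swap_symmetry(self):
        c = ConfusionCounts(7, 3, 5, 15)
        assert mcc(ConfusionCounts(c.tn, c.fn, c.fp, c.tp)) == pytest.approx(mcc(c))


class TestMetricSuite:
    def test_reconstructed_counts_reproduce_suite(self):
        m = metric_suite(ConfusionCounts(18, 7, 25, 82))
        assert m.accuracy == pytest.approx(100 / 132)
        assert m.macro_f1 == pytest.approx(0.68, abs=0.005)
        assert m.precision == pytest.approx(18 / 25)
        assert m.recall_tpr == pytest.approx(18 / 43)
        assert m.tnr == pytest.approx(82 / 89)

    def test_perfect_confusion_all_ones(self):
        m = metric_suite(ConfusionCounts(5, 0, 0, 7))
        assert (m.mcc, m.macro_f1, m.accuracy, m.precision, m.recall_tpr, m.tnr) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_no_positives_zero_denominator_convention(self):
        """A participant with no responders and no positive predictions has
        recall 0 and TNR 1 under the zero-denominator convention."""
        m = metric_suite(ConfusionCounts(0, 0, 0, 8))
        assert m.recall_tpr == 0.0 and m.precision == 0.0 and m.tnr == 1.0


class TestGranularBreakdowns:
    def test_participant_counts_sum_to_overall(self):
        per = participant_metrics(FIXTURE)
        assert set(per) == {"p1", "p2", "p3"}
        assert sum(r.n for r in per.values()) == confusion(FIXTURE).n

    def test_single_responder_participant_recall_one(self):
        recs = [_rec(f"m{i}", "p", 0, 0) for i in range(7)] + [_rec("m8", "p", 1, 1)]
        assert participant_metrics(recs)["p"].recall_tpr == 1.0

    def test_ais_partition_covers_all_records(self):
        ais = {"p1": "A", "p2": "B", "p3": "D"}
        by_g = ais_breakdown(FIXTURE, ais)
        assert sum(r.n for r in by_g.values()) == len(FIXTURE)

    def test_single_grade_breakdown_equals_overall(self):
        ais = {"p1": "C", "p2": "C", "p3": "C"}
        by_g = ais_breakdown(FIXTURE, ais)
        overall = metric_suite(confusion(FIXTURE))
        assert by_g["C"].mcc == pytest.approx(overall.mcc)
        assert by_g["C"].n == overall.n


class TestChanceBaseline:
    def test_balanced_prevalence_gives_half_accuracy(self):
        assert chance_baseline(10, 5).accuracy == pytest.approx(0.5)

    def test_monte_carlo_random_predictor_agrees(self, rng):
        """Empirical means of a prevalence-matched independent predictor
        (1e5 replicates) match the closed forms within 3 SE."""
        n, n_pos, reps = 132, 43, 100_000
        pi = n_pos / n
        truth = np.zeros(n, dtype=bool)
        truth[:n_pos] = True
        preds = rng.random((reps, n)) < pi
        tp = (preds[:, :n_pos]).sum(axis=1)
        fp = (preds[:, n_pos:]).sum(axis=1)
        acc = (tp + (n - n_pos - fp)) / n
        with np.errstate(invalid="ignore"):
            prec = np.where(tp + fp > 0, tp / np.maximum(tp + fp, 1), 0.0)
        rec = tp / n_pos
        tnr = (n - n_pos - fp) / (n - n_pos)
        cb = chance_baseline(n, n_pos)
        for emp, closed in [
            (acc, cb.accuracy), (prec, cb.precision), (rec, cb.recall_tpr), (tnr, cb.tnr),
        ]:
            se = emp.std() / np.sqrt(reps)
            assert abs(emp.mean() - closed) < 3 * se + 1e-4

    def test_degenerate_prevalence_rejected(self):
        with pytest.raises(ValueError):
            chance_baseline(10, 0)


class TestReconstruction:
    def test_headline_feature_set_column_unique(self):
        c = reconstruct_confusion(132, 43, 0.72, 0.42, 0.92)
        assert (c.tp, c.fp, c.fn, c.tn) == (18, 7, 25, 82)

    def test_clinical_column_unique(self):
        c = reconstruct_confusion(132, 43, 0.69, 0.21, 0.96)
        assert (c.tp, c.fp, c.fn, c.tn) == (9, 4, 34, 85)

    def test_perfect_metrics_recover_diagonal(self):
        c = reconstruct_confusion(132, 43, 1.0, 1.0, 1.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (43, 0, 0, 89)

    def test_inconsistent_metrics_raise(self):
        with pytest.raises(ReconstructionError):
            reconstruct_confusion(10, 5, 1.0, 0.0, 0.0)

    def test_rounding_is_half_up(self):
        assert round_half_up(0.425) == 0.43
        assert round_half_up(0.4249) == 0.42
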