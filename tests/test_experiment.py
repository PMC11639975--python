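import numpy as np
import pytest

from exactnet.experiment import (
    REFERENCE_TEN_CASE_COUNTS,
    CaseRecord,
    case_record_from_counts,
    evaluate_case,
    make_phantom_cohort,
    records_to_frame,
    run_experiment,
    summarize_experiment,
)
from exactnet.imgio import Box3D
from exactnet.pipeline import CandidateNodule


def cand(lo, hi, lobe="LUL", score=0.9):
    return CandidateNodule(box=Box3D(lo=lo, hi=hi, score=score), score=score, lobe=lobe, lobe_overlap=1.0)


class TestEvaluateCase:
    def test_two_truth_seven_detected_five_removed_matches(self):
        dets = [cand((i, 0, 0), (i + 2, 2, 2)) for i in range(0, 21, 3)]
        retained = dets[:2]
        rec = evaluate_case(2, dets, retained)
        assert rec.match_guided and rec.removed_n == 5
        assert rec.detected_fp and not rec.match_unguided

    def test_missed_truth_is_fn_under_both_modes(self):
        rec = evaluate_case(1, [], [])
        assert rec.has_fn
        assert not rec.match_guided and not rec.match_unguided

    def test_excess_retained_is_fp_no_match(self):
        dets = [cand((i, 0, 0), (i + 2, 2, 2)) for i in range(0, 12, 3)]
        rec = evaluate_case(1, dets, dets[:2])
        assert not rec.match_guided and rec.has_fp

    def test_retained_must_be_subset(self):
        dets = [cand((0, 0, 0), (2, 2, 2))]
        stranger = cand((9, 9, 9), (11, 11, 11))
        with pytest.raises(ValueError):
            evaluate_case(1, dets, [stranger])

    def test_localization_mode_rejects_misplaced_detection(self):
        truth = [Box3D((0, 0, 0), (4, 4, 4))]
        hit = cand((0, 0, 0), (4, 4, 4))
        miss = cand((20, 20, 20), (24, 24, 24))
        rec = evaluate_case(1, [hit], [hit], truth_boxes=truth, iou_threshold=0.1)
        assert rec.match_guided and rec.match_unguided
        rec2 = evaluate_case(1, [miss], [miss], truth_boxes=truth, iou_threshold=0.1)
        assert not rec2.match_guided and rec2.detected_fp


class TestReferenceAccounting:
    def test_ten_case_worked_example(self):
        """The printed ten-case counts give guided 70%, unguided 20%, boost 250%."""
        records = [
            case_record_from_counts(cid, t, d, r, detected_fp=fp, detected_fn=fn)
            for cid, t, d, r, fp, fn in REFERENCE_TEN_CASE_COUNTS
        ]
        summary = summarize_experiment(records)
        assert summary.guided_match_rate == pytest.approx(70.0)
        assert summary.unguided_match_rate == pytest.approx(20.0)
        assert summary.relative_boost == pytest.approx(250.0)

    def test_case_level_outcomes(self):
        recs = {
            cid: case_record_from_counts(cid, t, d, r, detected_fp=fp, detected_fn=fn)
            for cid, t, d, r, fp, fn in REFERENCE_TEN_CASE_COUNTS
        }
        assert recs[4].match_guided and recs[4].removed_n == 5
        assert not recs[6].match_guided and recs[6].has_fn
        assert not recs[8].match_guided and recs[8].has_fp
        assert not recs[10].match_guided  # the single detection was spurious

    def test_frame_mirrors_reference_columns(self):
        records = [
            case_record_from_counts(cid, t, d, r, detected_fp=fp, detected_fn=fn)
            for cid, t, d, r, fp, fn in REFERENCE_TEN_CASE_COUNTS
        ]
        df = records_to_frame(records)
        assert list(df.columns) == [
            "Case ID",
            "Ground Truth",
            "Detected Nodules",
            "Removed Nodules",
            "Matching Ground Truth",
        ]
        assert df.loc[3, "Detected Nodules"] == "7 (FP)"
        assert df.loc[5, "Detected Nodules"] == "0 (FN)"


class TestSummarize:
    def test_all_matching(self):
        recs = [case_record_from_counts(i, 1, 1, 0, detected_fp=False) for i in range(4)]
        s = summarize_experiment(recs)
        assert s.guided_match_rate == 100.0 and s.unguided_match_rate == 100.0
        assert s.relative_boost == 0.0

    def test_single_matching_case(self):
        s = summarize_experiment([case_record_from_counts(1, 1, 1, 0, detected_fp=False)])
        assert s.guided_match_rate == 100.0

    def test_zero_unguided_rate_gives_undefined_boost(self):
        s = summarize_experiment([case_record_from_counts(1, 1, 3, 2)])
        assert s.unguided_match_rate == 0.0
        assert s.relative_boost is None

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        recs = [
            case_record_from_counts(i, 1, int(rng.integers(0, 4)), 0)
            for i in range(8)
        ]
        a = summarize_experiment(recs)
        b = summarize_experiment(list(reversed(recs)))
        assert (a.guided_match_rate, a.unguided_match_rate) == (b.guided_match_rate, b.unguided_match_rate)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            summarize_experiment([])


@pytest.fixture(scope="module")
def cohort():
    return make_phantom_cohort(6, seed=31, grid_shape=(48, 48, 48), n_distractors=(1, 2))


class TestRunExperimentWithOracleDetector:
    def test_perfect_detector_with_distractors(self, cohort):
        """All true nodule boxes detected: guidance removes exactly the
        out-of-lobe distractors, so guided matches every case and unguided
        none (every case has >= 1 distractor)."""
        result = run_experiment(cohort, lambda case: list(case.truth_boxes))
        assert result.summary.guided_match_rate == 100.0
        assert result.summary.unguided_match_rate == 0.0
        assert result.failures == []

    def test_perfect_detector_no_distractors(self):
        cohort = make_phantom_cohort(4, seed=17, grid_shape=(48, 48, 48), n_distractors=(0, 0))
        result = run_experiment(cohort, lambda case: list(case.truth_boxes))
        assert result.summary.guided_match_rate == 100.0
        assert result.summary.unguided_match_rate == 100.0
        assert result.summary.relative_boost == 0.0

    def test_guided_never_removes_confirmed_lobe_candidates(self, cohort):
        result = run_experiment(cohort, lambda case: list(case.truth_boxes))
        for rec, cc in zip(result.records, cohort):
            assert rec.retained_n >= 1  # the true tumor candidate survives

    def test_failures_recorded_not_raised(self, cohort):
        def flaky(case):
            raise RuntimeError("detector crashed")

        bad = [cohort[0]]
        good = cohort[1:]

        def detector(case):
            if case is bad[0].case:
                raise RuntimeError("boom")
            return list(case.truth_boxes)

        result = run_experiment(bad + list(good), detector)
        assert len(result.failures) == 1
        assert len(result.records) == len(good)


class TestCaseRecordInvariants:
    def test_count_conservation_enforced(self):
        with pytest.raises(ValueError):
            CaseRecord(
                case_id=1,
                ground_truth_n=1,
                detected_n=3,
                removed_n=1,
                retained_n=1,  # violates detected - removed
                detected_fp=True,
                has_fp=False,
                has_fn=False,
                match_guided=False,
                match_unguided=False,
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            case_record_from_counts(1, 1, 1, 2)
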