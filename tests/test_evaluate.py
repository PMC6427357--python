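"""Detection matching, performance metrics, kinematics, annotation I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from blinkflow.detector import FrameRecord
from blinkflow.evaluate import (
    EvalCounts,
    compute_metrics,
    frame_period_ms,
    match_detections,
    mean_metrics,
    phase_breakdown,
    read_annotations,
    records_from_annotations,
    required_fps,
    write_annotations,
)
from blinkflow.synth import BlinkKinematics, spontaneous_defaults, voluntary_defaults


def metrics_brute(tp, fn, fp):
    """Independent fraction arithmetic for the four detection metrics."""
    return (
        tp / (tp + fp) if tp + fp else None,
        tp / (tp + fn) if tp + fn else None,
        tp / (tp + fp + fn) if tp + fp + fn else None,
        fp / (fp + tp) if fp + tp else None,
    )


class TestMatchDetections:
    def test_overlapping_detection_is_tp(self):
        c = match_detections([(10, 20)], [(12, 18)])
        assert (c.tp, c.fp, c.fn) == (1, 0, 0)

    def test_disjoint_detection_is_fp_and_gt_fn(self):
        c = match_detections([(10, 20)], [(30, 35)])
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_second_overlap_of_same_gt_is_fp(self):
        c = match_detections([(10, 20), (40, 50)], [(12, 18), (13, 19), (60, 61)])
        assert (c.tp, c.fp, c.fn) == (1, 2, 1)
        assert c.db == 3

    def test_touching_endpoints_count_as_overlap(self):
        c = match_detections([(10, 20)], [(20, 25)])
        assert c.tp == 1

    def test_slack_extends_matching(self):
        assert match_detections([(10, 20)], [(22, 25)], slack_frames=0).tp == 0
        assert match_detections([(10, 20)], [(22, 25)], slack_frames=2).tp == 1

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.tuples(st.integers(0, 500), st.integers(0, 50)), max_size=10),
        st.lists(st.tuples(st.integers(0, 500), st.integers(0, 50)), max_size=10),
        st.randoms(),
    )
    def test_invariant_to_detection_ordering(self, gt_raw, det_raw, rnd):
        gt = [(s, s + w) for s, w in gt_raw]
        det = [(s, s + w) for s, w in det_raw]
        shuffled = det[:]
        rnd.shuffle(shuffled)
        assert match_detections(gt, det) == match_detections(gt, shuffled)


class TestComputeMetrics:
    def test_published_sample_row(self):
        m = compute_metrics(EvalCounts.from_counts(tp=19, fn=2, fp=2)).rounded()
        assert (m.precision, m.recall, m.accuracy, m.fdr) == (0.905, 0.905, 0.826, 0.095)

    def test_perfect_sample(self):
        m = compute_metrics(EvalCounts.from_counts(tp=8, fn=0, fp=0)).rounded()
        assert (m.precision, m.recall, m.accuracy, m.fdr) == (1.0, 1.0, 1.0, 0.0)

    def test_empty_sample_all_undefined(self):
        m = compute_metrics(EvalCounts.from_counts(tp=0, fn=0, fp=0))
        assert m.precision is None and m.recall is None and m.accuracy is None and m.fdr is None

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500))
    def test_matches_fraction_arithmetic_and_precision_fdr_complement(self, tp, fn, fp):
        m = compute_metrics(EvalCounts.from_counts(tp=tp, fn=fn, fp=fp))
        bp, br, ba, bf = metrics_brute(tp, fn, fp)
        assert (m.precision, m.recall, m.accuracy, m.fdr) == (bp, br, ba, bf)
        if tp + fp > 0:
            assert m.precision + m.fdr == pytest.approx(1.0, abs=1e-12)

    def test_counts_invariants_enforced(self):
        with pytest.raises(ValueError):
            EvalCounts(gt=5, tp=3, fn=1, fp=0, db=3)  # gt != tp + fn
        with pytest.raises(ValueError):
            EvalCounts(gt=4, tp=3, fn=1, fp=0, db=4)  # db != tp + fp

    def test_mean_metrics_unweighted(self):
        ms = [
            compute_metrics(EvalCounts.from_counts(8, 0, 0)),
            compute_metrics(EvalCounts.from_counts(5, 5, 5)),
        ]
        mm = mean_metrics(ms)
        assert mm.precision == pytest.approx((1.0 + 0.5) / 2)


class TestKinematics:
    def test_spontaneous_budget(self):
        pb = phase_breakdown(spontaneous_defaults())
        assert pb.total_ms == pytest.approx(256.7)
        assert round(pb.pause_pct, 1) == 5.3
        assert round(pb.closing_pct, 1) == 27.9
        assert round(pb.reopening_pct, 1) == 66.8

    def test_voluntary_budget(self):
        pb = phase_breakdown(voluntary_defaults())
        assert pb.total_ms == pytest.approx(283.5)
        assert round(pb.closing_pct, 1) == 25.0
        assert round(pb.pause_pct, 1) == 15.6
        assert round(pb.reopening_pct, 1) == 59.4

    def test_symmetric_phases(self):
        pb = phase_breakdown(BlinkKinematics(1, 1, 1))
        for pct in (pb.closing_pct, pb.pause_pct, pb.reopening_pct):
            assert round(pct, 1) == 33.3

    def test_percentages_sum_to_100(self):
        pb = phase_breakdown(BlinkKinematics(3.3, 97.1, 55.5))
        assert pb.closing_pct + pb.pause_pct + pb.reopening_pct == pytest.approx(100.0)

    def test_required_fps_for_spontaneous_pause(self):
        assert required_fps(13.7) == 73

    def test_30fps_frame_period_exceeds_pause(self):
        assert frame_period_ms(30) == pytest.approx(33.3, abs=0.05)
        assert frame_period_ms(30) > 13.7 + 3.3

    def test_required_fps_trivial(self):
        assert required_fps(100.0) == 10

    def test_invalid_pause_rejected(self):
        with pytest.raises(ValueError):
            required_fps(0)


class TestAnnotations:
    def _records(self, n=100):
        rng = np.random.default_rng(0)
        return [
            FrameRecord(
                frame_number=i,
                dmv_magnitude=float(rng.uniform(0, 10)),
                umv_magnitude=float(rng.uniform(0, 10)),
                eye_state=["open", "closed", "unknown"][i % 3],
                blink_detected=bool(i % 7 == 0),
                roi_detected=bool(i % 5 != 0),
            )
            for i in range(n)
        ]

    def test_roundtrip_lossless(self, tmp_path):
        records = self._records()
        p = tmp_path / "ann.csv"
        write_annotations(records, p)
        back = records_from_annotations(read_annotations(p))
        assert back == records

    def test_missing_mandatory_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        pd.DataFrame({"dmv_magnitude": [1.0]}).to_csv(p, index=False)
        with pytest.raises(ValueError, match="frame_number"):
            read_annotations(p)

    def test_reviewed_columns_roundtrip(self, tmp_path):
        records = self._records(10)
        p = tmp_path / "reviewed.csv"
        write_annotations(
            records,
            p,
            ground_truth=[i in (3, 7) for i in range(10)],
            categories=["TP" if i == 3 else "" for i in range(10)],
        )
        df = read_annotations(p)
        assert df["ground_truth"].sum() == 2
        assert (df["category"] == "TP").sum() == 1
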