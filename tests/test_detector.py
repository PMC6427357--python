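"""Per-frame orchestration and the blink FSM on synthetic streams."""

import numpy as np
import pytest

from blinkflow.config import RunConfig
from blinkflow.detector import (
    Detector,
    DetectorFsm,
    DetectorState,
    EyeState,
    run_detector,
)
from blinkflow.frameio import crop_frame, frames_from_arrays
from blinkflow.synth import default_blink_video_config, generate_video
from blinkflow.threshold import ThresholdState

#: Transitions observable between successive per-step states.  S2 (candidate
#: under verification) is transient within one step, so a step that registers
#: AND verifies a closure shows as S1 -> S3: that composite is only legal when
#: a blink event was emitted on that step, which proves the S1 -> S2 -> S3
#: path was taken; a rejected candidate (S1 -> S2 -> S1) shows as S1 -> S1.
ALLOWED_EDGES = {
    (DetectorFsm.S0, DetectorFsm.S0),
    (DetectorFsm.S0, DetectorFsm.S1),
    (DetectorFsm.S1, DetectorFsm.S1),
    (DetectorFsm.S1, DetectorFsm.S2),
    (DetectorFsm.S2, DetectorFsm.S1),
    (DetectorFsm.S2, DetectorFsm.S3),
    (DetectorFsm.S3, DetectorFsm.S3),
    (DetectorFsm.S3, DetectorFsm.S1),
}


def assert_edges_sound(states, records):
    """Every observed transition is an allowed edge, or the S1->S3 composite
    accompanied by a blink event (the verification path through S2)."""
    for (a, b), rec in zip(zip(states, states[1:]), records):
        if (a.fsm, b.fsm) == (DetectorFsm.S1, DetectorFsm.S3):
            assert rec.blink_detected, "S1->S3 without a verified blink event"
        else:
            assert (a.fsm, b.fsm) in ALLOWED_EDGES, (a.fsm, b.fsm)


def stepwise_run(frames, cfg=None):
    """Drive Detector.step manually, returning per-step states and events."""
    cfg = cfg or RunConfig()
    det = Detector(cfg)
    state = DetectorState(
        threshold_state=ThresholdState.initial(cfg.threshold_window_n, cfg.initial_threshold)
    )
    cropped = [crop_frame(f, cfg.crop_px, cfg.crop_edge) for f in frames]
    states, records, events = [state], [], []
    for prev, curr in zip(cropped, cropped[1:]):
        state, rec, ev = det.step(state, prev, curr)
        states.append(state)
        records.append(rec)
        if ev is not None:
            events.append(ev)
    return states, records, events


class TestStaticInput:
    def test_two_identical_frames_one_record_no_events(self):
        img = np.random.default_rng(0).integers(0, 255, (320, 240), dtype=np.uint8)
        records, events = run_detector(frames_from_arrays([img, img]))
        assert len(records) == 1 and events == []
        assert records[0].dmv_magnitude == 0.0

    def test_fewer_than_two_frames_rejected(self):
        img = np.zeros((320, 240), dtype=np.uint8)
        with pytest.raises(ValueError):
            run_detector(frames_from_arrays([img]))

    def test_step_rejects_shape_mismatch(self):
        det = Detector(RunConfig())
        a = frames_from_arrays([np.zeros((320, 170))])[0]
        b = frames_from_arrays([np.zeros((320, 100))])[0]
        with pytest.raises(ValueError):
            det.step(DetectorState(), a, b)


@pytest.fixture(scope="module")
def single_blink_steps(one_blink_video):
    frames, gt, _ = one_blink_video
    states, records, events = stepwise_run(frames)
    return frames, gt, states, records, events


class TestFsmOnSingleBlink:
    def test_transitions_confined_to_allowed_edges(self, single_blink_steps):
        _, _, states, records, _ = single_blink_steps
        assert_edges_sound(states, records)

    def test_state_eye_state_coupling_holds_throughout(self, single_blink_steps):
        _, _, states, _, _ = single_blink_steps
        for s in states:
            if s.fsm is DetectorFsm.S3:
                assert s.eye_state is EyeState.CLOSED
            if s.fsm is DetectorFsm.S1:
                assert s.eye_state is EyeState.OPEN

    def test_blink_detected_closed_then_reopened(self, single_blink_steps):
        _, (g,), states, records, events = single_blink_steps
        assert len(events) == 1
        ev = events[0]
        # Verified during the closing or pause phase, before reopening begins.
        assert g.start_frame <= ev.verified_frame <= g.pause_end
        assert ev.verification_q < RunConfig().ncc_threshold
        # The eye was classified closed at verification and open again later.
        closed_frames = [r.frame_number for r in records if r.eye_state == "closed"]
        assert ev.verified_frame in closed_frames
        assert states[-1].eye_state is EyeState.OPEN

    def test_records_cover_every_transition(self, single_blink_steps):
        frames, _, _, records, _ = single_blink_steps
        assert [r.frame_number for r in records] == [f.index for f in frames[1:]]
        assert all(r.dmv_magnitude >= 0 and r.umv_magnitude >= 0 for r in records)


class TestCleanFiveBlinkScene:
    def test_exactly_five_events_matching_ground_truth(self, clean_blink_run):
        frames, gt, records, events, _ = clean_blink_run
        assert len(events) == 5
        from blinkflow.evaluate import compute_metrics, match_detections

        counts = match_detections([g.interval() for g in gt], [e.interval() for e in events])
        m = compute_metrics(counts)
        assert m.recall == 1.0
        assert m.fdr == 0.0

    def test_every_blink_verified_before_reopening_onset(self, clean_blink_run):
        _, gt, _, events, _ = clean_blink_run
        for ev, g in zip(sorted(events, key=lambda e: e.initial_frame), gt):
            assert g.start_frame <= ev.verified_frame <= g.pause_end

    def test_event_structure_invariants(self, clean_blink_run):
        _, _, _, events, cfg = clean_blink_run
        for ev in events:
            assert ev.initial_frame <= ev.verified_frame
            assert ev.reopen_frame is None or ev.reopen_frame > ev.verified_frame
            assert ev.verification_q < cfg.ncc_threshold

    def test_determinism(self, clean_blink_run):
        frames, _, records, events, cfg = clean_blink_run
        records2, events2 = run_detector(frames, cfg)
        assert records2 == records
        assert [(e.initial_frame, e.verified_frame, e.reopen_frame) for e in events2] == [
            (e.initial_frame, e.verified_frame, e.reopen_frame) for e in events
        ]


class TestSaccadesOnly:
    def test_vertical_saccades_below_threshold_yield_no_events(self):
        from blinkflow.synth import SynthConfig

        cfg = SynthConfig(
            duration_s=2.0,
            noise_sd=0.0,
            seed=4,
            saccade_schedule=((1000.0, "down", 8.0), (1450.0, "up", 8.0)),
        )
        frames, gt = generate_video(cfg)
        records, events = run_detector(frames, RunConfig())
        assert gt == []
        assert events == []
        # Saccades did produce motion, so the stream is not trivially static.
        assert max(r.dmv_magnitude for r in records) > 0
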