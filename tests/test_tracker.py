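"""Hybrid tracking loop: mode switching, initialisation, stepping,
pause/resume and full-video behaviour on ground-truthed scenes."""

import math

import numpy as np
import pytest

import hybridtrack as ht
from hybridtrack.appearance import Detection
from hybridtrack.tracker import (
    HybridTracker,
    handle_reappearance,
    initialize_track,
    select_mode,
    track_video,
    read_tracks,
    write_tracks,
)

from conftest import make_scene, run_tracker

# ------------------------------------------------------------ select_mode


@pytest.mark.parametrize(
    "n_regions,expected",
    [(0, "appearance"), (1, "motion"), (2, "motion"), (3, "motion"), (4, "appearance"), (10, "appearance")],
)
def test_mode_truth_table(n_regions, expected, small_cfg):
    assert select_mode(n_regions, motion_found=True, cfg=small_cfg) == expected


def test_empty_motion_channel_forces_appearance(small_cfg):
    assert select_mode(1, motion_found=False, cfg=small_cfg) == "appearance"


# --------------------------------------------------------- initialisation


def test_initialize_finds_first_appearance(small_cfg):
    cfg = make_scene(seed=21, n_frames=80)
    truth = ht.simulate_trajectory(cfg)
    truth.visible[:40] = False  # insect enters at frame 40
    frames = ht.render_frames(truth, cfg)
    det = ht.OracleDetector(truth, seed=21)
    track = initialize_track(ht.ArraySource(frames), det, small_cfg)
    assert track.points[0].frame_index == 40
    assert track.points[0].source == "appearance"
    assert track.state == "tracking"


def test_initialize_without_detections_terminates(small_cfg):
    cfg = make_scene(seed=22, n_frames=30)
    truth = ht.simulate_trajectory(cfg)
    truth.visible[:] = False
    frames = ht.render_frames(truth, cfg)
    det = ht.OracleDetector(truth, seed=22)
    track = initialize_track(ht.ArraySource(frames), det, small_cfg)
    assert track.state == "terminated_end_of_video"
    assert track.points == []


def test_initialize_prefers_highest_confidence(small_cfg):
    class TwoDetections:
        min_confidence = 0.5

        def detect(self, frame, k):
            if k != 3:
                return []
            return [
                Detection(frame_index=3, centroid=(10.0, 10.0), confidence=0.7),
                Detection(frame_index=3, centroid=(50.0, 50.0), confidence=0.95),
            ]

    frames = [np.zeros((60, 60), dtype=np.uint8)] * 6
    track = initialize_track(ht.ArraySource(frames), TwoDetections(), small_cfg)
    assert (track.points[0].x, track.points[0].y) == (50.0, 50.0)


# ------------------------------------------------------------- reappearance


def _paused_track(cfg, disappearance=(100.0, 100.0)):
    tracker = HybridTracker(cfg, (320, 240))
    tr = tracker.new_track(
        Detection(frame_index=0, centroid=disappearance, confidence=0.9)
    )
    tr.gating.speed_history = [2.0, 3.0, 4.0]
    tr.gating.tau = 30
    tr.disappearance_position = disappearance
    tr.disappearance_frame = 0
    tr.state = "paused_candidate_exit"
    return tr, tracker


def test_reappearance_near_disappearance_resumes_same_id(small_cfg):
    tr, tracker = _paused_track(small_cfg)
    det = Detection(frame_index=40, centroid=(103.0, 104.0), confidence=0.9)
    out = handle_reappearance(tr, det, small_cfg, tracker)
    assert out is tr
    assert out.state == "tracking"
    assert out.points[-1].frame_index == 40
    assert any(e.event == "resumed" for e in out.events)


def test_reappearance_across_frame_terminates_and_seeds_new_track(small_cfg):
    tr, tracker = _paused_track(small_cfg)
    det = Detection(frame_index=40, centroid=(310.0, 10.0), confidence=0.9)
    out = handle_reappearance(tr, det, small_cfg, tracker)
    assert out is not tr
    assert tr.state == "terminated_exit"
    assert out.id != tr.id
    assert out.state == "tracking"


def test_terminal_states_are_absorbing(small_cfg):
    tr, tracker = _paused_track(small_cfg)
    tr.set_state("terminated_exit")
    with pytest.raises(ValueError):
        tr.set_state("tracking")


# ----------------------------------------------------------- whole videos


def test_single_insect_yields_one_accurate_track(small_cfg):
    sc = make_scene(seed=31, n_frames=300)
    truth, tracks = run_tracker(sc, small_cfg)
    assert len(tracks) == 1
    scores = ht.score_against_truth(tracks, truth)
    assert scores.detection_rate >= 0.99
    # every recorded point came from a gated association or carry-forward
    for p in tracks[0].points:
        if p.gate_used is not None and p.source != "carried_forward":
            assert p.gate_used > 0


def test_empty_scene_yields_no_tracks(small_cfg):
    sc = make_scene(seed=32, n_frames=60)
    truth = ht.simulate_trajectory(sc)
    truth.visible[:] = False
    truth.areas[:] = 0.0
    frames = ht.render_frames(truth, sc)
    det = ht.OracleDetector(truth, seed=32)
    tracks = track_video(ht.ArraySource(frames), det, small_cfg)
    assert tracks == []


def test_occluded_insect_pauses_and_resumes_on_same_track(small_cfg):
    sc = make_scene(
        seed=33,
        n_frames=400,
        occlusions=[ht.OcclusionEvent(start=150, ramp=10, duration=60)],
        interior_margin=40.0,
    )
    truth, tracks = run_tracker(sc, small_cfg)
    assert len(tracks) == 1
    tr = tracks[0]
    events = {e.event for e in tr.events}
    assert "occluded" in events and "resumed" in events
    occl_frame = next(e.frame for e in tr.events if e.event == "occluded")
    assert 150 <= occl_frame <= 230
    # positions are carried forward during the occlusion
    carried = [p for p in tr.points if p.source == "carried_forward"]
    assert len(carried) >= 15


def test_exit_scene_pauses_then_terminates(small_cfg):
    sc = make_scene(seed=34, n_frames=400, exit=ht.ExitEvent(frame=250, side="right"))
    truth, tracks = run_tracker(sc, small_cfg)
    assert truth.exit_frame is not None
    assert tracks[0].state == "terminated_exit"
    exited = [e for e in tracks[0].events if e.event == "exited"]
    assert exited and exited[0].frame >= truth.exit_frame
    assert not any(e.event == "occluded" for e in tracks[0].events)


def test_two_sequential_insects_get_two_tracks(small_cfg):
    """Second insect enters after the first exits: two non-overlapping
    tracks."""
    sc1 = make_scene(seed=35, n_frames=400, exit=ht.ExitEvent(frame=200, side="left"))
    truth1 = ht.simulate_trajectory(sc1)
    sc2 = make_scene(seed=36, n_frames=400)
    truth2 = ht.simulate_trajectory(sc2)
    # splice: insect 2 appears well after insect 1 left
    start2 = truth1.exit_frame + 60
    truth2.visible[:start2] = False
    truth2.areas[:start2] = 0.0
    # composite: insect 2 is stamped onto scene 1's frames after start2
    frames = ht.render_frames(truth1, sc1).copy()

    class TwoInsectDetector:
        min_confidence = 0.5

        def __init__(self):
            self.d1 = ht.OracleDetector(truth1, seed=35)
            self.d2 = ht.OracleDetector(truth2, seed=36)

        def detect(self, frame, k):
            return self.d1.detect(frame, k) + self.d2.detect(frame, k)

    for k in range(start2, sc2.n_frames):
        if truth2.areas[k] > 0:
            x, y = truth2.positions[k]
            rr = slice(max(0, int(y) - 8), int(y) + 8)
            cc = slice(max(0, int(x) - 8), int(x) + 8)
            frames[k, rr, cc] = sc2.insect_intensity
    tracks = track_video(ht.ArraySource(frames), TwoInsectDetector(), small_cfg)
    assert len(tracks) == 2
    end_first = tracks[0].points[-1].frame_index
    start_second = tracks[1].points[0].frame_index
    assert start_second > end_first - small_cfg.gating.tau_bar
    assert tracks[0].state == "terminated_exit"


def test_mode_utilization_accounted(small_cfg):
    sc = make_scene(seed=37, n_frames=200)
    truth, tracks = run_tracker(sc, small_cfg)
    util = tracks[0].mode_utilization()
    assert util["motion"] + util["appearance"] == pytest.approx(1.0)
    assert util["motion"] > 0.5  # sparse clean scene: motion channel dominates


def test_track_roundtrip_through_csv(tmp_path, small_cfg):
    sc = make_scene(seed=38, n_frames=150)
    _, tracks = run_tracker(sc, small_cfg)
    write_tracks(tracks, tmp_path, fps=60.0)
    back = read_tracks(tmp_path)
    assert len(back) == len(tracks)
    assert [p.frame_index for p in back[0].points] == [
        p.frame_index for p in tracks[0].points
    ]
    assert [(e.frame, e.event) for e in back[0].events] == [
        (e.frame, e.event) for e in tracks[0].events
    ]
    assert back[0].points[5].x == pytest.approx(tracks[0].points[5].x, abs=1e-3)
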