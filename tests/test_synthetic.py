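"""Simulator: body geometry, determinism, archetype kinematics, datasets."""

from dataclasses import replace

import numpy as np
import pytest

import fishbout as fb
from fishbout import kinematics
from fishbout.synthetic import ARCHETYPES, ScheduleError, body_pose


class TestBodyPose:
    def test_zero_curvature_collinear_along_heading(self, cfg24):
        pts = body_pose([0.0, 0.0], 90.0, np.zeros(7), cfg24)
        np.testing.assert_allclose(pts[:, 0], 0.0, atol=1e-12)
        assert np.all(np.diff(pts[:, 1]) < 0)  # snout at top, tail below

    def test_straight_body_length(self, cfg24):
        pts = body_pose([1.0, -2.0], 33.0, np.zeros(7), cfg24)
        assert np.linalg.norm(pts[0] - pts[7]) == pytest.approx(
            cfg24.body_length_mm
        )

    def test_center_keypoint_at_position(self, cfg24):
        pts = body_pose([2.5, 1.5], 10.0, np.full(7, 20.0), cfg24)
        np.testing.assert_allclose(pts[3], [2.5, 1.5], atol=1e-12)

    def test_wrong_profile_length_raises(self, cfg24):
        with pytest.raises(ValueError):
            body_pose([0, 0], 0.0, np.zeros(6), cfg24)

    def test_full_circle_profile_clamped(self, cfg24):
        # 7 x 60 deg sums to 420 deg: would self-intersect; clamped < 360
        pts = body_pose([0, 0], 0.0, np.full(7, 60.0), cfg24)
        assert np.isfinite(pts).all()
        # total turning of the emitted polyline stays below a full circle
        segs = np.diff(pts, axis=0)
        angles = np.degrees(np.arctan2(segs[:, 1], segs[:, 0]))
        turns = (np.diff(angles) + 180.0) % 360.0 - 180.0
        assert np.abs(turns).sum() < 360.0

    def test_segment_lengths_are_uniform(self, cfg24):
        pts = body_pose([0, 0], 45.0, np.full(7, 10.0), cfg24)
        seglens = np.linalg.norm(np.diff(pts, axis=0), axis=-1)
        np.testing.assert_allclose(seglens, cfg24.body_length_mm / 7)


class TestGenerateTrack:
    def test_seeded_determinism_bit_identical(self, cfg24):
        t1, l1 = fb.generate_track("random", cfg24, seed=11)
        t2, l2 = fb.generate_track("random", cfg24, seed=11)
        np.testing.assert_array_equal(t1.coords, t2.coords)
        np.testing.assert_array_equal(l1, l2)

    def test_scheduled_scoot_labeled_at_frame_320(self, cfg24):
        _, labels = fb.generate_track([(2.0, "scoot")], cfg24, seed=1)
        runs = np.flatnonzero(labels == "scoot")
        assert runs[0] == 320
        assert np.array_equal(runs, np.arange(runs[0], runs[-1] + 1))

    def test_overlapping_schedule_rejected(self, cfg24):
        with pytest.raises(ScheduleError, match="overlap"):
            fb.generate_track(
                [(1.0, "scoot"), (1.05, "turn")], cfg24, seed=0
            )

    def test_bout_outside_acquisition_rejected(self, cfg24):
        cfg = replace(cfg24, seconds=1.0)
        with pytest.raises(ScheduleError):
            fb.generate_track([(0.95, "AsLB")], cfg, seed=0)

    def test_fish_stays_inside_well(self, cfg24):
        track, _ = fb.generate_track("random", cfg24, seed=17)
        mm = track.coords * track.pixel_size / 1000.0
        center = mm[:, 3] - cfg24.well_radius_mm
        assert np.linalg.norm(center, axis=-1).max() <= cfg24.well_radius_mm

    def test_rigid_body_segment_lengths(self, cfg24):
        track, _ = fb.generate_track([(1.0, "AsLB")], cfg24, seed=2)
        mm = track.coords * track.pixel_size / 1000.0
        seglens = np.linalg.norm(np.diff(mm, axis=1), axis=-1)
        expected = cfg24.body_length_mm / 7
        # AR(1) jitter sigma is 8 um; allow a few sigma on each endpoint
        assert np.abs(seglens - expected).max() < 6 * 0.008

    def test_stationary_frames_below_speed_threshold(self, cfg24):
        cfg = replace(cfg24, seconds=5.0)
        track, labels = fb.generate_track([], cfg, seed=9)
        series = kinematics.kinematic_series(track)
        assert (labels == "stationary").all()
        assert series.speed.max() < 2.0

    def test_events_carried_on_track(self, cfg24):
        ev = fb.StimulusEvent("acoustic", 5.0)
        track, _ = fb.generate_track([], cfg24, seed=0, events=[ev])
        assert track.events == [ev]


@pytest.fixture(scope="module")
def summaries(cfg24):
    """Net |heading change| and max speed per archetype at sigma=0."""
    cfg = replace(cfg24, noise_sigma_mm=0.0, seconds=2.0)
    out = {}
    for label in ("scoot", "turn", "AsLB", "VsLB"):
        rows = []
        for seed in range(12):
            track, labels = fb.generate_track(
                [(0.5, label)], cfg, seed=100 + seed
            )
            series = kinematics.kinematic_series(track)
            sel = labels == label
            rows.append(
                (
                    abs(series.dheading[sel].sum()),
                    series.speed[sel].max(),
                )
            )
        out[label] = np.array(rows)
    return out


class TestArchetypeKinematics:
    def test_net_heading_change_within_configured_range(self, summaries):
        for label, rows in summaries.items():
            lo, hi = ARCHETYPES[label].heading_change_deg
            assert (rows[:, 0] >= lo - 1.0).all()
            assert (rows[:, 0] <= hi + 1.0).all()

    def test_aslb_heading_exceeds_scoot_range(self, summaries):
        assert summaries["AsLB"][:, 0].min() > ARCHETYPES[
            "scoot"
        ].heading_change_deg[1]

    def test_startle_vs_routine_zero_overlap(self, summaries):
        """Startle-like classes separate from scoot/turn without overlap."""
        routine_heading = np.concatenate(
            [summaries["scoot"][:, 0], summaries["turn"][:, 0]]
        )
        startle_heading = np.concatenate(
            [summaries["AsLB"][:, 0], summaries["VsLB"][:, 0]]
        )
        assert startle_heading.min() > routine_heading.max()
        assert (
            summaries["AsLB"][:, 1].min()
            > max(
                summaries["scoot"][:, 1].max(), summaries["turn"][:, 1].max()
            )
        )

    def test_peak_speed_within_configured_range(self, summaries):
        for label, rows in summaries.items():
            lo, hi = ARCHETYPES[label].peak_speed_mm_s
            assert (rows[:, 1] <= hi + 0.5).all()


class TestLabeledDataset:
    def test_24_well_counts_and_classes(self):
        cfg = fb.SyntheticConfig(plate_format=24)
        windows, labels = fb.generate_labeled_dataset(cfg, 10, seed=0)
        assert windows.shape == (50, 40, 8, 2)
        assert set(labels) == {"stationary", "scoot", "turn", "AsLB", "VsLB"}
        assert all((labels == c).sum() == 10 for c in set(labels))

    def test_96_well_merges_scoot_turn_into_movement(self):
        cfg = fb.SyntheticConfig(plate_format=96)
        windows, labels = fb.generate_labeled_dataset(cfg, 10, seed=0)
        assert windows.shape == (40, 40, 8, 2)
        assert set(labels) == {"stationary", "movement", "AsLB", "VsLB"}

    def test_seeded_determinism(self):
        cfg = fb.SyntheticConfig(plate_format=24)
        w1, l1 = fb.generate_labeled_dataset(cfg, 3, seed=4)
        w2, l2 = fb.generate_labeled_dataset(cfg, 3, seed=4)
        np.testing.assert_array_equal(w1, w2)
        np.testing.assert_array_equal(l1, l2)

    def test_windows_are_aligned(self):
        cfg = fb.SyntheticConfig(plate_format=24)
        windows, _ = fb.generate_labeled_dataset(cfg, 2, seed=1)
        np.testing.assert_allclose(windows[:, 0, 3, :], 0.0, atol=1e-9)
        np.testing.assert_allclose(windows[:, 0, 0, 0], 0.0, atol=1e-9)
        assert (windows[:, 0, 0, 1] > 0).all()

    def test_n_per_class_must_be_positive(self, cfg24):
        with pytest.raises(ValueError):
            fb.generate_labeled_dataset(cfg24, 0, seed=0)


def test_archetype_invariants():
    assert (
        ARCHETYPES["AsLB"].heading_change_deg[0]
        > ARCHETYPES["scoot"].heading_change_deg[1]
    )
    assert (
        ARCHETYPES["AsLB"].peak_speed_mm_s[0]
        > ARCHETYPES["scoot"].peak_speed_mm_s[1]
    )
    assert (
        ARCHETYPES["VsLB"].time_to_peak_frames[0]
        > ARCHETYPES["AsLB"].time_to_peak_frames[1]
    )


def test_config_validation():
    with pytest.raises(ValueError):
        fb.SyntheticConfig(plate_format=12)
    with pytest.raises(ValueError):
        fb.SyntheticConfig(well_radius_mm=1.0, body_length_mm=3.56)
    with pytest.raises(ValueError):
        fb.SyntheticConfig(noise_sigma_mm=-0.1)
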