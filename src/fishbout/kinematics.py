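"""Kinematic series and summaries: speed, heading change, tail angle.

All series have the same length T as the track; first-difference series
(speed, heading change) define frame 0 as 0 so indices line up with frames.
Speed is the frame-to-frame displacement of the body-center keypoint
(index 3) scaled to mm/s; heading is the angle of the center->snout vector;
the "instantaneous" heading change is the wrapped per-frame first
difference in (-180, 180] degrees.  The caudal tail angle is the signed
angle between the trunk axis (snout->center direction, i.e. the body axis
reversed) and the caudal-most segment (keypoint 6 -> keypoint 7): zero for
a straight body, positive for a bend toward the fish's left.

Frames with a masked contributing keypoint propagate NaN into the series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose_io import CAUDAL_BASE, CAUDAL_TIP, CENTER, SNOUT, PoseTrack


def wrap_deg(angle):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    return -(((-np.asarray(angle, dtype=float) + 180.0) % 360.0) - 180.0)


@dataclass
class KinematicSeries:
    """Per-frame kinematics of one track (lengths all equal T)."""

    speed: np.ndarray  # mm/s
    heading: np.ndarray  # degrees, (-180, 180]
    dheading: np.ndarray  # degrees/frame, signed, frame 0 = 0
    tail_angle: np.ndarray  # degrees, signed, 0 = straight
    fps: float
    pixel_size: float

    @property
    def n_frames(self) -> int:
        return self.speed.shape[0]


def kinematic_series(track: PoseTrack) -> KinematicSeries:
    """Compute the per-frame kinematic series of a (cleaned) track."""
    mm = track.coords * (track.pixel_size / 1000.0)
    masked = track.missing
    center = mm[:, CENTER].copy()
    snout = mm[:, SNOUT].copy()
    center[masked[:, CENTER]] = np.nan
    snout[masked[:, SNOUT]] = np.nan

    step = np.diff(center, axis=0)
    speed = np.concatenate(([0.0], np.linalg.norm(step, axis=-1) * track.fps))

    hv = snout - center
    heading = wrap_deg(np.degrees(np.arctan2(hv[:, 1], hv[:, 0])))
    dheading = np.concatenate(([0.0], wrap_deg(np.diff(heading))))

    trunk = center - snout  # body axis reversed
    caudal = mm[:, CAUDAL_TIP] - mm[:, CAUDAL_BASE]
    caudal[masked[:, CAUDAL_TIP] | masked[:, CAUDAL_BASE]] = np.nan
    cross = trunk[:, 0] * caudal[:, 1] - trunk[:, 1] * caudal[:, 0]
    dot = (trunk * caudal).sum(axis=1)
    tail_angle = np.degrees(np.arctan2(cross, dot))
    return KinematicSeries(
        speed=speed,
        heading=heading,
        dheading=dheading,
        tail_angle=tail_angle,
        fps=track.fps,
        pixel_size=track.pixel_size,
    )


def detect_speed_bouts(
    speed: np.ndarray | KinematicSeries,
    threshold: float = 2.0,
    min_frames: int = 5,
) -> list[tuple[int, int]]:
    """Maximal half-open runs with speed > threshold lasting >= min_frames.

    The 2 mm/s threshold with a 5-frame (31 ms at 160 fps) minimum defines
    simple displacement-based movement bouts, independent of the
    classifier.
    """
    if isinstance(speed, KinematicSeries):
        speed = speed.speed
    above = np.asarray(speed) > threshold
    edges = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    stops = np.flatnonzero(edges == -1)
    return [
        (int(a), int(b)) for a, b in zip(starts, stops) if b - a >= min_frames
    ]


def interval_max(
    series: np.ndarray,
    intervals: list[tuple[int, int]],
    signed: bool = False,
) -> np.ndarray:
    """Per-interval maximum of |series| (or the signed maximum).

    Used for the 200-ms (32 frames at 160 fps) pre/at/post stimulus
    comparisons; NaNs inside an interval are ignored.
    """
    series = np.asarray(series, dtype=float)
    out = np.empty(len(intervals))
    for i, (a, b) in enumerate(intervals):
        if b <= a:
            raise ValueError(f"empty interval [{a}, {b})")
        seg = series[a:b]
        out[i] = np.nanmax(seg if signed else np.abs(seg))
    return out


def annotate_bouts(bouts, series: KinematicSeries):
    """Fill each bout's duration and kinematic maxima from the series.

    Returns new :class:`~fishbout.smoothing.Bout` objects with
    ``duration_ms``, ``max_speed`` (mm/s) and ``max_abs_dheading``
    (degrees/frame) computed over the bout's own frames.
    """
    from dataclasses import replace

    out = []
    for b in bouts:
        sl = slice(b.start, b.end)
        out.append(
            replace(
                b,
                duration_ms=(b.end - b.start) / series.fps * 1000.0,
                max_speed=float(np.nanmax(series.speed[sl])),
                max_abs_dheading=float(np.nanmax(np.abs(series.dheading[sl]))),
            )
        )
    return out
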