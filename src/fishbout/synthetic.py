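"""Synthetic larval-zebrafish pose tracks with known per-frame labels.

Real acquisitions come from proprietary multi-well imaging hardware and
cannot ship with the package, so this module emulates them: a larva swims
inside a circular well, executing scheduled motor bouts drawn from five
archetypes, and emits the same 8-keypoint pose track format the rest of
the pipeline consumes, together with ground-truth frame labels.

Archetypes (literature-informed defaults; the field's classic kinematic
descriptions of each maneuver, all configurable):

* ``stationary`` — tracking jitter only, no active movement.
* ``scoot`` — forward propulsion at 5-20 mm/s peak with < 30 deg of net
  heading change and a gentle tail beat.
* ``turn`` — routine turn (R-turn): 30-90 deg reorientation largely in
  place (< 5 mm/s).
* ``AsLB`` — acoustic-startle-like (C-start-like): > 90 deg bend reached
  within ~40 ms and peak speed > 30 mm/s.
* ``VsLB`` — visual-startle-like (O-bend-like): > 90 deg reorientation
  developing over 100-250 ms at lower peak speed.

The body is a 7-segment polyline of total length ``body_length``; bends
are distributed along the tail so the caudal segments carry most of the
curvature.  Tracking noise is a temporally correlated AR(1) jitter per
keypoint, small enough that stationary frames never cross the pipeline's
2 mm/s movement threshold.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import features
from .pose_io import N_KEYPOINTS, PoseTrack, StimulusEvent

LABELS_24 = ("stationary", "scoot", "turn", "AsLB", "VsLB")
LABELS_96 = ("stationary", "movement", "AsLB", "VsLB")

#: standard plate geometry (mm), not a measured quantity
WELL_RADIUS_MM = {24: 7.75, 96: 3.2}
BODY_LENGTH_MM = {24: 3.56, 96: 3.85}


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class ArchetypeParams:
    """Kinematic envelope of one motor archetype (ranges are inclusive)."""

    label: str
    duration_frames: tuple[int, int]
    peak_speed_mm_s: tuple[float, float]
    heading_change_deg: tuple[float, float]
    time_to_peak_frames: tuple[int, int]
    tail_amp_deg: float
    latency_s: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        for lo, hi in (
            self.duration_frames,
            self.peak_speed_mm_s,
            self.heading_change_deg,
            self.time_to_peak_frames,
        ):
            if hi < lo:
                raise ValueError(f"{self.label}: empty range ({lo}, {hi})")
        if self.peak_speed_mm_s[0] < 0:
            raise ValueError(f"{self.label}: speeds must be >= 0")


ARCHETYPES: dict[str, ArchetypeParams] = {
    "stationary": ArchetypeParams(
        "stationary", (1, 10_000), (0.0, 0.0), (0.0, 0.0), (1, 1), 0.0
    ),
    "scoot": ArchetypeParams(
        "scoot", (20, 40), (5.0, 20.0), (2.0, 25.0), (20, 40), 12.0
    ),
    "turn": ArchetypeParams(
        "turn", (15, 35), (2.0, 4.5), (30.0, 88.0), (8, 16), 30.0
    ),
    "AsLB": ArchetypeParams(
        "AsLB", (25, 40), (32.0, 60.0), (95.0, 175.0), (3, 6), 110.0,
        latency_s=(0.005, 0.02),
    ),
    "VsLB": ArchetypeParams(
        "VsLB", (30, 40), (12.0, 25.0), (95.0, 160.0), (16, 38), 85.0,
        latency_s=(0.15, 0.45),
    ),
}


@dataclass
class SyntheticConfig:
    """Acquisition geometry and noise for the simulator.

    ``pixel_size_um`` defaults to 37.8 um/px, the sensor scale of the
    emulated imaging platform; coordinates are generated in mm and emitted
    in pixels with the well's bounding box in the positive quadrant.
    """

    fps: float = 160.0
    seconds: float = 10.0
    plate_format: int = 24
    well_radius_mm: float | None = None
    body_length_mm: float | None = None
    pixel_size_um: float = 37.8
    noise_sigma_mm: float = 0.008
    noise_rho: float = 0.98
    seed: int = 0

    def __post_init__(self):
        if self.plate_format not in (24, 96):
            raise ValueError("plate_format must be 24 or 96")
        if self.well_radius_mm is None:
            self.well_radius_mm = WELL_RADIUS_MM[self.plate_format]
        if self.body_length_mm is None:
            self.body_length_mm = BODY_LENGTH_MM[self.plate_format]
        if not self.well_radius_mm > self.body_length_mm / 2:
            raise ValueError("well radius must exceed body_length / 2")
        if self.noise_sigma_mm < 0:
            raise ValueError("noise sigma must be >= 0")
        if not self.fps > 0:
            raise ValueError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.seconds * self.fps))

    @property
    def class_labels(self) -> tuple[str, ...]:
        return LABELS_24 if self.plate_format == 24 else LABELS_96


# weights distributing a bend across the 7 joints, caudal-heavy
_BEND_WEIGHTS = np.arange(1, 8, dtype=float) ** 1.5
_BEND_WEIGHTS /= _BEND_WEIGHTS.sum()


def body_pose(
    position_mm: np.ndarray,
    heading_deg: float,
    bend_deg: np.ndarray,
    config: SyntheticConfig,
) -> np.ndarray:
    """Place the 8 keypoints (mm) for a given center position and posture.

    ``bend_deg`` holds the 7 inter-segment bend angles, each relative to
    the previous segment's direction (the first relative to the reversed
    heading).  Zero curvature gives 8 collinear points along the heading
    with the snout (keypoint 0) at the head end and the body-center
    keypoint (index 3) at ``position_mm``.  Profiles whose total absolute
    bend reaches 360 deg would self-intersect grossly and are clamped to
    355 deg total.
    """
    bend = np.asarray(bend_deg, dtype=float)
    if bend.shape != (7,):
        raise ValueError("curvature profile must have 7 bend angles")
    total = np.abs(bend).sum()
    if total >= 360.0:
        bend = bend * (355.0 / total)
    seg = config.body_length_mm / 7.0
    angles = np.deg2rad(heading_deg + 180.0 + np.cumsum(bend))
    pts = np.zeros((N_KEYPOINTS, 2))
    steps = seg * np.column_stack([np.cos(angles), np.sin(angles)])
    pts[1:] = np.cumsum(steps, axis=0)
    pts += np.asarray(position_mm, dtype=float) - pts[3]
    return pts


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


@dataclass
class _BoutPlan:
    label: str
    start: int
    duration: int
    speed: np.ndarray  # mm/s per frame
    dheading: np.ndarray  # deg per frame
    bend_amp: np.ndarray  # deg per frame (signed)

    @property
    def end(self) -> int:
        return self.start + self.duration


def _plan_bout(
    label: str,
    start: int,
    params: ArchetypeParams,
    config: SyntheticConfig,
    rng: np.random.Generator,
    duration: int | None = None,
) -> _BoutPlan:
    lo, hi = params.duration_frames
    n = int(duration if duration is not None else rng.integers(lo, hi + 1))
    peak = rng.uniform(*params.peak_speed_mm_s)
    total = rng.uniform(*params.heading_change_deg) * rng.choice([-1.0, 1.0])
    ttp = int(min(rng.integers(params.time_to_peak_frames[0],
                               params.time_to_peak_frames[1] + 1), n))
    t = np.arange(n)
    # propulsion is a short burst around the bend, not the whole bout:
    # scoots push throughout, startle/turn bouts glide after ~2x the bend
    if label == "scoot":
        n_pulse = n
    else:
        n_pulse = min(n, max(2 * ttp, 10), 24)
    speed = np.where(
        t < n_pulse, peak * np.sin(np.pi * (t + 0.5) / n_pulse), 0.0
    )
    cum = total * _smoothstep((t + 1) / max(ttp, 1))
    dheading = np.diff(np.concatenate(([0.0], cum)))
    if label == "scoot":
        # gentle tail beat at ~22 Hz throughout the bout
        beat = np.sin(2 * np.pi * 22.0 * t / config.fps)
        bend_amp = params.tail_amp_deg * beat * np.sin(np.pi * (t + 0.5) / n)
    else:
        # single C-/O-like bend developing over the turn, then a damped
        # counter-flexion oscillation while the body straightens
        amp = math.copysign(params.tail_amp_deg, total)
        bend_amp = amp * np.sin(np.pi * np.clip((t + 1) / max(ttp, 1), 0, 1))
        after = t >= ttp
        ta = t[after] - ttp
        bend_amp[after] = (
            0.3
            * amp
            * np.sin(2 * np.pi * 12.0 * ta / config.fps)
            * np.exp(-3.0 * ta / max(n - ttp, 1))
        )
    return _BoutPlan(label, start, n, speed, dheading, bend_amp)


def _resolve_schedule(
    schedule, config: SyntheticConfig, rng: np.random.Generator
) -> list[tuple[int, ArchetypeParams, int | None]]:
    """Normalize a schedule to sorted (start_frame, params, duration)."""
    if isinstance(schedule, str) and schedule == "random":
        return _random_schedule(config, rng)
    out = []
    for start_s, arch in schedule:
        params = ARCHETYPES[arch] if isinstance(arch, str) else arch
        out.append((int(round(start_s * config.fps)), params, None))
    return sorted(out, key=lambda x: x[0])


#: spontaneous movement-bout mix (scoot-dominated exploratory swimming)
_SPONTANEOUS_MIX = (("scoot", 0.61), ("turn", 0.28), ("AsLB", 0.056),
                    ("VsLB", 0.054))


def _random_schedule(config, rng):
    """~1 movement bout per second with a scoot/turn-dominated mix."""
    out = []
    t = int(rng.integers(0, 40))
    labels = [m[0] for m in _SPONTANEOUS_MIX]
    probs = np.array([m[1] for m in _SPONTANEOUS_MIX])
    probs /= probs.sum()
    T = config.n_frames
    while t < T - 45:
        label = labels[rng.choice(len(labels), p=probs)]
        params = ARCHETYPES[label]
        dur = int(rng.integers(params.duration_frames[0],
                               params.duration_frames[1] + 1))
        if t + dur >= T:
            break
        out.append((t, params, dur))
        t += dur + int(rng.integers(60, 260))  # exponentialish gaps
    return out


def generate_track(
    schedule,
    config: SyntheticConfig,
    seed: int | None = None,
    events: list[StimulusEvent] | None = None,
    well_id: str = "synthetic",
) -> tuple[PoseTrack, np.ndarray]:
    """Simulate one acquisition; returns (track, per-frame label array).

    ``schedule`` is either the string ``"random"`` or a list of
    ``(start_s, archetype)`` pairs where archetype is a label or an
    :class:`ArchetypeParams`.  Frames outside scheduled bouts are
    stationary (jitter only); the heading reflects specularly off the well
    wall.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    T = config.n_frames
    entries = _resolve_schedule(schedule, config, rng)
    plans: list[_BoutPlan] = []
    for start, params, dur in entries:
        plan = _plan_bout(params.label, start, params, config, rng, dur)
        if plan.end > T:
            raise ScheduleError(
                f"bout {params.label!r} at frame {start} ends at "
                f"{plan.end} > acquisition length {T}"
            )
        if plans and plan.start < plans[-1].end:
            raise ScheduleError(
                f"bout {params.label!r} at frame {plan.start} overlaps the "
                f"previous bout ending at {plans[-1].end}"
            )
        plans.append(plan)

    labels = np.full(T, "stationary", dtype=object)
    speed = np.zeros(T)
    dheading = np.zeros(T)
    bend_amp = np.zeros(T)
    for p in plans:
        labels[p.start:p.end] = p.label
        speed[p.start:p.end] = p.speed
        dheading[p.start:p.end] = p.dheading
        bend_amp[p.start:p.end] = p.bend_amp

    r_max = config.well_radius_mm - config.body_length_mm / 2.0
    pos = rng.uniform(-0.4, 0.4, 2) * r_max
    heading = rng.uniform(-180.0, 180.0)
    coords = np.empty((T, N_KEYPOINTS, 2))
    for t in range(T):
        heading = heading + dheading[t]
        step = speed[t] / config.fps
        if step > 0:
            h = np.deg2rad(heading)
            new = pos + step * np.array([np.cos(h), np.sin(h)])
            if np.linalg.norm(new) > r_max:
                # specular reflection of the heading off the wall
                nhat = pos / max(np.linalg.norm(pos), 1e-9)
                d = np.array([np.cos(h), np.sin(h)])
                d = d - 2 * (d @ nhat) * nhat
                heading = math.degrees(math.atan2(d[1], d[0]))
                new = pos + step * d
                if np.linalg.norm(new) > r_max:
                    # still outside (shallow angle): slide along the wall
                    new = new / np.linalg.norm(new) * r_max
            pos = new
        coords[t] = body_pose(pos, heading, bend_amp[t] * _BEND_WEIGHTS, config)

    if config.noise_sigma_mm > 0:
        rho = config.noise_rho
        eps = rng.normal(
            0.0,
            config.noise_sigma_mm * math.sqrt(1 - rho**2),
            size=coords.shape,
        )
        noise = np.empty_like(eps)
        noise[0] = rng.normal(0.0, config.noise_sigma_mm, coords.shape[1:])
        for t in range(1, T):
            noise[t] = rho * noise[t - 1] + eps[t]
        coords = coords + noise

    px_mm = config.pixel_size_um / 1000.0
    coords_px = (coords + config.well_radius_mm) / px_mm
    track = PoseTrack(
        coords=coords_px,
        fps=config.fps,
        pixel_size=config.pixel_size_um,
        plate_format=config.plate_format,
        well_id=well_id,
        body_length=config.body_length_mm,
        events=list(events or []),
    )
    return track, labels


def generate_labeled_dataset(
    config: SyntheticConfig,
    n_per_class: int,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced, aligned, labeled behavior windows for supervised training.

    Stands in for a manually reviewed clip library: for each class the
    simulator synthesizes a short track containing one archetypal bout and
    extracts a 40-frame window that contains at least half the bout, at a
    random phase — the way a human labeller accepts any clip that clearly
    shows the behavior, not only clips that start on it.  Returns
    ``(windows, labels)`` with windows of shape (n, W, 8, 2), already
    egocentrically aligned, in pixels.  The class set follows the plate
    format (5 classes for 24-well; 4 for 96-well, where scoot and turn are
    merged into "movement").  Deterministic given the seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    W = features.DEFAULT_WINDOW
    out, labels = [], []
    for label in config.class_labels:
        for i in range(n_per_class):
            if label == "stationary":
                arch = None
            elif label == "movement":
                arch = ARCHETYPES["scoot" if i % 2 == 0 else "turn"]
            else:
                arch = ARCHETYPES[label]
            out.append(_one_window(arch, config, rng, W))
            labels.append(label)
    return np.stack(out), np.asarray(labels, dtype=object)


def _one_window(
    arch: ArchetypeParams | None,
    config: SyntheticConfig,
    rng: np.random.Generator,
    W: int,
) -> np.ndarray:
    """One aligned W-frame window; bout (if any) >= half inside the window."""
    if arch is None:
        seg_frames = W + 1
        bout = []
        w_start = 0
    else:
        lo, hi = arch.duration_frames
        dur = int(rng.integers(lo, min(hi, W) + 1))
        ttp = arch.time_to_peak_frames[1]
        w_start = W  # window start inside a long-enough segment
        # the clip must show the behavior: keep the bend phase and at
        # least half the bout inside the window, at a random phase
        r_max = W - max(min(ttp, dur), (dur + 1) // 2)
        offset = int(rng.integers(-2, r_max + 1))
        b_start = w_start + offset
        seg_frames = max(w_start + W + 1, b_start + dur + 1)
        bout = [(b_start / config.fps, replace(arch, duration_frames=(dur, dur)))]
    cfg = replace(config, seconds=seg_frames / config.fps)
    track, _ = generate_track(
        bout, cfg, seed=int(rng.integers(2**31)), well_id="clip"
    )
    arr, usable = features._window_stack(track, W)
    return features.align_stack(arr[w_start:w_start + 1])[0]
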