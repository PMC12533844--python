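"""Windowing, egocentric alignment, and feature-vector construction.

A track of T frames is cut into overlapping fixed-width behavior windows
(default W = 40 frames, i.e. 250 ms at 160 fps).  Each window is put in a
body-centred frame by one rigid transform computed from its first frame:
rotate about the frame-0 body-center keypoint so the center->snout vector
points along +y, then translate the center to the origin; the same
transform is applied to all W frames.  Aligned windows are flattened
(timepoint-major, then keypoint, then x, y) to W*8*2-dimensional vectors
and normalized with two dataset-level scalars: divide by the maximum
absolute coordinate, then subtract the mean of the scaled data.

The windowing convention yields T - W windows with starts 0 .. T-W-1 (a
1600-frame acquisition gives 1560 windows).  A window overlapping any
masked keypoint is kept but flagged ``usable=False``; unusable windows are
excluded from normalization statistics and from inference.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .pose_io import CENTER, N_KEYPOINTS, SNOUT, PoseTrack

DEFAULT_WINDOW = 40


class WindowingError(ValueError):
    pass


class DegeneratePoseError(ValueError):
    """Frame-0 center and snout coincide; no heading can be defined."""


class NormalizationError(ValueError):
    pass


@dataclass
class BehaviorWindow:
    """One W-frame slice of a track, optionally egocentrically aligned."""

    start: int
    coords: np.ndarray  # (W, 8, 2)
    aligned: bool = False
    usable: bool = True

    @property
    def width(self) -> int:
        return self.coords.shape[0]


@dataclass
class FeatureMatrix:
    """Flattened normalized windows plus the scalars that produced them.

    ``norm_max``/``norm_mean`` are frozen at training time and shipped in
    the classifier bundle so inference reproduces training-time scaling.
    """

    vectors: np.ndarray  # (n_windows, W*8*2)
    norm_max: float
    norm_mean: float
    window_starts: np.ndarray
    usable: np.ndarray
    width: int = DEFAULT_WINDOW
    plate_format: int | None = None


def make_windows(track: PoseTrack, width: int = DEFAULT_WINDOW) -> list[BehaviorWindow]:
    """Cut a track into its T - W overlapping behavior windows.

    Raises :class:`WindowingError` when the track is shorter than W + 1
    frames (the convention requires at least one spare frame past the last
    window).
    """
    T = track.n_frames
    if T <= width:
        raise WindowingError(
            f"track has {T} frames; windowing needs at least {width + 1}"
        )
    arr, usable = _window_stack(track, width)
    return [
        BehaviorWindow(start=s, coords=arr[s].copy(), usable=bool(usable[s]))
        for s in range(T - width)
    ]


def _window_stack(track: PoseTrack, width: int) -> tuple[np.ndarray, np.ndarray]:
    """(N, W, 8, 2) window view and per-window usability, N = T - W."""
    T = track.n_frames
    n = T - width
    arr = sliding_window_view(track.coords, width, axis=0)  # (T-W+1, 8, 2, W)
    arr = np.moveaxis(arr, -1, 1)[:n]
    frame_bad = track.missing.any(axis=1)
    bad = sliding_window_view(frame_bad, width)[:n].any(axis=1)
    return arr, ~bad


def egocentric_align(window: BehaviorWindow) -> BehaviorWindow:
    """Rigidly align one window to its frame-0 body axis.

    After alignment the frame-0 center keypoint sits at the origin and the
    frame-0 snout on the +y axis at its original distance from the center.
    Alignment preserves all intra-frame pairwise distances and is
    idempotent.
    """
    center0 = window.coords[0, CENTER]
    snout0 = window.coords[0, SNOUT]
    v = snout0 - center0
    norm = np.hypot(*v)
    if norm == 0 or not np.isfinite(norm):
        raise DegeneratePoseError(
            f"window at start {window.start}: frame-0 center and snout "
            "coincide; cannot define heading"
        )
    out = align_stack(window.coords[None])[0]
    return replace(window, coords=out, aligned=True)


def align_stack(stack: np.ndarray) -> np.ndarray:
    """Vectorized egocentric alignment of an (N, W, 8, 2) window stack.

    Degenerate windows (zero-length frame-0 heading vector) come back
    unshifted-rotation-free; callers should have flagged them unusable.
    """
    center0 = stack[:, 0, CENTER]  # (N, 2)
    snout0 = stack[:, 0, SNOUT]
    v = snout0 - center0
    norm = np.linalg.norm(v, axis=-1)
    safe = np.where(norm > 0, norm, 1.0)
    # rotation taking v to +y: R = [[vy, -vx], [vx, vy]] / |v|
    vx, vy = v[:, 0] / safe, v[:, 1] / safe
    rot = np.empty((stack.shape[0], 2, 2))
    rot[:, 0, 0] = vy
    rot[:, 0, 1] = -vx
    rot[:, 1, 0] = vx
    rot[:, 1, 1] = vy
    shifted = stack - center0[:, None, None, :]
    return np.einsum("nij,nwkj->nwki", rot, shifted)


def flatten_windows(coords: np.ndarray) -> np.ndarray:
    """Flatten (..., W, 8, 2) aligned coords to (..., W*8*2) vectors.

    Order is timepoint-major, then keypoint, then (x, y); recorded in the
    classifier bundle so models are portable.
    """
    return np.asarray(coords).reshape(*coords.shape[:-3], -1)


def unflatten_windows(vectors: np.ndarray, width: int = DEFAULT_WINDOW) -> np.ndarray:
    """Inverse of :func:`flatten_windows`."""
    return np.asarray(vectors).reshape(
        *vectors.shape[:-1], width, N_KEYPOINTS, 2
    )


def featurize(
    windows: list[BehaviorWindow],
    stats: tuple[float, float] | None = None,
    plate_format: int | None = None,
) -> FeatureMatrix:
    """Flatten and normalize aligned windows into a feature matrix.

    With ``stats=None`` the two scalars are computed over the usable
    windows — ``norm_max`` is the maximum absolute coordinate and
    ``norm_mean`` the mean of the max-scaled coordinates — and stored for
    reuse; passing stored ``(norm_max, norm_mean)`` reproduces
    training-time scaling at inference.  Every coordinate is transformed as
    ``v / norm_max - norm_mean``.
    """
    if not windows:
        raise WindowingError("no windows to featurize")
    if not all(w.aligned for w in windows):
        raise WindowingError("featurize requires aligned windows")
    width = windows[0].width
    stack = np.stack([w.coords for w in windows])
    usable = np.array([w.usable for w in windows], dtype=bool)
    starts = np.array([w.start for w in windows])
    vectors, norm_max, norm_mean = _normalize_stack(stack, usable, stats)
    return FeatureMatrix(
        vectors=vectors,
        norm_max=norm_max,
        norm_mean=norm_mean,
        window_starts=starts,
        usable=usable,
        width=width,
        plate_format=plate_format,
    )


def _normalize_stack(
    stack: np.ndarray,
    usable: np.ndarray,
    stats: tuple[float, float] | None,
) -> tuple[np.ndarray, float, float]:
    if stats is None:
        if not usable.any():
            raise NormalizationError("no usable windows to compute stats from")
        norm_max = float(np.abs(stack[usable]).max())
        if norm_max == 0:
            raise NormalizationError("all-zero coordinates; norm_max is 0")
        norm_mean = float((stack[usable] / norm_max).mean())
    else:
        norm_max, norm_mean = float(stats[0]), float(stats[1])
        if norm_max == 0:
            raise NormalizationError("norm_max must be nonzero")
    vectors = flatten_windows(stack) / norm_max - norm_mean
    return vectors, norm_max, norm_mean


def featurize_track(
    track: PoseTrack,
    stats: tuple[float, float] | None = None,
    width: int = DEFAULT_WINDOW,
) -> FeatureMatrix:
    """Track -> aligned, normalized feature matrix in one vectorized pass.

    Equivalent to ``featurize([egocentric_align(w) for w in
    make_windows(track, width)], stats)`` but avoids per-window Python
    overhead; the equivalence is exercised in the test suite.  Windows with
    a degenerate frame-0 pose are flagged unusable rather than raising.
    """
    T = track.n_frames
    if T <= width:
        raise WindowingError(
            f"track has {T} frames; windowing needs at least {width + 1}"
        )
    arr, usable = _window_stack(track, width)
    v = arr[:, 0, SNOUT] - arr[:, 0, CENTER]
    usable = usable & (np.linalg.norm(v, axis=-1) > 0)
    aligned = align_stack(arr)
    vectors, norm_max, norm_mean = _normalize_stack(aligned, usable, stats)
    return FeatureMatrix(
        vectors=vectors,
        norm_max=norm_max,
        norm_mean=norm_mean,
        window_starts=np.arange(T - width),
        usable=usable,
        width=width,
        plate_format=track.plate_format,
    )
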