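"""Majority-vote smoothing of window calls and bout segmentation.

Sliding-window classification produces one call per window start, not per
frame, and raw window calls can flicker frame-to-frame in a way no real
larva moves.  Majority voting aggregates, for each frame t, the calls of
every window overlapping t (starts in [t-W+1, t], clipped to valid starts)
and assigns the most frequent call.  Ties break deterministically by class
order, stationary first, so ties default to the least eventful call.
Frames covered by no usable window are "unknown".

Bouts are maximal runs of identical frame calls strictly longer than
``min_run`` (default 5) frames; shorter runs stay as unlabeled gaps and
are never merged into neighbors.  An "unknown" frame always terminates a
run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

UNKNOWN = "unknown"
STATIONARY = "stationary"


@dataclass
class FrameLabels:
    """Per-frame behavior calls after majority voting."""

    labels: np.ndarray  # (T,) object array of class names / "unknown"
    margins: np.ndarray  # (T,) winner count minus runner-up count
    width: int  # source window width W

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


@dataclass(frozen=True)
class Bout:
    """A maximal same-label run of frame calls, with kinematic annotations."""

    label: str
    start: int
    end: int  # half-open
    fps: float
    duration_ms: float | None = None
    max_speed: float | None = None
    max_abs_dheading: float | None = None
    fish_id: str = ""
    trial_id: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("bout end must exceed start")


def majority_vote(
    window_labels,
    starts,
    width: int,
    n_frames: int,
    class_order,
) -> FrameLabels:
    """Aggregate per-window calls into per-frame calls by majority vote.

    Parameters
    ----------
    window_labels : sequence of str
        One call per window; ``"unknown"`` entries (unusable windows) do
        not vote.
    starts : sequence of int
        Window start frames, each in [0, n_frames - width].
    width : int
        Window width W; a window starting at s covers frames [s, s + W).
    n_frames : int
        Track length T.
    class_order : sequence of str
        Tie-break priority (earlier label wins a tie).
    """
    window_labels = np.asarray(window_labels, dtype=object)
    starts = np.asarray(starts, dtype=int)
    if starts.size and (starts.min() < 0 or starts.max() > n_frames - width):
        raise ValueError("window starts outside [0, T - W]")
    classes = [c for c in class_order if c != UNKNOWN]
    # counts[t, c] = number of voting windows with start in [t-W+1, t]
    counts = np.zeros((n_frames, len(classes)), dtype=np.int64)
    for ci, c in enumerate(classes):
        sel = starts[window_labels == c]
        if sel.size == 0:
            continue
        delta = np.zeros(n_frames + 1, dtype=np.int64)
        np.add.at(delta, sel, 1)
        ends = np.minimum(sel + width, n_frames)
        np.add.at(delta, ends, -1)
        counts[:, ci] = np.cumsum(delta[:-1])
    total = counts.sum(axis=1)
    # argmax takes the first maximum -> earlier class wins ties
    winner_idx = counts.argmax(axis=1)
    winner_count = counts[np.arange(n_frames), winner_idx]
    counts_wo = counts.copy()
    counts_wo[np.arange(n_frames), winner_idx] = -1
    runner_up = counts_wo.max(axis=1)
    labels = np.array(
        [classes[i] if t > 0 else UNKNOWN for i, t in zip(winner_idx, total)],
        dtype=object,
    )
    margins = np.where(total > 0, winner_count - np.maximum(runner_up, 0), 0)
    return FrameLabels(labels=labels, margins=margins, width=width)


def label_runs(labels) -> list[tuple[str, int, int]]:
    """Run-length encode a label sequence into (label, start, stop) runs."""
    labels = np.asarray(labels, dtype=object)
    runs = []
    start = 0
    for t in range(1, len(labels) + 1):
        if t == len(labels) or labels[t] != labels[start]:
            runs.append((labels[start], start, t))
            start = t
    return runs


def extract_bouts(
    frame_labels: FrameLabels,
    fps: float,
    min_run: int = 5,
    labels: list[str] | None = None,
    fish_id: str = "",
    trial_id: str = "",
) -> list[Bout]:
    """Segment frame calls into bouts: same-label runs strictly > min_run.

    By default only movement classes become bouts (stationary and unknown
    runs are excluded); pass ``labels=["stationary"]`` to collect
    stationary periods instead.  Runs of length <= min_run are dropped, not
    merged, so bouts plus gaps always partition the frame axis.
    """
    bouts = []
    for label, start, stop in label_runs(frame_labels.labels):
        if stop - start <= min_run:
            continue
        if label == UNKNOWN:
            continue
        if labels is None:
            if label == STATIONARY:
                continue
        elif label not in labels:
            continue
        bouts.append(
            Bout(
                label=label,
                start=start,
                end=stop,
                fps=fps,
                duration_ms=(stop - start) / fps * 1000.0,
                fish_id=fish_id,
                trial_id=trial_id,
            )
        )
    return bouts


def filter_bouts_by_interval(
    bouts: list[Bout], interval: tuple[int, int]
) -> list[Bout]:
    """Bouts whose half-open [start, end) intersects the half-open interval.

    Used for stimulus-locked analyses, e.g. keeping only bouts that
    surround a tap delivered at 5.0 s (frames [800, 840) at 160 fps).
    """
    a, b = interval
    return [bout for bout in bouts if bout.start < b and bout.end > a]
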