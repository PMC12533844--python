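"""Assay-level readouts: stimulus response rates and spontaneous summaries.

A trial "responds" to a stimulus when the elicited behavior (AsLB for
acoustic, VsLB for visual) is called at least once inside the stimulus
response window — 250 ms after a tap, 1.0 s after light-off, windows that
exceed the established latency of each response.  Rates are reported two
ways: the trial-level rate (responding trials over all trials) and the
fish-level responder rate (fish with at least one responding trial, out of
all fish — by construction the OR over that fish's trials).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pose_io import RESPONSE_WINDOW_S, StimulusEvent
from .smoothing import Bout, FrameLabels, filter_bouts_by_interval

#: elicited behavior per stimulus kind
TARGET_LABEL = {"acoustic": "AsLB", "visual": "VsLB"}


def response_window(event: StimulusEvent, fps: float) -> tuple[int, int]:
    """Half-open frame interval in which a response counts.

    Acoustic: [onset, onset + 0.25 s); visual: [onset, onset + 1.0 s).
    At 160 fps an onset of 5.0 s gives [800, 840) and [800, 960)
    respectively.  The onset frame is included.
    """
    if event.kind not in RESPONSE_WINDOW_S:
        raise ValueError(f"unknown stimulus kind {event.kind!r}")
    start = int(round(event.onset_s * fps))
    stop = int(round((event.onset_s + RESPONSE_WINDOW_S[event.kind]) * fps))
    return start, stop


def trial_response(
    calls: FrameLabels | list[Bout],
    event: StimulusEvent,
    fps: float,
    target_label: str | None = None,
    mode: str = "frames",
) -> bool:
    """Did this trial respond to the stimulus?

    ``mode="frames"`` — true iff at least one frame inside the response
    window carries the target label (default: the elicited behavior for
    the stimulus kind).  ``mode="bouts"`` — true iff a target-labeled bout
    overlaps the window; pass the bout list as ``calls`` in that case.
    """
    target = target_label or TARGET_LABEL[event.kind]
    a, b = response_window(event, fps)
    if mode == "frames":
        if not isinstance(calls, FrameLabels):
            raise TypeError("mode='frames' requires FrameLabels")
        return bool((calls.labels[a:b] == target).any())
    if mode == "bouts":
        bouts = [bt for bt in calls if bt.label == target]
        return bool(filter_bouts_by_interval(bouts, (a, b)))
    raise ValueError(f"unknown mode {mode!r}")


def make_response_table(records: list[dict]) -> pd.DataFrame:
    """Tidy response table from per-trial records.

    Each record needs ``fish_id``, ``trial_id``, ``stimulus`` and
    ``responded`` (bool).
    """
    df = pd.DataFrame.from_records(records)
    required = {"fish_id", "trial_id", "stimulus", "responded"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return df


def response_rates(table: pd.DataFrame) -> tuple[float, float]:
    """(trial-level rate, fish-level responder rate) from a response table.

    The fish-level responder flag is the OR over that fish's trials.
    """
    if table.empty:
        raise ValueError("empty response table")
    trial_rate = float(table["responded"].mean())
    fish_rate = float(table.groupby("fish_id")["responded"].any().mean())
    return trial_rate, fish_rate


def spontaneous_summary(
    bouts: list[Bout], total_frames: int, fps: float
) -> dict:
    """Per-class accounting of spontaneous movement bouts.

    Returns counts and proportions per class (over movement bouts),
    bouts per second, and the fraction of recorded time spent in movement
    bouts.
    """
    counts: dict[str, int] = {}
    frames_in_bouts = 0
    for b in bouts:
        counts[b.label] = counts.get(b.label, 0) + 1
        frames_in_bouts += b.end - b.start
    n = len(bouts)
    return {
        "n_bouts": n,
        "counts": counts,
        "proportions": {
            k: (v / n if n else 0.0) for k, v in counts.items()
        },
        "bouts_per_second": n / (total_frames / fps) if total_frames else 0.0,
        "time_in_movement": (
            frames_in_bouts / total_frames if total_frames else 0.0
        ),
    }
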