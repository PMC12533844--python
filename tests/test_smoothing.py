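"""Majority voting and bout segmentation against brute-force oracles."""

import numpy as np
import pytest

from fishbout.smoothing import (
    Bout,
    FrameLabels,
    extract_bouts,
    filter_bouts_by_interval,
    label_runs,
    majority_vote,
)

CLASSES = ("stationary", "scoot", "turn", "AsLB", "VsLB")


def brute_force_vote(window_labels, starts, W, T, class_order):
    """Independent oracle: enumerate overlapping windows per frame."""
    out = []
    for t in range(T):
        votes = {}
        for label, s in zip(window_labels, starts):
            if label == "unknown":
                continue
            if s <= t < s + W:
                votes[label] = votes.get(label, 0) + 1
        if not votes:
            out.append("unknown")
            continue
        best = max(votes.values())
        for c in class_order:  # earlier class wins ties
            if votes.get(c) == best:
                out.append(c)
                break
    return np.array(out, dtype=object)


def _vote(labels, W, T):
    starts = np.arange(len(labels))
    return majority_vote(labels, starts, W, T, CLASSES)


class TestMajorityVote:
    def test_unanimity(self):
        T, W = 60, 10
        labels = ["scoot"] * (T - W)
        fl = _vote(labels, W, T)
        # the last window starts at T-W-1 and covers up to frame T-2;
        # the final frame is uncovered under the T-W convention
        assert (fl.labels[:-1] == "scoot").all()
        assert fl.labels[-1] == "unknown"
        # margin equals the coverage count (fewer windows near the edges)
        assert fl.margins[0] == 1
        assert fl.margins[W - 1] == W
        assert fl.margins[T - W - 1] == W

    def test_single_flipped_window_removed(self):
        T, W = 120, 40
        labels = np.array(["scoot"] * (T - W), dtype=object)
        labels[40] = "turn"  # flanked by >= W consistent windows
        fl = _vote(labels, W, T)
        assert not (fl.labels == "turn").any()

    def test_spec_worked_example(self):
        # T=50, W=10; windows 0-9 labeled A, 10-40 labeled B; frame 15
        # sees starts 6..15: 4 x A vs 6 x B -> B
        T, W = 50, 10
        labels = ["scoot"] * 10 + ["turn"] * 31
        fl = _vote(labels, W, T)
        assert fl.labels[15] == "turn"
        assert fl.margins[15] == 2

    def test_matches_brute_force_on_random_sequences(self, rng):
        for _ in range(300):
            T = int(rng.integers(12, 60))
            W = int(rng.integers(2, min(T, 12)))
            n = T - W
            labels = rng.choice(
                np.array(list(CLASSES) + ["unknown"], dtype=object), size=n
            )
            fl = _vote(labels, W, T)
            expected = brute_force_vote(labels, np.arange(n), W, T, CLASSES)
            np.testing.assert_array_equal(fl.labels, expected)

    def test_strict_majority_always_wins(self, rng):
        for _ in range(50):
            T, W = 80, 16
            labels = rng.choice(
                np.array(CLASSES, dtype=object), size=T - W
            )
            fl = _vote(labels, W, T)
            for t in range(T):
                lo, hi = max(0, t - W + 1), min(t, T - W - 1)
                if hi < lo:  # uncovered tail frame
                    assert fl.labels[t] == "unknown"
                    continue
                overlapping = labels[lo:hi + 1]
                vals, counts = np.unique(overlapping, return_counts=True)
                if counts.max() > len(overlapping) / 2:
                    assert fl.labels[t] == vals[counts.argmax()]

    def test_never_invents_labels(self, rng):
        T, W = 70, 12
        labels = rng.choice(
            np.array(["scoot", "turn"], dtype=object), size=T - W
        )
        fl = _vote(labels, W, T)
        for t in range(T):
            lo, hi = max(0, t - W + 1), min(t, T - W - 1)
            if hi < lo:
                assert fl.labels[t] == "unknown"
                continue
            assert fl.labels[t] in set(labels[lo:hi + 1])

    def test_call_within_W_frames_of_a_source_window(self, rng):
        T, W = 100, 20
        labels = rng.choice(np.array(CLASSES, dtype=object), size=T - W)
        fl = _vote(labels, W, T)
        for t in range(T):
            c = fl.labels[t]
            lo, hi = max(0, t - W + 1), min(t, T - W - 1)
            if hi < lo:
                assert c == "unknown"
                continue
            # the winning call originates from a window < W frames away
            assert (labels[lo:hi + 1] == c).any()

    def test_uncovered_frames_unknown(self):
        fl = majority_vote(["scoot"], [0], 5, 20, CLASSES)
        assert (fl.labels[:5] == "scoot").all()
        assert (fl.labels[5:] == "unknown").all()

    def test_tie_breaks_by_class_order(self):
        # one stationary and one scoot window covering the same frames
        fl = majority_vote(["scoot", "stationary"], [0, 0], 4, 5, CLASSES)
        assert (fl.labels[:4] == "stationary").all()
        assert (fl.margins[:4] == 0).all()

    def test_out_of_range_starts_rejected(self):
        with pytest.raises(ValueError):
            majority_vote(["scoot"], [17], 5, 20, CLASSES)


def _fl(labels, W=40):
    labels = np.asarray(labels, dtype=object)
    return FrameLabels(
        labels=labels, margins=np.zeros(len(labels), dtype=int), width=W
    )


class TestExtractBouts:
    def test_short_run_dropped_not_merged(self):
        labels = ["scoot"] * 10 + ["turn"] * 3 + ["scoot"] * 10
        bouts = extract_bouts(_fl(labels), fps=160.0)
        assert [b.label for b in bouts] == ["scoot", "scoot"]
        assert [(b.start, b.end) for b in bouts] == [(0, 10), (13, 23)]

    def test_six_frame_bout_duration_37_5_ms(self):
        labels = ["stationary"] * 4 + ["AsLB"] * 6 + ["stationary"] * 4
        bouts = extract_bouts(_fl(labels), fps=160.0)
        assert len(bouts) == 1
        assert bouts[0].duration_ms == pytest.approx(37.5)

    def test_exactly_min_run_is_not_a_bout(self):
        labels = ["stationary"] * 6 + ["turn"] * 5 + ["stationary"] * 6
        assert extract_bouts(_fl(labels), fps=160.0, min_run=5) == []

    def test_stationary_collected_separately(self):
        labels = ["stationary"] * 10 + ["scoot"] * 10
        movement = extract_bouts(_fl(labels), fps=160.0)
        stationary = extract_bouts(
            _fl(labels), fps=160.0, labels=["stationary"]
        )
        assert [b.label for b in movement] == ["scoot"]
        assert [b.label for b in stationary] == ["stationary"]

    def test_unknown_terminates_runs(self):
        labels = ["scoot"] * 6 + ["unknown"] + ["scoot"] * 6
        bouts = extract_bouts(_fl(labels), fps=160.0)
        assert [(b.start, b.end) for b in bouts] == [(0, 6), (7, 13)]

    def test_matches_run_length_oracle(self, rng):
        for _ in range(200):
            T = int(rng.integers(10, 120))
            labels = rng.choice(
                np.array(
                    ["stationary", "scoot", "turn", "AsLB", "unknown"],
                    dtype=object,
                ),
                size=T,
                p=[0.3, 0.3, 0.2, 0.1, 0.1],
            )
            bouts = extract_bouts(_fl(labels), fps=160.0, min_run=5)
            expected = [
                (lab, a, b)
                for lab, a, b in label_runs(labels)
                if b - a > 5 and lab not in ("stationary", "unknown")
            ]
            assert [(b.label, b.start, b.end) for b in bouts] == expected

    def test_runs_partition_sequence(self, rng):
        labels = rng.choice(
            np.array(["scoot", "turn"], dtype=object), size=200
        )
        runs = label_runs(labels)
        rebuilt = np.concatenate(
            [np.full(b - a, lab, dtype=object) for lab, a, b in runs]
        )
        np.testing.assert_array_equal(rebuilt, labels)
        assert runs[0][1] == 0 and runs[-1][2] == 200
        for (_, _, b1), (_, a2, _) in zip(runs, runs[1:]):
            assert b1 == a2


class TestFilterBoutsByInterval:
    def _bout(self, start, end):
        return Bout(label="AsLB", start=start, end=end, fps=160.0)

    def test_overlapping_bout_kept(self):
        # tap window 5.0-5.25 s at 160 fps = frames [800, 840)
        assert filter_bouts_by_interval(
            [self._bout(790, 820)], (800, 840)
        )

    def test_disjoint_bout_dropped(self):
        assert not filter_bouts_by_interval(
            [self._bout(0, 100)], (800, 840)
        )

    def test_bout_ending_at_interval_start_dropped(self):
        assert not filter_bouts_by_interval(
            [self._bout(700, 800)], (800, 840)
        )

    def test_bout_starting_at_interval_end_dropped(self):
        assert not filter_bouts_by_interval(
            [self._bout(840, 900)], (800, 840)
        )


def test_bout_requires_positive_length():
    with pytest.raises(ValueError):
        Bout(label="scoot", start=5, end=5, fps=160.0)
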