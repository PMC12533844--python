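"""Shared fixtures: synthetic tracks and a trained classifier bundle.

The heavier fixtures are session-scoped so the synthetic benchmark
(dataset generation + PCA/forest training) is paid for once and reused by
the unit and acceptance tests alike.
"""

from dataclasses import replace

import numpy as np
import pytest

import fishbout as fb
from fishbout import classify, features


@pytest.fixture(scope="session")
def cfg24():
    """Default 24-well acquisition config (160 fps, 10 s)."""
    return fb.SyntheticConfig(plate_format=24, seed=0)


@pytest.fixture(scope="session")
def short_track(cfg24):
    """A 3-second track with one scoot and one turn, plus ground truth."""
    cfg = replace(cfg24, seconds=3.0)
    track, labels = fb.generate_track(
        [(0.5, "scoot"), (2.0, "turn")], cfg, seed=5
    )
    return track, labels


def _featurize_windows(windows, plate_format):
    return fb.featurize(
        [
            features.BehaviorWindow(start=i, coords=w, aligned=True)
            for i, w in enumerate(windows)
        ],
        plate_format=plate_format,
    )


@pytest.fixture(scope="session")
def bench24():
    """The synthetic 24-well benchmark: dataset, split, bundle, report.

    Conditions: 200 windows per class, default noise, seed 2023, 90/10
    stratified split, PCA(0.95, random state 2023) + random forest.
    """
    cfg = fb.SyntheticConfig(plate_format=24)
    windows, labels = fb.generate_labeled_dataset(cfg, 200, seed=2023)
    fm = _featurize_windows(windows, 24)
    X_tr, X_te, y_tr, y_te = classify.split_dataset(
        fm.vectors, labels, 0.9, seed=2023
    )
    bundle = classify.train(
        X_tr,
        y_tr,
        classify.ClassSet.for_plate(24),
        stats=(fm.norm_max, fm.norm_mean),
        rfc_seed=2023,
    )
    report = classify.evaluate(bundle, X_te, y_te)
    return {
        "config": cfg,
        "windows": windows,
        "labels": labels,
        "fm": fm,
        "split": (X_tr, X_te, y_tr, y_te),
        "bundle": bundle,
        "report": report,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)
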