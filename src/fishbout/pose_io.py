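"""Pose-track containers and on-disk formats.

A :class:`PoseTrack` holds the per-frame 8-keypoint pose of a single larva
in a single well, together with the acquisition metadata every downstream
stage needs (frame rate, pixel size, plate format, stimulus events).

Coordinate conventions
----------------------
On disk, keypoint positions are stored as image ``(row, col)`` pairs — the
native order emitted by pose-estimation software.  In memory all coordinates
are right-handed Cartesian ``(x, y)`` with ``x = col`` and ``y = -row`` so
that "up" in the well image is the +y direction.  The conversion happens
exactly once, on read, and is inverted on write; round-tripping a track
through either dialect is the identity.

Two dialects are supported:

* HDF5 — datasets ``coords`` (frame, keypoint, [row, col]) and ``missing``
  (frame, keypoint), file attributes for the metadata, and an ``events``
  group with one subgroup per stimulus event.
* CSV (long form) — columns ``acquisition_id, frame, keypoint, row_px,
  col_px, missing`` plus a JSON sidecar (``<path>.json``) for metadata and
  events.

Frames are 0-based throughout; intervals are half-open ``[start, stop)``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_KEYPOINTS = 8
#: keypoint indices, snout -> caudal tail tip
SNOUT, CENTER, CAUDAL_BASE, CAUDAL_TIP = 0, 3, 6, 7

#: default stimulus durations (s): 0.1 s tap, 2.0 s light-off
STIMULUS_DURATION_S = {"acoustic": 0.1, "visual": 2.0}
#: default response-window lengths (s) implied by stimulus kind
RESPONSE_WINDOW_S = {"acoustic": 0.25, "visual": 1.0}


class SchemaError(ValueError):
    """A pose file or track violates the 8-keypoint schema."""


class FormatError(ValueError):
    """A pose file is malformed (names the first violated field)."""


@dataclass(frozen=True)
class StimulusEvent:
    """A stimulus delivered during an acquisition.

    Parameters
    ----------
    kind : {"acoustic", "visual"}
    onset_s : float
        Seconds from acquisition start (>= 0).
    duration_s : float, optional
        Stimulus duration; defaults to 0.1 s for acoustic (tap) and 2.0 s
        for visual (light-off).
    """

    kind: str
    onset_s: float
    duration_s: float | None = None

    def __post_init__(self):
        if self.kind not in STIMULUS_DURATION_S:
            raise FormatError(f"unknown stimulus kind {self.kind!r}")
        if self.onset_s < 0:
            raise FormatError("event onset_s must be >= 0")
        if self.duration_s is None:
            object.__setattr__(
                self, "duration_s", STIMULUS_DURATION_S[self.kind]
            )


@dataclass
class PoseTrack:
    """Per-frame 8-keypoint pose of one fish plus acquisition metadata.

    Attributes
    ----------
    coords : (T, 8, 2) float array
        Cartesian ``(x, y)`` keypoint positions in pixels (see module notes
        on the row/col <-> x/y conversion).
    missing : (T, 8) bool array
        True where the keypoint was not observed; coords under the mask are
        carried but must not be interpreted.
    fps : float
        Acquisition frame rate (Hz).
    pixel_size : float
        Micrometres per pixel.
    plate_format : int
        24 or 96.
    well_id : str
    body_length : float or None
        Body length in mm, if known.
    events : list of StimulusEvent
    """

    coords: np.ndarray
    fps: float
    pixel_size: float
    plate_format: int
    well_id: str = ""
    body_length: float | None = None
    events: list[StimulusEvent] = field(default_factory=list)
    missing: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (N_KEYPOINTS, 2):
            raise SchemaError(
                f"coords must have shape (T, {N_KEYPOINTS}, 2), "
                f"got {self.coords.shape}"
            )
        if self.missing is None:
            self.missing = np.zeros(self.coords.shape[:2], dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        if self.missing.shape != self.coords.shape[:2]:
            raise SchemaError(
                f"missing mask shape {self.missing.shape} does not match "
                f"coords {self.coords.shape[:2]}"
            )
        if not self.fps > 0:
            raise SchemaError("fps must be > 0")
        if not self.pixel_size > 0:
            raise SchemaError("pixel_size must be > 0")
        if int(self.plate_format) not in (24, 96):
            raise SchemaError(
                f"plate_format must be 24 or 96, got {self.plate_format}"
            )
        self.plate_format = int(self.plate_format)
        if not np.all(np.isfinite(self.coords[~self.missing])):
            raise SchemaError("non-masked coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def copy(self) -> "PoseTrack":
        return replace(
            self,
            coords=self.coords.copy(),
            missing=self.missing.copy(),
            events=list(self.events),
        )


def _cartesian_from_rowcol(rowcol: np.ndarray) -> np.ndarray:
    out = np.empty_like(rowcol)
    out[..., 0] = rowcol[..., 1]
    out[..., 1] = -rowcol[..., 0]
    return out


def _rowcol_from_cartesian(xy: np.ndarray) -> np.ndarray:
    out = np.empty_like(xy)
    out[..., 0] = -xy[..., 1]
    out[..., 1] = xy[..., 0]
    return out


def _infer_dialect(path: Path) -> str:
    if path.suffix.lower() in (".h5", ".hdf5", ".nc"):
        return "hdf5"
    if path.suffix.lower() == ".csv":
        return "csv"
    raise FormatError(f"cannot infer dialect from suffix {path.suffix!r}")


def write_pose_track(
    track: PoseTrack, path: str | Path, dialect: str | None = None
) -> Path:
    """Write a track in the HDF5 or long-form CSV dialect.

    The dialect is inferred from the suffix when not given.  CSV output adds
    a ``<path>.json`` metadata sidecar.
    """
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    rowcol = _rowcol_from_cartesian(track.coords)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("coords", data=rowcol)
            f.create_dataset("missing", data=track.missing)
            f.attrs["fps"] = track.fps
            f.attrs["pixel_size_um"] = track.pixel_size
            f.attrs["plate_format"] = track.plate_format
            f.attrs["well_id"] = track.well_id
            if track.body_length is not None:
                f.attrs["body_length_mm"] = track.body_length
            g = f.create_group("events")
            for i, ev in enumerate(track.events):
                eg = g.create_group(f"event_{i}")
                eg.attrs["kind"] = ev.kind
                eg.attrs["onset_s"] = ev.onset_s
                eg.attrs["duration_s"] = ev.duration_s
    elif dialect == "csv":
        T = track.n_frames
        frames = np.repeat(np.arange(T), N_KEYPOINTS)
        kps = np.tile(np.arange(N_KEYPOINTS), T)
        df = pd.DataFrame(
            {
                "acquisition_id": track.well_id,
                "frame": frames,
                "keypoint": kps,
                "row_px": rowcol[..., 0].ravel(),
                "col_px": rowcol[..., 1].ravel(),
                "missing": track.missing.ravel().astype(int),
            }
        )
        # 17 significant digits: float64 round-trips exactly through text
        df.to_csv(path, index=False, float_format="%.17g")
        meta = {
            "fps": track.fps,
            "pixel_size_um": track.pixel_size,
            "plate_format": track.plate_format,
            "well_id": track.well_id,
            "body_length_mm": track.body_length,
            "events": [
                {"kind": e.kind, "onset_s": e.onset_s, "duration_s": e.duration_s}
                for e in track.events
            ],
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    return path


def read_pose_track(path: str | Path, dialect: str | None = None) -> PoseTrack:
    """Read and validate a pose track written by :func:`write_pose_track`.

    Raises
    ------
    FormatError
        Malformed file; the message names the first violated field.
    SchemaError
        Structurally valid file whose contents violate the 8-keypoint
        schema (e.g. a CSV with 9 keypoints per frame).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            for name in ("coords", "missing"):
                if name not in f:
                    raise FormatError(f"missing dataset {name!r}")
            rowcol = np.asarray(f["coords"], dtype=np.float64)
            missing = np.asarray(f["missing"], dtype=bool)
            for attr in ("fps", "pixel_size_um", "plate_format"):
                if attr not in f.attrs:
                    raise FormatError(f"missing attribute {attr!r}")
            events = []
            if "events" in f:
                for key in sorted(f["events"]):
                    eg = f["events"][key]
                    events.append(
                        StimulusEvent(
                            kind=str(eg.attrs["kind"]),
                            onset_s=float(eg.attrs["onset_s"]),
                            duration_s=float(eg.attrs["duration_s"]),
                        )
                    )
            meta = dict(
                fps=float(f.attrs["fps"]),
                pixel_size=float(f.attrs["pixel_size_um"]),
                plate_format=int(f.attrs["plate_format"]),
                well_id=str(f.attrs.get("well_id", "")),
                body_length=(
                    float(f.attrs["body_length_mm"])
                    if "body_length_mm" in f.attrs
                    else None
                ),
            )
    elif dialect == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
        required = {"frame", "keypoint", "row_px", "col_px", "missing"}
        missing_cols = required - set(df.columns)
        if missing_cols:
            raise FormatError(f"missing column {sorted(missing_cols)[0]!r}")
        kp_per_frame = df.groupby("frame")["keypoint"].nunique()
        if not (kp_per_frame == N_KEYPOINTS).all():
            bad = kp_per_frame[kp_per_frame != N_KEYPOINTS].index[0]
            raise SchemaError(
                f"frame {bad} has {kp_per_frame[bad]} keypoints, "
                f"expected {N_KEYPOINTS}"
            )
        df = df.sort_values(["frame", "keypoint"])
        T = df["frame"].nunique()
        rowcol = np.column_stack(
            [df["row_px"].to_numpy(), df["col_px"].to_numpy()]
        ).reshape(T, N_KEYPOINTS, 2)
        missing = (
            df["missing"].to_numpy().astype(bool).reshape(T, N_KEYPOINTS)
        )
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise FormatError(f"missing metadata sidecar {sidecar.name!r}")
        md = json.loads(sidecar.read_text())
        for key in ("fps", "pixel_size_um", "plate_format"):
            if key not in md:
                raise FormatError(f"missing metadata field {key!r}")
        events = [
            StimulusEvent(e["kind"], e["onset_s"], e.get("duration_s"))
            for e in md.get("events", [])
        ]
        meta = dict(
            fps=float(md["fps"]),
            pixel_size=float(md["pixel_size_um"]),
            plate_format=int(md["plate_format"]),
            well_id=str(md.get("well_id", "")),
            body_length=md.get("body_length_mm"),
        )
    else:
        raise FormatError(f"unknown dialect {dialect!r}")

    # NaNs under the mask are legitimate; mark any unmasked NaN as missing
    nan_mask = ~np.isfinite(rowcol).all(axis=-1)
    missing = missing | nan_mask
    xy = _cartesian_from_rowcol(rowcol)
    xy[missing] = np.nan_to_num(xy[missing])
    return PoseTrack(coords=xy, missing=missing, events=events, **meta)


def clean_track(track: PoseTrack, max_gap: int = 5) -> PoseTrack:
    """Fill short tracking dropouts by linear interpolation.

    Interior masked runs of length <= ``max_gap`` frames are linearly
    interpolated per keypoint per coordinate and unmasked; longer runs (and
    runs touching the track edges, which have no flanking observation) stay
    masked so downstream windowing can flag them unusable.  Non-masked
    coordinates are never altered.
    """
    out = track.copy()
    if out.missing.all():
        logger.warning("clean_track: all keypoints masked; returning unchanged")
        return out
    T = out.n_frames
    frames = np.arange(T)
    for k in range(N_KEYPOINTS):
        mask = out.missing[:, k]
        if not mask.any():
            continue
        obs = np.flatnonzero(~mask)
        if obs.size < 2:
            continue
        # walk masked runs; interpolate those bracketed by observations
        runs = _mask_runs(mask)
        for start, stop in runs:
            gap = stop - start
            if gap > max_gap or start == 0 or stop == T:
                continue
            for c in range(2):
                out.coords[start:stop, k, c] = np.interp(
                    frames[start:stop],
                    [start - 1, stop],
                    [out.coords[start - 1, k, c], out.coords[stop, k, c]],
                )
            out.missing[start:stop, k] = False
    return out


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a 1-D boolean array."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def write_labels(labels: Sequence[str], path: str | Path) -> Path:
    """Write per-frame labels as the two-column ``frame,label`` CSV."""
    path = Path(path)
    pd.DataFrame(
        {"frame": np.arange(len(labels)), "label": list(labels)}
    ).to_csv(path, index=False)
    return path


def read_labels(path: str | Path) -> np.ndarray:
    """Read a ``frame,label`` CSV back to a per-frame label array."""
    df = pd.read_csv(Path(path))
    for col in ("frame", "label"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r}")
    return df.sort_values("frame")["label"].to_numpy(dtype=object)
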