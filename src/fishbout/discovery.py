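"""Unsupervised candidate-bout discovery.

KMeans (k = 9 by default) over the normalized feature vectors partitions
windows into clusters; clusters do not map onto nameable behaviors, but
they split cleanly into "stationary" and "movement" roles, which is enough
to enrich clips for manual labeling.  Roles are assigned by a displacement
rule: a cluster whose windows imply a mean center-keypoint speed below
2 mm/s — the same threshold the pipeline uses for movement bouts — is
stationary (strictly below; a borderline cluster counts as movement).

``export_clips`` samples windows from a role or cluster and writes them as
small pose files for review, optionally with a schematic skeleton
rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .features import CENTER, FeatureMatrix, unflatten_windows
from .pose_io import PoseTrack, write_pose_track

logger = logging.getLogger(__name__)

SPEED_THRESHOLD_MM_S = 2.0


class InsufficientDataError(ValueError):
    pass


@dataclass
class ClusterModel:
    """Fitted KMeans plus the stationary/movement role of each cluster."""

    k: int
    kmeans: KMeans
    seed: int
    cluster_roles: dict[int, str] = field(default_factory=dict)

    @property
    def centroids(self) -> np.ndarray:
        return self.kmeans.cluster_centers_

    def predict(self, fm: FeatureMatrix) -> np.ndarray:
        return self.kmeans.predict(fm.vectors)


def fit_clusters(
    fm: FeatureMatrix,
    k: int = 9,
    seed: int = 0,
    fps: float = 160.0,
    pixel_size: float | None = None,
    threshold: float = SPEED_THRESHOLD_MM_S,
) -> ClusterModel:
    """KMeans over usable feature vectors, with roles assigned.

    ``pixel_size`` (um/px) is needed to express implied window speeds in
    mm/s for role assignment; it defaults to 1000 (i.e. coordinates
    already in mm) when not given.
    """
    X = fm.vectors[fm.usable]
    if X.shape[0] < k:
        raise InsufficientDataError(
            f"{X.shape[0]} usable windows < k = {k}"
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    model = ClusterModel(k=k, kmeans=km, seed=seed)
    model.cluster_roles = assign_roles(
        model, fm, fps=fps, pixel_size=pixel_size, threshold=threshold
    )
    return model


def assign_roles(
    model: ClusterModel,
    fm: FeatureMatrix,
    fps: float = 160.0,
    pixel_size: float | None = None,
    threshold: float = SPEED_THRESHOLD_MM_S,
) -> dict[int, str]:
    """Stationary/movement role per cluster from implied center speed.

    For each cluster, the mean over its windows of the center keypoint's
    per-frame path speed is computed from the (denormalized) window
    coordinates; clusters strictly below ``threshold`` mm/s are stationary.
    At least one cluster per role is guaranteed: if thresholding yields
    none, the extreme cluster is reassigned.
    """
    px_mm = (pixel_size if pixel_size is not None else 1000.0) / 1000.0
    coords = unflatten_windows(
        (fm.vectors[fm.usable] + fm.norm_mean) * fm.norm_max, fm.width
    )
    centers = coords[:, :, CENTER, :]  # (n, W, 2)
    step = np.linalg.norm(np.diff(centers, axis=1), axis=-1)
    win_speed = step.mean(axis=1) * fps * px_mm  # mm/s per window
    assign = model.kmeans.predict(fm.vectors[fm.usable])
    mean_speed = np.full(model.k, np.nan)
    for c in range(model.k):
        sel = assign == c
        if sel.any():
            mean_speed[c] = win_speed[sel].mean()
    roles = {
        c: ("stationary" if mean_speed[c] < threshold else "movement")
        for c in range(model.k)
    }
    vals = list(roles.values())
    if "stationary" not in vals:
        roles[int(np.nanargmin(mean_speed))] = "stationary"
    elif "movement" not in vals:
        roles[int(np.nanargmax(mean_speed))] = "movement"
    return roles


def export_clips(
    track: PoseTrack,
    fm: FeatureMatrix,
    model: ClusterModel,
    which: str | int,
    n: int,
    out_dir: str | Path,
    seed: int = 0,
    width: int | None = None,
    frame_interval: tuple[int, int] | None = None,
    render: bool = False,
) -> list[Path]:
    """Sample candidate windows and write them as clip files for labeling.

    ``which`` is a role name ("stationary"/"movement") or a cluster index.
    Clips are written through the standard pose schema so their coordinates
    round-trip bit-exactly; filenames encode track, start frame and
    cluster.  ``frame_interval`` restricts candidates to windows whose
    start falls in the half-open interval (e.g. near a stimulus frame).
    With ``render=True`` a schematic skeleton GIF is written next to each
    clip.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    W = width or fm.width
    assign = np.full(fm.vectors.shape[0], -1)
    assign[fm.usable] = model.kmeans.predict(fm.vectors[fm.usable])
    if isinstance(which, str):
        wanted = [c for c, r in model.cluster_roles.items() if r == which]
        sel = np.isin(assign, wanted) & fm.usable
    else:
        sel = (assign == int(which)) & fm.usable
    if frame_interval is not None:
        a, b = frame_interval
        sel &= (fm.window_starts >= a) & (fm.window_starts < b)
    candidates = np.flatnonzero(sel)
    if candidates.size < n:
        logger.warning(
            "requested %d clips, only %d matching windows", n, candidates.size
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(
        candidates, size=min(n, candidates.size), replace=False
    )
    paths = []
    for idx in sorted(chosen.tolist()):
        start = int(fm.window_starts[idx])
        clip = PoseTrack(
            coords=track.coords[start:start + W].copy(),
            missing=track.missing[start:start + W].copy(),
            fps=track.fps,
            pixel_size=track.pixel_size,
            plate_format=track.plate_format,
            well_id=track.well_id,
            body_length=track.body_length,
        )
        name = f"{track.well_id or 'track'}_f{start:05d}_c{assign[idx]}"
        path = write_pose_track(clip, out_dir / f"{name}.h5")
        if render:
            _render_clip(clip, out_dir / f"{name}.gif")
        paths.append(path)
    return paths


def _render_clip(clip: PoseTrack, path: Path) -> None:
    """Schematic 8-keypoint skeleton animation on a blank background."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.animation import FuncAnimation, PillowWriter

    fig, ax = plt.subplots(figsize=(3, 3))
    xy = clip.coords
    ax.set_xlim(xy[..., 0].min() - 5, xy[..., 0].max() + 5)
    ax.set_ylim(xy[..., 1].min() - 5, xy[..., 1].max() + 5)
    ax.set_aspect("equal")
    ax.axis("off")
    (line,) = ax.plot([], [], "o-", ms=3)

    def update(i):
        line.set_data(xy[i, :, 0], xy[i, :, 1])
        return (line,)

    anim = FuncAnimation(fig, update, frames=clip.n_frames)
    anim.save(path, writer=PillowWriter(fps=20))
    plt.close(fig)
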