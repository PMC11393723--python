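"""Identify which skeleton track belongs to the child.

Behavioral-assessment rooms contain the child plus one or more adults
(clinician, parent), and downstream movement analysis must use only the
child's skeleton.  This module provides a pluggable per-frame scorer
interface (any ``SkeletonFrame -> probability`` map) together with a shipped
baseline that exploits the most reliable geometric cue available without a
trained image classifier: preschool-age children are substantially shorter
than adults, so a skeleton whose shoulder-ankle extent falls below the scene
median is more likely the child.  Per-frame probabilities are mean-pooled per
track and the track with the highest mean is selected.

Externally computed probabilities (e.g. from a trained child/adult detector)
can be supplied as a CSV with columns ``frame, person_id, p_child`` and
bypass the baseline entirely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .pose_io import JOINT_INDEX, SkeletonFrame, Track

__all__ = [
    "ChildProbSeries",
    "SceneStats",
    "NoTrackError",
    "compute_scene_stats",
    "compute_scene_stats_dense",
    "child_prob_series_dense",
    "skeleton_height",
    "heuristic_child_score",
    "child_prob_series",
    "select_child_track",
    "read_child_probs_csv",
]

_SHOULDERS = (JOINT_INDEX["left_shoulder"], JOINT_INDEX["right_shoulder"])
_ANKLES = (JOINT_INDEX["left_ankle"], JOINT_INDEX["right_ankle"])


class NoTrackError(ValueError):
    """Child selection was asked to choose among zero tracks."""


@dataclass
class ChildProbSeries:
    """Per-frame probability that a tracked person is the child."""

    person_id: int
    frames: np.ndarray  # frame indices where the person appears and was scored
    probs: np.ndarray  # matching probabilities in [0, 1]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.probs = np.asarray(self.probs, dtype=float)
        if self.frames.shape != self.probs.shape:
            raise ValueError("frames and probs must have equal length")
        if self.probs.size and not ((self.probs >= 0) & (self.probs <= 1)).all():
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.probs.mean()) if self.probs.size else float("nan")


@dataclass(frozen=True)
class SceneStats:
    """Per-video skeleton-size statistics used to standardize heights."""

    median_height: float
    height_scale: float  # robust spread (MAD * 1.4826); floored to stay positive


def skeleton_height(frame: SkeletonFrame) -> float | None:
    """Shoulder-ankle vertical extent in pixels, or None if not measurable.

    Requires at least one visible shoulder and one visible ankle; uses the
    mean y of the visible joints on each end so a single occluded side does
    not bias the estimate.
    """
    sh = [frame.keypoints[j] for j in _SHOULDERS if not frame.keypoints[j].missing]
    an = [frame.keypoints[j] for j in _ANKLES if not frame.keypoints[j].missing]
    if not sh or not an:
        return None
    sh_y = float(np.mean([k.y for k in sh]))
    an_y = float(np.mean([k.y for k in an]))
    h = abs(an_y - sh_y)
    return h if h > 0 else None


def compute_scene_stats(tracks: Iterable[Track]) -> SceneStats:
    """Median and robust spread of skeleton heights over every frame of every track."""
    heights = []
    for tr in tracks:
        for fr in tr.frames:
            h = skeleton_height(fr)
            if h is not None:
                heights.append(h)
    if not heights:
        raise ValueError("no measurable skeleton heights in scene")
    arr = np.asarray(heights)
    med = float(np.median(arr))
    mad = float(np.median(np.abs(arr - med)))
    scale = max(1.4826 * mad, 1e-6 * max(med, 1.0))
    return SceneStats(median_height=med, height_scale=scale)


def heuristic_child_score(frame: SkeletonFrame, scene_stats: SceneStats) -> float | None:
    """Logistic score in the standardized negative skeleton height.

    ``score = sigmoid((median - height) / scale)``: 0.5 at the scene median,
    rising toward 1 as the skeleton shrinks below it.  Returns None for
    frames where the height cannot be measured (the frame is skipped).
    """
    h = skeleton_height(frame)
    if h is None:
        return None
    z = (scene_stats.median_height - h) / scene_stats.height_scale
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


ChildScorer = Callable[[SkeletonFrame, SceneStats], "float | None"]


def child_prob_series(
    track: Track, scene_stats: SceneStats, scorer: ChildScorer = heuristic_child_score
) -> ChildProbSeries:
    """Apply a per-frame child scorer along one track, skipping unscorable frames."""
    frames, probs = [], []
    for fr in track.frames:
        p = scorer(fr, scene_stats)
        if p is not None:
            frames.append(fr.frame_index)
            probs.append(p)
    return ChildProbSeries(track.person_id, np.array(frames, int), np.array(probs))


def select_child_track(prob_series: Sequence[ChildProbSeries]) -> int:
    """Pick the person with the highest mean per-frame child probability.

    Mean pooling over the whole track (rather than per-frame switching) keeps
    one child identity per recording, matching how the child skeleton is
    annotated.  Ties break deterministically toward the lower person id;
    tracks with no scorable frames are ignored.
    """
    scored = [(s.mean, s.person_id) for s in prob_series if s.probs.size]
    if not scored:
        raise NoTrackError("no scorable tracks to select the child from")
    best = max(scored, key=lambda t: (t[0], -t[1]))
    return best[1]


def _heights_from_dense(arr: np.ndarray) -> np.ndarray:
    """Per-frame shoulder-ankle extents from a (n, 17, 3) array; NaN when unmeasurable."""
    def _end_y(joints):
        y = arr[:, joints, 1]
        vis = arr[:, joints, 2] > 0
        with np.errstate(invalid="ignore"):
            s = np.where(vis, y, 0.0).sum(axis=1)
            c = vis.sum(axis=1)
            return np.where(c > 0, s / np.maximum(c, 1), np.nan)

    h = np.abs(_end_y(list(_ANKLES)) - _end_y(list(_SHOULDERS)))
    h[h <= 0] = np.nan
    return h


def compute_scene_stats_dense(arrays: Iterable[np.ndarray]) -> SceneStats:
    """Vectorized :func:`compute_scene_stats` over (n, 17, 3) per-person arrays."""
    heights = np.concatenate([_heights_from_dense(a) for a in arrays])
    heights = heights[~np.isnan(heights)]
    if heights.size == 0:
        raise ValueError("no measurable skeleton heights in scene")
    med = float(np.median(heights))
    mad = float(np.median(np.abs(heights - med)))
    scale = max(1.4826 * mad, 1e-6 * max(med, 1.0))
    return SceneStats(median_height=med, height_scale=scale)


def child_prob_series_dense(
    person_id: int, arr: np.ndarray, scene_stats: SceneStats
) -> ChildProbSeries:
    """Vectorized height-heuristic scoring of one person's dense array."""
    h = _heights_from_dense(arr)
    valid = ~np.isnan(h)
    z = (scene_stats.median_height - h[valid]) / scene_stats.height_scale
    probs = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
    return ChildProbSeries(person_id, np.flatnonzero(valid), probs)


def read_child_probs_csv(path) -> list[ChildProbSeries]:
    """Load externally computed per-frame child probabilities.

    Expected columns: ``frame, person_id, p_child``.
    """
    df = pd.read_csv(path)
    required = {"frame", "person_id", "p_child"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"child-probability CSV missing columns: {sorted(missing)}")
    out = []
    for pid, grp in df.groupby("person_id", sort=True):
        grp = grp.sort_values("frame")
        out.append(
            ChildProbSeries(
                int(pid),
                grp["frame"].to_numpy(dtype=int),
                grp["p_child"].to_numpy(dtype=float),
            )
        )
    return out
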