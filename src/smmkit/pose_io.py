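"""Data model and serialization for multi-person 2-D skeleton streams.

A *skeleton stream* is the per-frame output of a pose estimator plus tracker:
for every video frame, each visible person contributes one 17-keypoint
COCO-layout skeleton tagged with a persistent ``person_id``.  Streams are
serialized as a JSON list of records ``{"frame": int, "person_id": int,
"keypoints": [[x, y, confidence] * 17]}``, one file per camera per
assessment; the writer emits records sorted by ``(frame, person_id)``.

Conventions used throughout the package:

* keypoints follow the canonical COCO-17 order (:data:`COCO_KEYPOINT_NAMES`);
* a keypoint with ``confidence == 0`` is *missing* and its coordinates are
  ignored by all geometry;
* frame indices are 0-based and all intervals are half-open ``[start, end)``;
* image coordinates are in pixels, origin at the top-left corner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "COCO_KEYPOINT_NAMES",
    "N_KEYPOINTS",
    "Keypoint",
    "SkeletonFrame",
    "Track",
    "BBox",
    "BoxMatch",
    "SkeletonStreamError",
    "DegenerateSkeletonError",
    "track_dense_array",
    "read_skeleton_stream",
    "write_skeleton_stream",
    "bbox_from_skeleton",
    "iou",
    "match_boxes_to_skeletons",
]

#: Canonical COCO-17 joint order.
COCO_KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)
N_KEYPOINTS = 17

JOINT_INDEX = {name: i for i, name in enumerate(COCO_KEYPOINT_NAMES)}


class SkeletonStreamError(ValueError):
    """Malformed skeleton-stream file (parse or schema violation)."""


class DegenerateSkeletonError(ValueError):
    """A skeleton with too few visible keypoints for the requested geometry."""


@dataclass(frozen=True, slots=True)
class Keypoint:
    """A single 2-D joint location with detection confidence.

    ``confidence == 0`` marks the keypoint as missing; its coordinates carry
    no information and are excluded from all geometric computations.
    """

    x: float
    y: float
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0, 1], got {self.confidence}")

    @property
    def missing(self) -> bool:
        return self.confidence == 0.0


@dataclass(frozen=True, slots=True)
class SkeletonFrame:
    """One person's 17-keypoint skeleton in one video frame."""

    frame_index: int
    person_id: int
    keypoints: tuple[Keypoint, ...]

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if len(self.keypoints) != N_KEYPOINTS:
            raise SkeletonStreamError(
                f"skeleton must have exactly {N_KEYPOINTS} keypoints, "
                f"got {len(self.keypoints)} (frame {self.frame_index}, "
                f"person {self.person_id})"
            )

    def visible_xy(self) -> np.ndarray:
        """(n, 2) array of coordinates of non-missing keypoints."""
        return np.array(
            [(k.x, k.y) for k in self.keypoints if not k.missing], dtype=float
        ).reshape(-1, 2)


@dataclass
class Track:
    """The time-ordered skeleton sequence of one tracked person."""

    person_id: int
    frames: list[SkeletonFrame] = field(default_factory=list)
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SkeletonStreamError(
                f"frame indices must be strictly increasing in track "
                f"{self.person_id}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    def frame_indices(self) -> np.ndarray:
        return np.array([f.frame_index for f in self.frames], dtype=int)

    def to_array(self) -> np.ndarray:
        """(n_frames, 17, 3) array of (x, y, confidence)."""
        out = np.empty((len(self.frames), N_KEYPOINTS, 3), dtype=float)
        for i, fr in enumerate(self.frames):
            for j, kp in enumerate(fr.keypoints):
                out[i, j] = (kp.x, kp.y, kp.confidence)
        return out


def track_dense_array(track: Track, n_frames: int | None = None) -> np.ndarray:
    """(n_frames, 17, 3) array on a dense 0..n_frames-1 grid.

    Frames where the track is absent get confidence 0 (all-missing skeleton).
    ``n_frames`` defaults to ``last frame index + 1``.
    """
    if n_frames is None:
        n_frames = (track.frames[-1].frame_index + 1) if track.frames else 0
    out = np.zeros((n_frames, N_KEYPOINTS, 3), dtype=float)
    for fr in track.frames:
        if fr.frame_index >= n_frames:
            break
        for j, kp in enumerate(fr.keypoints):
            out[fr.frame_index, j] = (kp.x, kp.y, kp.confidence)
    return out


@dataclass(frozen=True)
class BBox:
    """Axis-aligned bounding box in pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate box: {self}")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


def _frame_from_record(rec: dict, where: str) -> SkeletonFrame:
    try:
        frame = int(rec["frame"])
        person = int(rec["person_id"])
        kps = rec["keypoints"]
    except (KeyError, TypeError, ValueError) as exc:
        raise SkeletonStreamError(f"malformed skeleton record at {where}: {exc}") from exc
    if len(kps) != N_KEYPOINTS:
        raise SkeletonStreamError(
            f"record at {where} has {len(kps)} keypoints, expected {N_KEYPOINTS}"
        )
    try:
        keypoints = tuple(Keypoint(float(x), float(y), float(c)) for x, y, c in kps)
    except (TypeError, ValueError) as exc:
        raise SkeletonStreamError(f"bad keypoint triple at {where}: {exc}") from exc
    return SkeletonFrame(frame_index=frame, person_id=person, keypoints=keypoints)


def read_skeleton_stream(path, fps: float = 30.0) -> list[Track]:
    """Read a skeleton-stream JSON file into per-person :class:`Track` objects.

    Unknown record fields are ignored.  Tracks are returned sorted by
    ``person_id`` with strictly increasing frame indices.
    """
    with open(path) as fh:
        try:
            records = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SkeletonStreamError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(records, list):
        raise SkeletonStreamError(f"{path}: top level must be a JSON list")
    by_person: dict[int, list[SkeletonFrame]] = {}
    for i, rec in enumerate(records):
        sf = _frame_from_record(rec, f"{path} record {i}")
        by_person.setdefault(sf.person_id, []).append(sf)
    tracks = []
    for pid in sorted(by_person):
        frames = sorted(by_person[pid], key=lambda f: f.frame_index)
        tracks.append(Track(person_id=pid, frames=frames, fps=fps))
    return tracks


def write_skeleton_stream(path, tracks: Iterable[Track]) -> None:
    """Write tracks to the skeleton-stream JSON dialect, sorted by (frame, person)."""
    records = []
    for tr in tracks:
        for fr in tr.frames:
            records.append(
                {
                    "frame": fr.frame_index,
                    "person_id": fr.person_id,
                    "keypoints": [[k.x, k.y, k.confidence] for k in fr.keypoints],
                }
            )
    records.sort(key=lambda r: (r["frame"], r["person_id"]))
    with open(path, "w") as fh:
        json.dump(records, fh)


def bbox_from_skeleton(frame: SkeletonFrame, pad: float = 0.0) -> BBox:
    """Tight axis-aligned box over the visible keypoints, expanded by ``pad``.

    Raises :class:`DegenerateSkeletonError` when fewer than two keypoints are
    visible (a single point has no extent).
    """
    xy = frame.visible_xy()
    if xy.shape[0] < 2:
        raise DegenerateSkeletonError(
            f"need >=2 visible keypoints to build a box, got {xy.shape[0]} "
            f"(frame {frame.frame_index}, person {frame.person_id})"
        )
    x_min, y_min = xy.min(axis=0)
    x_max, y_max = xy.max(axis=0)
    return BBox(x_min - pad, y_min - pad, x_max + pad, y_max + pad)


def iou(a: BBox, b: BBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0.0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    return inter / (a.area + b.area - inter)


@dataclass(frozen=True)
class BoxMatch:
    """Result of greedy box-to-skeleton assignment."""

    pairs: tuple[tuple[int, int, float], ...]  # (box index, person_id, IoU)
    unmatched_boxes: tuple[int, ...]
    unmatched_persons: tuple[int, ...]


def match_boxes_to_skeletons(
    boxes: Sequence[BBox], frames: Sequence[SkeletonFrame], pad: float = 0.0
) -> BoxMatch:
    """One-to-one greedy assignment of detector boxes to same-frame skeletons.

    Candidate pairs are ranked by descending IoU between each box and each
    skeleton's bounding box; ties break toward the lower box index, then the
    lower person id.  Pairs with zero IoU are never assigned.
    """
    skel_boxes = [bbox_from_skeleton(f, pad=pad) for f in frames]
    cand = []
    for bi, box in enumerate(boxes):
        for si, sb in enumerate(skel_boxes):
            v = iou(box, sb)
            if v > 0.0:
                cand.append((-v, bi, frames[si].person_id, si))
    cand.sort()
    used_boxes: set[int] = set()
    used_skels: set[int] = set()
    pairs = []
    for neg_v, bi, pid, si in cand:
        if bi in used_boxes or si in used_skels:
            continue
        used_boxes.add(bi)
        used_skels.add(si)
        pairs.append((bi, pid, -neg_v))
    unmatched_boxes = tuple(i for i in range(len(boxes)) if i not in used_boxes)
    unmatched_persons = tuple(
        frames[i].person_id for i in range(len(frames)) if i not in used_skels
    )
    return BoxMatch(tuple(pairs), unmatched_boxes, unmatched_persons)
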