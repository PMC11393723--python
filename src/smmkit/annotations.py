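"""Annotation schema, interval algebra, and dataset curation.

Manual annotation of a behavioral-assessment recording produces a table of
labeled time segments: intervals during which the child exhibited a
stereotypical motor movement (SMM) of some type, plus sampled control
intervals containing ordinary (non-SMM) movement.  This module defines that
schema, rasterizes segments to per-frame masks for frame-wise evaluation,
samples length-matched negative segments, splits datasets by child so no
child contributes to both training and testing, and produces the per-split
accounting table (segments / assessments / children per side).

All intervals are half-open ``[start_s, end_s)`` in seconds; a frame belongs
to a segment iff its start time ``frame / fps`` falls inside the interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NON_SMM",
    "DEFAULT_SMM_TYPES",
    "Taxonomy",
    "AnnotatedSegment",
    "DatasetSplit",
    "CapacityError",
    "rasterize_segments",
    "sample_negative_segments",
    "split_by_child",
    "dataset_accounting",
    "read_annotations_csv",
    "write_annotations_csv",
]

#: Label for control segments that contain movement but no SMM.
NON_SMM = "non_smm"

#: Common SMM types; the vocabulary is open and extensible via :class:`Taxonomy`.
DEFAULT_SMM_TYPES: tuple[str, ...] = (
    "hand_flapping",
    "body_rocking",
    "jumping",
    "spinning",
    "smm_other",
)

CSV_COLUMNS = [
    "assessment_id",
    "child_id",
    "camera_id",
    "start_s",
    "end_s",
    "label",
    "skeleton_id",
    "annotator_id",
]


class CapacityError(RuntimeError):
    """A sampling request could not be fully satisfied.

    ``achieved`` carries the number of items successfully produced and
    ``partial`` the items themselves.
    """

    def __init__(self, msg: str, achieved: int, partial: list | None = None):
        super().__init__(msg)
        self.achieved = achieved
        self.partial = partial or []


@dataclass
class Taxonomy:
    """Open enumeration of SMM type labels.

    Seeded with the common types (hand flapping, body rocking, jumping,
    spinning); site-specific types can be registered with :meth:`add`.
    """

    smm_types: set[str] = field(default_factory=lambda: set(DEFAULT_SMM_TYPES))

    def add(self, label: str) -> None:
        if label == NON_SMM:
            raise ValueError(f"{NON_SMM!r} is reserved for control segments")
        self.smm_types.add(label)

    def validate(self, label: str) -> None:
        if label != NON_SMM and label not in self.smm_types:
            raise ValueError(
                f"unknown label {label!r}; known: {sorted(self.smm_types)} + [{NON_SMM!r}]"
            )


@dataclass(frozen=True)
class AnnotatedSegment:
    """A labeled time interval tied to an assessment and a skeleton."""

    assessment_id: str
    start_s: float
    end_s: float
    label: str
    skeleton_id: int = -1
    annotator_id: str = ""
    child_id: str = ""
    camera_id: str = ""

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(
                f"segment must have end_s > start_s, got [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_smm(self) -> bool:
        return self.label != NON_SMM


@dataclass
class DatasetSplit:
    """Segments partitioned by child into disjoint train and test sides."""

    train: dict[str, list[AnnotatedSegment]]
    test: dict[str, list[AnnotatedSegment]]

    def __post_init__(self) -> None:
        overlap = set(self.train) & set(self.test)
        if overlap:
            raise ValueError(f"children present in both splits: {sorted(overlap)}")


def rasterize_segments(
    segments: Iterable[AnnotatedSegment], fps: float, n_frames: int
) -> np.ndarray:
    """Per-frame boolean mask of SMM presence.

    Frame ``f`` is positive iff its start time ``f / fps`` falls inside any
    SMM-labeled segment; ``non_smm`` segments contribute nothing.  Segments
    must lie within ``[0, n_frames / fps]``.
    """
    mask = np.zeros(n_frames, dtype=bool)
    duration = n_frames / fps
    for seg in segments:
        if seg.start_s < 0 or seg.end_s > duration + 0.5 / fps:
            raise ValueError(
                f"segment [{seg.start_s}, {seg.end_s}) outside video duration "
                f"{duration:.3f} s"
            )
        if not seg.is_smm:
            continue
        # frame f in segment  <=>  start_s <= f/fps < end_s
        first = int(np.ceil(seg.start_s * fps - 1e-9))
        last = int(np.ceil(seg.end_s * fps - 1e-9))  # exclusive
        mask[max(first, 0) : min(last, n_frames)] = True
    return mask


def _overlaps(a_start: float, a_end: float, b_start: float, b_end: float) -> bool:
    return a_start < b_end and b_start < a_end


def sample_negative_segments(
    positives: Sequence[AnnotatedSegment],
    total_duration_s: float,
    n: int,
    seed: int,
    max_attempts_per_segment: int = 1000,
    annotator_id: str = "sampler",
) -> list[AnnotatedSegment]:
    """Sample ``n`` control segments length-matched to the positives.

    Lengths are drawn with replacement from the empirical distribution of
    positive-segment lengths, so negatives mirror the positives' duration
    profile.  Start times are drawn uniformly; a candidate is rejected if it
    overlaps any positive segment or a previously accepted negative
    (rejection sampling, at most ``max_attempts_per_segment`` draws each).

    Raises :class:`CapacityError` (carrying the partial sample) when the free
    timeline cannot accommodate all ``n`` segments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    positives = [p for p in positives if p.is_smm]
    if not positives:
        raise ValueError("need at least one positive segment to match lengths")
    pos_lengths = np.array([p.duration_s for p in positives])
    if pos_lengths.sum() >= total_duration_s:
        raise ValueError("total positive duration exceeds the timeline")
    rng = np.random.default_rng(seed)
    template = positives[0]
    occupied = [(p.start_s, p.end_s) for p in positives]
    out: list[AnnotatedSegment] = []
    for i in range(n):
        placed = False
        for _ in range(max_attempts_per_segment):
            length = float(rng.choice(pos_lengths))
            if length >= total_duration_s:
                continue
            start = float(rng.uniform(0.0, total_duration_s - length))
            end = start + length
            if any(_overlaps(start, end, s, e) for s, e in occupied):
                continue
            seg = replace(
                template,
                start_s=start,
                end_s=end,
                label=NON_SMM,
                annotator_id=annotator_id,
            )
            occupied.append((start, end))
            out.append(seg)
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could only place {len(out)} of {n} negative segments in "
                f"{total_duration_s:.1f} s after {max_attempts_per_segment} "
                f"attempts each",
                achieved=len(out),
                partial=out,
            )
    return out


def split_by_child(
    segments: Iterable[AnnotatedSegment], test_child_ids: Iterable[str]
) -> DatasetSplit:
    """Partition segments so every child lands wholly on one side."""
    by_child: dict[str, list[AnnotatedSegment]] = {}
    for seg in segments:
        by_child.setdefault(seg.child_id, []).append(seg)
    test_ids = set(test_child_ids)
    unknown = test_ids - set(by_child)
    if unknown:
        raise KeyError(f"unknown test child ids: {sorted(unknown)}")
    train = {c: segs for c, segs in by_child.items() if c not in test_ids}
    test = {c: segs for c, segs in by_child.items() if c in test_ids}
    return DatasetSplit(train=train, test=test)


def _side_counts(side: dict[str, list[AnnotatedSegment]]) -> dict[str, int]:
    segs = [s for group in side.values() for s in group]
    return {
        "smm_segments": sum(s.is_smm for s in segs),
        "non_smm_segments": sum(not s.is_smm for s in segs),
        "assessments": len({s.assessment_id for s in segs}),
        "children": len(side),
    }


def dataset_accounting(split: DatasetSplit) -> pd.DataFrame:
    """Counts of SMM / non-SMM segments, assessments and children per split side.

    Returns a DataFrame indexed by ``train / test / total``; the ``total``
    row is the column-wise sum of the two sides.
    """
    rows = {"train": _side_counts(split.train), "test": _side_counts(split.test)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["total"] = df.sum(axis=0)
    return df


def read_annotations_csv(path, taxonomy: Taxonomy | None = None) -> list[AnnotatedSegment]:
    """Read an annotation table; labels are validated against the taxonomy."""
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    tax = taxonomy or Taxonomy()
    out = []
    for rec in df.itertuples(index=False):
        tax.validate(str(rec.label))
        out.append(
            AnnotatedSegment(
                assessment_id=str(rec.assessment_id),
                child_id=str(rec.child_id),
                camera_id=str(rec.camera_id),
                start_s=float(rec.start_s),
                end_s=float(rec.end_s),
                label=str(rec.label),
                skeleton_id=int(rec.skeleton_id),
                annotator_id=str(rec.annotator_id),
            )
        )
    return out


def write_annotations_csv(path, segments: Iterable[AnnotatedSegment]) -> None:
    df = pd.DataFrame(
        [
            {
                "assessment_id": s.assessment_id,
                "child_id": s.child_id,
                "camera_id": s.camera_id,
                "start_s": s.start_s,
                "end_s": s.end_s,
                "label": s.label,
                "skeleton_id": s.skeleton_id,
                "annotator_id": s.annotator_id,
            }
            for s in segments
        ],
        columns=CSV_COLUMNS,
    )
    df.to_csv(path, index=False)
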