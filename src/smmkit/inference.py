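"""Detection procedure: sliding windows, frame-wise max aggregation, events.

The recording is split into overlapping fixed-width windows (width 200
frames, stride 30 at 30 fps), each window is scored independently, every
frame receives the maximum score over the windows covering it, frames with
score >= the confidence threshold (default 0.85, inclusive) are marked as
SMM frames, and maximal runs of marked frames become detected SMM events
with start/end times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pose_io import Track, track_dense_array
from .scorer import (
    DEFAULT_WINDOW_WIDTH,
    ScorerModel,
    WindowScorer,
    as_window_scorer,
    window_from_dense,
)

__all__ = [
    "WindowSpec",
    "InferenceConfig",
    "FrameScoreSeries",
    "SMMEvent",
    "make_windows",
    "framewise_scores",
    "extract_events",
    "score_dense",
    "score_track",
    "detect",
]

#: Threshold grid used for precision-recall sweeps.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry (defaults: width 200, stride 30 frames)."""

    width: int = DEFAULT_WINDOW_WIDTH
    stride: int = 30

    def __post_init__(self) -> None:
        if not self.width >= self.stride >= 1:
            raise ValueError(
                f"need width >= stride >= 1, got width={self.width}, stride={self.stride}"
            )


@dataclass(frozen=True)
class InferenceConfig:
    """Event-extraction configuration.

    ``threshold`` is inclusive (frames scoring exactly the threshold count as
    SMM).  ``min_event_frames`` is off by default: no minimum event length is
    imposed.
    """

    threshold: float = 0.85
    grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    min_event_frames: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError(f"threshold must be in (0, 1), got {self.threshold}")


@dataclass
class FrameScoreSeries:
    """Per-frame SMM confidence at a known frame rate."""

    scores: np.ndarray
    fps: float = 30.0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be 1-D")
        if self.scores.size and not np.isfinite(self.scores).all():
            raise ValueError("scores must be finite")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return self.scores.size


@dataclass(frozen=True)
class SMMEvent:
    """A detected contiguous supra-threshold run (frames half-open)."""

    start_frame: int
    end_frame: int
    start_s: float
    end_s: float
    peak_score: float

    def __post_init__(self) -> None:
        if not self.end_frame > self.start_frame:
            raise ValueError("event must have end_frame > start_frame")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def make_windows(n_frames: int, spec: WindowSpec = WindowSpec()) -> list[int]:
    """Window start frames covering every frame of the recording.

    Starts run 0, stride, 2*stride, ... while ``start + width <= n_frames``;
    if the last such window stops short of the final frame, one tail window
    anchored at ``n_frames - width`` is appended.  A recording shorter than
    the window yields the single start 0 (the caller scores a short window).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if n_frames < spec.width:
        return [0]
    starts = list(range(0, n_frames - spec.width + 1, spec.stride))
    if starts[-1] + spec.width < n_frames:
        starts.append(n_frames - spec.width)
    return starts


def framewise_scores(
    window_starts: list[int],
    window_scores: np.ndarray,
    n_frames: int,
    width: int = DEFAULT_WINDOW_WIDTH,
    fps: float = 30.0,
) -> FrameScoreSeries:
    """Per-frame score = max over all windows covering the frame.

    Frames covered by no window (impossible under :func:`make_windows`)
    would keep score 0.
    """
    window_scores = np.asarray(window_scores, dtype=float)
    if len(window_starts) != window_scores.size:
        raise ValueError(
            f"{len(window_starts)} window starts but {window_scores.size} scores"
        )
    out = np.zeros(n_frames, dtype=float)
    for start, sc in zip(window_starts, window_scores):
        np.maximum(out[start : start + width], sc, out=out[start : start + width])
    return FrameScoreSeries(scores=out, fps=fps)


def positive_frames(s: FrameScoreSeries, threshold: float) -> np.ndarray:
    """Boolean mask of frames scoring >= threshold (inclusive)."""
    return s.scores >= threshold


def extract_events(s: FrameScoreSeries, cfg: InferenceConfig = InferenceConfig()) -> list[SMMEvent]:
    """Concatenate contiguous supra-threshold frames into events.

    Returns the maximal runs of frames with ``score >= threshold``; events
    shorter than ``min_event_frames`` are dropped when that filter is
    enabled (it defaults to off).
    """
    mask = positive_frames(s, cfg.threshold)
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    events = []
    for a, b in zip(starts, ends):
        if cfg.min_event_frames and (b - a) < cfg.min_event_frames:
            continue
        events.append(
            SMMEvent(
                start_frame=int(a),
                end_frame=int(b),
                start_s=a / s.fps,
                end_s=b / s.fps,
                peak_score=float(s.scores[a:b].max()),
            )
        )
    return events


def score_dense(
    dense: np.ndarray,
    fps: float,
    model: "ScorerModel | WindowScorer",
    spec: WindowSpec = WindowSpec(),
) -> FrameScoreSeries:
    """Slide the scorer along a dense (n, 17, 3) child array; max per frame."""
    scorer = as_window_scorer(model)
    n = dense.shape[0]
    if n < 1:
        raise ValueError("track has no frames")
    starts = make_windows(n, spec)
    width = min(spec.width, n)
    scores = np.array([scorer(window_from_dense(dense, st, width, fps=fps)) for st in starts])
    return framewise_scores(starts, scores, n, width=width, fps=fps)


def score_track(
    track: Track,
    model: "ScorerModel | WindowScorer",
    spec: WindowSpec = WindowSpec(),
    n_frames: int | None = None,
) -> FrameScoreSeries:
    """Slide the scorer along a child track and max-aggregate per frame."""
    return score_dense(track_dense_array(track, n_frames), track.fps, model, spec=spec)


def detect(
    track: Track,
    model: "ScorerModel | WindowScorer",
    spec: WindowSpec = WindowSpec(),
    cfg: InferenceConfig = InferenceConfig(),
    n_frames: int | None = None,
) -> list[SMMEvent]:
    """End-to-end detection on one child track.

    Composition: :func:`make_windows` -> score each window ->
    :func:`framewise_scores` -> :func:`extract_events`.  Deterministic for
    fixed inputs.
    """
    series = score_track(track, model, spec=spec, n_frames=n_frames)
    return extract_events(series, cfg)
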