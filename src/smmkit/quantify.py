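"""Per-assessment SMM burden measures and cohort-level distribution tables.

An assessment's SMM burden is summarized by four measures: the number of
detected events, events per minute of recording, the median event length in
seconds, and the percentage of recording time spent in SMM.  Cohort tables
report the median and interquartile range of each measure across
assessments (quartiles by linear interpolation between order statistics —
the convention matters for small cohorts and is therefore pinned here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import SMMEvent

__all__ = ["AssessmentSummary", "summarize_assessment", "cohort_table"]


@dataclass(frozen=True)
class AssessmentSummary:
    """SMM burden of one assessment."""

    n_events: int
    events_per_min: float
    median_event_s: float
    pct_time: float
    no_events: bool = False  # median_event_s is a 0 placeholder when True

    def __post_init__(self) -> None:
        if min(self.n_events, self.events_per_min, self.median_event_s, self.pct_time) < 0:
            raise ValueError("summary measures must be >= 0")
        if self.pct_time > 100.0 + 1e-9:
            raise ValueError(f"pct_time cannot exceed 100, got {self.pct_time}")


def summarize_assessment(events: Sequence[SMMEvent], duration_s: float) -> AssessmentSummary:
    """Count, rate, median length and % time of events within one assessment.

    With an even number of events the median length is the mean of the two
    middle order statistics.  An empty event list yields a summary of zeros
    with ``no_events`` set (the median is undefined, reported as 0).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    for ev in events:
        if ev.start_s < -1e-9 or ev.end_s > duration_s + 1e-9:
            raise ValueError(
                f"event [{ev.start_s:.2f}, {ev.end_s:.2f}) outside assessment "
                f"duration {duration_s:.2f} s"
            )
    n = len(events)
    if n == 0:
        return AssessmentSummary(0, 0.0, 0.0, 0.0, no_events=True)
    lengths = np.array([ev.duration_s for ev in events])
    return AssessmentSummary(
        n_events=n,
        events_per_min=n / (duration_s / 60.0),
        median_event_s=float(np.median(lengths)),
        pct_time=100.0 * float(lengths.sum()) / duration_s,
    )


_MEASURES = ("n_events", "events_per_min", "median_event_s", "pct_time")


def cohort_table(summaries: Sequence[AssessmentSummary]) -> pd.DataFrame:
    """Median and IQR of each burden measure across assessments.

    Returns a DataFrame indexed by measure with columns
    ``median, q1, q3, iqr`` (quartiles by numpy's linear interpolation).
    Order of the input does not matter.
    """
    if not summaries:
        raise ValueError("cohort_table needs at least one assessment summary")
    rows = {}
    for m in _MEASURES:
        vals = np.array([getattr(s, m) for s in summaries], dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows[m] = {"median": med, "q1": q1, "q3": q3, "iqr": q3 - q1}
    return pd.DataFrame.from_dict(rows, orient="index")
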