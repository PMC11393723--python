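"""End-to-end composition: simulate -> train baseline -> detect -> evaluate.

These functions wire the package's stages together on a simulated corpus:
the child track is selected with the height heuristic (never the generator's
hidden truth), the baseline scorer is trained on ground-truth positive
segments plus length-matched sampled negatives from the training children,
and detection/evaluation runs on the held-out children only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import child_id as cid
from .annotations import rasterize_segments
from .inference import (
    InferenceConfig,
    WindowSpec,
    extract_events,
    score_dense,
)
from .metrics import (
    AccuracyResult,
    ConcordanceResult,
    ConfusionCounts,
    accuracy_from_confusion,
    aggregate_accuracy,
    concordance,
    framewise_confusion,
)
from .quantify import AssessmentSummary, summarize_assessment
from .scorer import ScorerModel, train_baseline_scorer, windows_from_segments_dense
from .synthetic import Corpus, CorpusAssessment, build_training_segments

__all__ = [
    "select_child",
    "select_child_id",
    "fit_baseline_from_corpus",
    "AssessmentEvaluation",
    "CorpusEvaluation",
    "evaluate_corpus",
]


def select_child_id(assessment: CorpusAssessment) -> int:
    """Pick the child person id of one assessment with the height heuristic."""
    arrays = assessment.result.person_arrays
    stats = cid.compute_scene_stats_dense(arrays.values())
    series = [
        cid.child_prob_series_dense(pid, arr, stats) for pid, arr in arrays.items()
    ]
    return cid.select_child_track(series)


def select_child(assessment: CorpusAssessment):
    """Pick the child track (object view) of one assessment."""
    pid = select_child_id(assessment)
    return next(t for t in assessment.result.tracks if t.person_id == pid)


def fit_baseline_from_corpus(
    corpus: Corpus,
    spec: WindowSpec = WindowSpec(),
    seed: int = 0,
    neg_per_pos: int = 4,
) -> ScorerModel:
    """Train the periodicity baseline on the corpus' training children.

    One window per labeled segment (episode or sampled negative), taken from
    the heuristically selected child track of the owning assessment.
    """
    segments = build_training_segments(corpus, neg_per_pos=neg_per_pos, seed=seed)
    by_assessment: dict[str, list] = {}
    for s in segments:
        by_assessment.setdefault(s.assessment_id, []).append(s)
    windows, labels = [], []
    for a in corpus.assessments:
        segs = by_assessment.get(a.assessment_id)
        if not segs:
            continue
        child_arr = a.result.person_arrays[select_child_id(a)]
        w, y = windows_from_segments_dense(
            child_arr, a.result.config.fps, segs, width=spec.width
        )
        windows.extend(w)
        labels.extend(y)
    return train_baseline_scorer(windows, labels, seed=seed)


@dataclass
class AssessmentEvaluation:
    """Detection outcome of one held-out assessment."""

    assessment_id: str
    confusion: ConfusionCounts
    detected: AssessmentSummary
    truth: AssessmentSummary
    n_events_detected: int
    n_events_true: int


@dataclass
class CorpusEvaluation:
    """Frame-wise accuracy and per-assessment quantification agreement."""

    per_assessment: list[AssessmentEvaluation]
    accuracy: AccuracyResult
    rate_concordance: ConcordanceResult | None
    pct_time_concordance: ConcordanceResult | None
    pr_points: list[tuple[float, AccuracyResult]] = field(default_factory=list)


def evaluate_corpus(
    corpus: Corpus,
    model: ScorerModel,
    spec: WindowSpec = WindowSpec(),
    cfg: InferenceConfig = InferenceConfig(),
    sweep_grid: tuple[float, ...] = (),
    seed: int = 0,
) -> CorpusEvaluation:
    """Detect on every test-side assessment and score against ground truth.

    Frame-wise precision/recall/specificity/NPV are pooled over assessments
    (with SEM-based CIs); detected and true per-assessment burden measures
    are compared with Pearson/Spearman/CCC.  ``sweep_grid``, when given,
    additionally pools a precision-recall point per threshold.
    """
    test_children = set(corpus.split.test)
    evals: list[AssessmentEvaluation] = []
    sweep_conf: dict[float, ConfusionCounts] = {
        float(t): ConfusionCounts(0, 0, 0, 0) for t in sweep_grid
    }
    for a in corpus.assessments:
        if a.child_id not in test_children:
            continue
        res = a.result
        n_frames = int(round(res.config.duration_s * res.config.fps))
        child_arr = res.person_arrays[select_child_id(a)]
        series = score_dense(child_arr, res.config.fps, model, spec=spec)
        true_mask = rasterize_segments(res.segments, res.config.fps, n_frames)
        events = extract_events(series, cfg)
        pred_mask = np.zeros(n_frames, dtype=bool)
        for ev in events:
            pred_mask[ev.start_frame : ev.end_frame] = True
        conf = framewise_confusion(pred_mask, true_mask)
        det_summary = summarize_assessment(events, res.config.duration_s)
        truth_summary = _truth_summary(res.segments, res.config.duration_s)
        evals.append(
            AssessmentEvaluation(
                assessment_id=a.assessment_id,
                confusion=conf,
                detected=det_summary,
                truth=truth_summary,
                n_events_detected=len(events),
                n_events_true=len(res.segments),
            )
        )
        for t in sweep_conf:
            ev_t = extract_events(series, InferenceConfig(threshold=t))
            pm = np.zeros(n_frames, dtype=bool)
            for ev in ev_t:
                pm[ev.start_frame : ev.end_frame] = True
            sweep_conf[t] = sweep_conf[t] + framewise_confusion(pm, true_mask)
    if not evals:
        raise ValueError("corpus has no test-side assessments to evaluate")
    accuracy = aggregate_accuracy([e.confusion for e in evals])
    rate_c = pct_c = None
    if len(evals) >= 3:
        det_rate = [e.detected.events_per_min for e in evals]
        true_rate = [e.truth.events_per_min for e in evals]
        det_pct = [e.detected.pct_time for e in evals]
        true_pct = [e.truth.pct_time for e in evals]
        if np.var(det_rate) > 0 and np.var(true_rate) > 0:
            rate_c = concordance(det_rate, true_rate, seed=seed)
        if np.var(det_pct) > 0 and np.var(true_pct) > 0:
            pct_c = concordance(det_pct, true_pct, seed=seed)
    pr_points = [
        (t, accuracy_from_confusion(c)) for t, c in sorted(sweep_conf.items())
    ]
    return CorpusEvaluation(
        per_assessment=evals,
        accuracy=accuracy,
        rate_concordance=rate_c,
        pct_time_concordance=pct_c,
        pr_points=pr_points,
    )


def _truth_summary(segments, duration_s: float) -> AssessmentSummary:
    n = len(segments)
    if n == 0:
        return AssessmentSummary(0, 0.0, 0.0, 0.0, no_events=True)
    lengths = np.array([s.duration_s for s in segments])
    return AssessmentSummary(
        n_events=n,
        events_per_min=n / (duration_s / 60.0),
        median_event_s=float(np.median(lengths)),
        pct_time=100.0 * float(lengths.sum()) / duration_s,
    )
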