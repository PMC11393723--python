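"""Evaluation and agreement statistics for SMM detection.

Frame-wise accuracy (precision / recall / specificity / NPV with SEM-based
confidence intervals aggregated across assessments), precision-recall
sweeps over a confidence-threshold grid, method-comparison statistics
(Pearson, Spearman, Lin's concordance correlation coefficient with a seeded
percentile bootstrap), interrater agreement (percent agreement and Cohen's
kappa), the confusion-stratified reannotation protocol (equal numbers of
hits / false alarms / correct rejections / misses, relabeled by
either-annotator union), and the cohort-comparison tests (Yates-corrected
chi-square, pooled-variance t, Mann-Whitney U).

Conventions that change third decimals and are therefore pinned:

* Lin's CCC uses population (1/n) moments;
* the Yates continuity correction clamps ``|O - E| - 0.5`` at zero;
* bootstrap CIs are percentile CIs over 1000 seeded resamples of
  assessment pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .inference import FrameScoreSeries, InferenceConfig, extract_events

__all__ = [
    "ConfusionCounts",
    "AccuracyResult",
    "ConcordanceResult",
    "AgreementResult",
    "framewise_confusion",
    "accuracy_from_confusion",
    "aggregate_accuracy",
    "pr_sweep",
    "concordance",
    "agreement",
    "stratified_confusion_sample",
    "union_relabel",
    "yates_chi_square",
    "two_sample_t",
    "mann_whitney",
]

CONFUSION_CELLS = ("tp", "fp", "tn", "fn")


@dataclass(frozen=True)
class ConfusionCounts:
    """Frame (or segment) counts of hits, false alarms, correct rejections, misses."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class AccuracyResult:
    """Precision / recall / specificity / NPV; NaN marks an undefined metric.

    ``ci`` maps metric name to a (lower, upper) 95% interval when the result
    was aggregated across assessments; empty for a single confusion table.
    """

    precision: float
    recall: float
    specificity: float
    npv: float
    ci: Mapping[str, tuple[float, float]] | None = None

    def defined(self, metric: str) -> bool:
        return not np.isnan(getattr(self, metric))


@dataclass(frozen=True)
class ConcordanceResult:
    """Pearson r, Spearman rho and Lin's CCC between two measure vectors."""

    pearson_r: float
    spearman_rho: float
    ccc: float
    r_ci: tuple[float, float]
    n: int


@dataclass(frozen=True)
class AgreementResult:
    """Percent agreement and Cohen's kappa between two raters."""

    percent_agreement: float
    kappa: float


def framewise_confusion(pred_mask: np.ndarray, true_mask: np.ndarray) -> ConfusionCounts:
    """Frame-level confusion counts between prediction and annotation masks."""
    pred = np.asarray(pred_mask, dtype=bool)
    true = np.asarray(true_mask, dtype=bool)
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def accuracy_from_confusion(c: ConfusionCounts) -> AccuracyResult:
    """Point estimates from one confusion table; zero denominators yield NaN."""
    return AccuracyResult(
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


def aggregate_accuracy(per_assessment: Sequence[ConfusionCounts]) -> AccuracyResult:
    """Pooled accuracy with SEM-based 95% CIs across assessments.

    Point estimates come from the summed confusion table; the interval for
    each metric is mean +/- 1.96 * SEM over the per-assessment values
    (assessments where the metric is undefined are excluded from its CI).
    """
    if not per_assessment:
        raise ValueError("need at least one assessment")
    total = per_assessment[0]
    for c in per_assessment[1:]:
        total = total + c
    pooled = accuracy_from_confusion(total)
    ci: dict[str, tuple[float, float]] = {}
    for metric in ("precision", "recall", "specificity", "npv"):
        vals = np.array(
            [getattr(accuracy_from_confusion(c), metric) for c in per_assessment]
        )
        vals = vals[~np.isnan(vals)]
        if vals.size >= 2:
            sem = vals.std(ddof=1) / np.sqrt(vals.size)
            ci[metric] = (float(vals.mean() - 1.96 * sem), float(vals.mean() + 1.96 * sem))
    return AccuracyResult(
        precision=pooled.precision,
        recall=pooled.recall,
        specificity=pooled.specificity,
        npv=pooled.npv,
        ci=ci,
    )


def pr_sweep(
    score_series: FrameScoreSeries,
    true_mask: np.ndarray,
    grid: Sequence[float] = (0.5, 0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85, 0.9),
) -> list[tuple[float, AccuracyResult]]:
    """Accuracy at each confidence threshold, using event-extraction semantics.

    Positive frames at each threshold are exactly the frames inside events
    extracted at that (inclusive) threshold, so the sweep reflects the full
    detection pipeline rather than raw thresholding alone.
    """
    true = np.asarray(true_mask, dtype=bool)
    if len(true) != len(score_series):
        raise ValueError("score series and mask must have equal length")
    out = []
    for theta in grid:
        if not 0.0 < theta < 1.0:
            raise ValueError(f"thresholds must lie in (0, 1), got {theta}")
        events = extract_events(score_series, InferenceConfig(threshold=theta))
        pred = np.zeros(len(true), dtype=bool)
        for ev in events:
            pred[ev.start_frame : ev.end_frame] = True
        out.append((float(theta), accuracy_from_confusion(framewise_confusion(pred, true))))
    return out


def lin_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Lin's concordance correlation coefficient with population (1/n) moments.

    ``CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    vx, vy = x.var(), y.var()
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    denom = vx + vy + (x.mean() - y.mean()) ** 2
    if denom == 0:
        return float("nan")
    return float(2.0 * cov / denom)


def concordance(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
) -> ConcordanceResult:
    """Pearson / Spearman / Lin's CCC with a seeded percentile bootstrap CI on r.

    The bootstrap resamples (x, y) pairs with replacement ``n_boot`` times;
    resamples with zero variance in either coordinate are skipped.  Zero
    variance in the full data makes all three coefficients NaN.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if x.var() == 0 or y.var() == 0:
        return ConcordanceResult(
            float("nan"), float("nan"), float("nan"), (float("nan"), float("nan")), n
        )
    r = float(stats.pearsonr(x, y).statistic)
    rho = float(stats.spearmanr(x, y).statistic)
    ccc = lin_ccc(x, y)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if xb.var() == 0 or yb.var() == 0:
            continue
        boots.append(stats.pearsonr(xb, yb).statistic)
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
        r_ci = (float(lo), float(hi))
    else:
        r_ci = (float("nan"), float("nan"))
    return ConcordanceResult(r, rho, ccc, r_ci, n)


def agreement(r1: Sequence[int], r2: Sequence[int]) -> AgreementResult:
    """Percent agreement and Cohen's kappa between two binary raters.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with chance agreement ``p_e`` from
    the product of the raters' marginals.  When both raters are constant and
    identical, ``p_e = 1`` and kappa is undefined (NaN); percent agreement
    is still 100.
    """
    a = np.asarray(r1, dtype=int)
    b = np.asarray(r2, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ValueError("raters must give equal-length nonempty label vectors")
    n = a.size
    p_o = float(np.mean(a == b))
    labels = np.union1d(a, b)
    p_e = float(
        sum((np.mean(a == l)) * (np.mean(b == l)) for l in labels)
    )
    if p_e >= 1.0 - 1e-12:
        kappa = float("nan")
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(percent_agreement=100.0 * p_o, kappa=kappa)


def stratified_confusion_sample(
    items: Sequence, cells: Sequence[str], n_per_cell: int, seed: int = 0
) -> list:
    """Sample an equal number of items from each confusion cell, without replacement.

    ``cells[i]`` names the confusion cell (``tp / fp / tn / fn``) of
    ``items[i]``.  Raises a capacity error naming any cell with fewer than
    ``n_per_cell`` members.  Output order: tp block, fp block, tn block, fn
    block (each block in sampled order); sampling is seeded.
    """
    if len(items) != len(cells):
        raise ValueError("items and cells must have equal length")
    by_cell: dict[str, list] = {c: [] for c in CONFUSION_CELLS}
    for item, cell in zip(items, cells):
        if cell not in by_cell:
            raise ValueError(f"unknown confusion cell {cell!r}")
        by_cell[cell].append(item)
    rng = np.random.default_rng(seed)
    out = []
    for cell in CONFUSION_CELLS:
        members = by_cell[cell]
        if len(members) < n_per_cell:
            raise ValueError(
                f"cell {cell!r} has only {len(members)} members, need {n_per_cell}"
            )
        idx = rng.choice(len(members), size=n_per_cell, replace=False)
        out.extend(members[i] for i in idx)
    return out


def union_relabel(r1: Sequence[int], r2: Sequence[int]) -> np.ndarray:
    """Either-annotator union: a segment is an SMM if either rater marked it."""
    a = np.asarray(r1, dtype=bool)
    b = np.asarray(r2, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    return (a | b).astype(int)


def yates_chi_square(table: Sequence[Sequence[float]]) -> float:
    """Yates continuity-corrected chi-square for a 2x2 table, clamped at zero.

    ``sum(max(|O - E| - 0.5, 0)^2 / E)`` with expectations from the marginal
    products.  The clamp keeps cells with ``|O - E| <= 0.5`` from
    contributing (the correction cannot overshoot past the expectation).
    Returns NaN when a marginal is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("cell counts must be >= 0")
    n = t.sum()
    if n <= 0:
        raise ValueError("table must have positive total count")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        return float("nan")
    expected = np.outer(row, col) / n
    d = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    return float((d**2 / expected).sum())


def two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance Student t from group summaries; df = n1 + n2 - 2."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be > 0")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U for the first sample, with the two-sided
    normal-approximation p value (midrank ties, tie-corrected variance)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
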