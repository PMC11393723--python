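"""Window scorer: fixed-width child-skeleton window -> SMM confidence in [0, 1].

The detection pipeline only requires *some* map from a 200-frame window of
the child's skeleton to a confidence score; any such map (e.g. a trained
spatio-temporal network) can be plugged in as a plain callable.  The shipped
baseline exploits the defining kinematic property of stereotypical motor
movements — sustained rhythmic oscillation of body parts at roughly
0.5-5 Hz — via interpretable spectral features and a logistic model:

1.  coordinates are normalized per window (centered on the window-mean
    mid-hip, scaled by the median shoulder-hip distance) so camera geometry
    and body size drop out;
2.  short occlusion gaps (<= 10 frames) are linearly interpolated; longer
    gaps are zero-filled and reduce the window's mean-confidence feature;
3.  per joint: dominant oscillation frequency, fraction of spectral power in
    the 0.5-5 Hz band, velocity autocorrelation peak, and displacement
    amplitude;
4.  across joints: quantiles of the per-frame band-limited motion envelope,
    which track what *fraction of the window* is oscillatory rather than
    just how strongly any part of it oscillates;
5.  a logistic regression on the aggregated feature vector yields the
    confidence.

Models serialize to a single JSON file with a version tag, so scoring a
saved model does not require scikit-learn objects to round-trip.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .annotations import AnnotatedSegment
from .pose_io import JOINT_INDEX, N_KEYPOINTS, Track, track_dense_array

__all__ = [
    "DEFAULT_WINDOW_WIDTH",
    "SkeletonWindow",
    "WindowFeatures",
    "ScorerModel",
    "LowVisibilityError",
    "DegenerateTrainingError",
    "extract_window_features",
    "feature_vector",
    "train_baseline_scorer",
    "score_window",
    "window_from_dense",
    "windows_from_segments",
    "windows_from_segments_dense",
    "save_model",
    "load_model",
]

DEFAULT_WINDOW_WIDTH = 200

#: SMM oscillations of interest live in this band (Hz): body rocking at the
#: slow end, hand flapping at the fast end.
BAND_HZ = (0.5, 5.0)

#: Analysis band used for the band-power sum, the envelope band-pass filter
#: and the autocorrelation lag range: the nominal band plus margins, so that
#: oscillations at the band edges are not lost to filter roll-off or to
#: spectral leakage (the 200-frame periodogram has ~0.15 Hz bins).
ANALYSIS_BAND_HZ = (0.35, 5.5)

#: Occlusion gaps longer than this many frames are zero-filled, not interpolated.
MAX_INTERP_GAP = 10

_MODEL_FORMAT_VERSION = 1

_HIPS = (JOINT_INDEX["left_hip"], JOINT_INDEX["right_hip"])
_SHOULDERS = (JOINT_INDEX["left_shoulder"], JOINT_INDEX["right_shoulder"])


class LowVisibilityError(ValueError):
    """Too many missing joints in a window for reliable feature extraction."""


class DegenerateTrainingError(ValueError):
    """Training set does not contain both classes."""


class UnfittedModelError(RuntimeError):
    """score_window called on a model that has not been fitted/loaded."""


@dataclass
class SkeletonWindow:
    """A fixed-width slice of the child track: (W, 17, 3) of (x, y, confidence)."""

    data: np.ndarray
    fps: float = 30.0
    start_frame: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1:] != (N_KEYPOINTS, 3):
            raise ValueError(f"window data must be (W, 17, 3), got {self.data.shape}")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def width(self) -> int:
        return self.data.shape[0]


@dataclass
class WindowFeatures:
    """Interpretable periodicity features of one window.

    Per-joint arrays are in COCO-17 order.  All coordinate-derived features
    are computed on normalized coordinates (torso-length units), which makes
    them invariant to translation and uniform spatial scaling of the input.
    """

    dominant_freq_hz: np.ndarray  # (17,)
    band_power_frac: np.ndarray  # (17,) in [0, 1]
    autocorr_peak: np.ndarray  # (17,) velocity autocorrelation peak, lag > 0
    amplitude: np.ndarray  # (17,) RMS-based displacement amplitude, torso units
    envelope_quantiles: np.ndarray  # (3,) q25/q50/q75 of band-motion envelope
    mean_confidence: float
    long_gap_joints: int = 0  # joints that had at least one zero-filled gap


FEATURE_NAMES = (
    "band_frac_max",
    "band_frac_mean",
    "autocorr_max",
    "autocorr_mean",
    "log_amp_max",
    "log_env_q25",
    "log_env_q50",
    "log_env_q75",
    "dom_freq_top_joint",
    "mean_confidence",
)


def _fill_gaps(coords: np.ndarray, visible: np.ndarray, max_gap: int) -> tuple[np.ndarray, bool]:
    """Interpolate short invisible runs of one joint; zero-fill long ones.

    ``coords``: (W, 2); ``visible``: (W,) bool.  Returns filled coords and a
    flag marking whether any long gap was zero-filled.  Edge gaps are held at
    the nearest visible value when short.
    """
    out = coords.copy()
    w = len(visible)
    if visible.all():
        return out, False
    if not visible.any():
        return np.zeros_like(out), True
    idx = np.flatnonzero(visible)
    long_gap = False
    # run-length scan over invisible stretches
    run_start = None
    for t in range(w + 1):
        invisible = t < w and not visible[t]
        if invisible and run_start is None:
            run_start = t
        elif not invisible and run_start is not None:
            run_len = t - run_start
            if run_len <= max_gap:
                left = run_start - 1
                right = t if t < w else None
                for k in range(run_start, t):
                    if left < 0:
                        out[k] = coords[right]
                    elif right is None:
                        out[k] = coords[left]
                    else:
                        a = (k - left) / (right - left)
                        out[k] = (1 - a) * coords[left] + a * coords[right]
            else:
                out[run_start:t] = 0.0
                long_gap = True
            run_start = None
    del idx
    return out, long_gap


def normalize_window(w: SkeletonWindow) -> tuple[np.ndarray, np.ndarray, int]:
    """Center on the window-mean mid-hip and scale by median torso length.

    Returns ``(coords, visible, n_long_gap_joints)`` where ``coords`` is
    (W, 17, 2) gap-filled normalized coordinates and ``visible`` the (W, 17)
    visibility mask before filling.  Centering uses one offset for the whole
    window so that within-window motion (the signal of interest) survives.
    """
    xy = w.data[:, :, :2]
    conf = w.data[:, :, 2]
    visible = conf > 0

    hip_vis = visible[:, _HIPS]
    hip_xy = xy[:, _HIPS, :]
    if hip_vis.any():
        center = hip_xy[hip_vis].mean(axis=0)
    elif visible.any():
        center = xy[visible].mean(axis=0)
    else:
        center = np.zeros(2)

    # median shoulder-hip distance over frames where both ends are measurable
    torso = []
    for t in range(w.width):
        sh = xy[t, [j for j in _SHOULDERS if visible[t, j]], :]
        hp = xy[t, [j for j in _HIPS if visible[t, j]], :]
        if len(sh) and len(hp):
            torso.append(np.linalg.norm(sh.mean(axis=0) - hp.mean(axis=0)))
    scale = float(np.median(torso)) if torso else 1.0
    if scale <= 0:
        scale = 1.0

    norm = (xy - center) / scale
    filled = np.zeros_like(norm)
    n_long = 0
    for j in range(N_KEYPOINTS):
        filled[:, j, :], long_gap = _fill_gaps(norm[:, j, :], visible[:, j], MAX_INTERP_GAP)
        n_long += int(long_gap)
    return filled, visible, n_long


def extract_window_features(w: SkeletonWindow) -> WindowFeatures:
    """Compute periodicity features; raises :class:`LowVisibilityError` when
    fewer than half the frames have at least 8 visible joints."""
    conf = w.data[:, :, 2]
    visible = conf > 0
    if (visible.sum(axis=1) >= 8).mean() < 0.5:
        raise LowVisibilityError(
            "window has <50% frames with >=8 visible joints; features unreliable"
        )
    coords, visible, n_long = normalize_window(w)
    W = w.width
    fs = w.fps
    nyq = fs / 2.0

    dom_freq = np.zeros(N_KEYPOINTS)
    band_frac = np.zeros(N_KEYPOINTS)
    ac_peak = np.zeros(N_KEYPOINTS)
    amp = np.zeros(N_KEYPOINTS)

    # shared band-pass filter for the envelope
    sos = signal.butter(
        3,
        [ANALYSIS_BAND_HZ[0] / nyq, min(ANALYSIS_BAND_HZ[1] / nyq, 0.99)],
        btype="bandpass",
        output="sos",
    )
    env_per_joint = np.zeros((W, N_KEYPOINTS))
    smooth_n = max(int(round(fs / 2)), 1)  # ~0.5 s RMS smoothing
    kernel = np.ones(smooth_n) / smooth_n

    min_lag = max(int(np.floor(fs / ANALYSIS_BAND_HZ[1])), 1)
    max_lag = min(int(np.ceil(fs / ANALYSIS_BAND_HZ[0])), W - 2)

    for j in range(N_KEYPOINTS):
        p = coords[:, j, :] - coords[:, j, :].mean(axis=0)
        var = p.var(axis=0).sum()
        amp[j] = np.sqrt(2.0 * var)
        if var < 1e-12:
            continue
        # combined x+y power spectrum (Hann window)
        freqs, px = signal.periodogram(p[:, 0], fs=fs, window="hann")
        _, py = signal.periodogram(p[:, 1], fs=fs, window="hann")
        psd = px + py
        psd[0] = 0.0
        total = psd.sum()
        if total > 0:
            dom_freq[j] = freqs[int(np.argmax(psd))]
            in_band = (freqs >= ANALYSIS_BAND_HZ[0]) & (freqs <= ANALYSIS_BAND_HZ[1])
            band_frac[j] = float(psd[in_band].sum() / total)
        # velocity autocorrelation peak at oscillation-scale lags
        v = np.diff(p, axis=0)
        denom = (v * v).sum()
        if denom > 1e-12 and max_lag > min_lag:
            acs = [
                (v[:-l] * v[l:]).sum() / denom for l in range(min_lag, max_lag + 1)
            ]
            ac_peak[j] = float(np.max(acs))
        # band-limited motion envelope
        if W > 21:  # sosfiltfilt needs padding room
            band = signal.sosfiltfilt(sos, p, axis=0)
            mag2 = (band**2).sum(axis=1)
            env_per_joint[:, j] = np.sqrt(np.convolve(mag2, kernel, mode="same"))

    env = env_per_joint.max(axis=1)
    env_q = np.quantile(env, [0.25, 0.5, 0.75])
    return WindowFeatures(
        dominant_freq_hz=dom_freq,
        band_power_frac=band_frac,
        autocorr_peak=ac_peak,
        amplitude=amp,
        envelope_quantiles=env_q,
        mean_confidence=float(conf[visible].mean()) if visible.any() else 0.0,
        long_gap_joints=n_long,
    )


def feature_vector(f: WindowFeatures) -> np.ndarray:
    """Aggregate per-joint features into the fixed-length model input."""
    top_joint = int(np.argmax(f.band_power_frac))
    return np.array(
        [
            f.band_power_frac.max(),
            f.band_power_frac.mean(),
            f.autocorr_peak.max(),
            f.autocorr_peak.mean(),
            np.log1p(f.amplitude.max()),
            np.log1p(f.envelope_quantiles[0]),
            np.log1p(f.envelope_quantiles[1]),
            np.log1p(f.envelope_quantiles[2]),
            f.dominant_freq_hz[top_joint],
            f.mean_confidence,
        ]
    )


@dataclass
class ScorerModel:
    """Fitted logistic map from window features to SMM confidence."""

    coef: np.ndarray | None = None
    intercept: float = 0.0
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0
    n_windows: int = 0
    version: int = _MODEL_FORMAT_VERSION

    @property
    def fitted(self) -> bool:
        return self.coef is not None

    def decision(self, x: np.ndarray) -> float:
        z = (x - self.scaler_mean) / self.scaler_scale
        return float(self.coef @ z + self.intercept)


def train_baseline_scorer(
    windows: Sequence[SkeletonWindow],
    labels: Sequence[float],
    seed: int = 0,
) -> ScorerModel:
    """Fit the logistic baseline on labeled windows.

    Labels may be binary (1 = window drawn from an SMM segment) or
    fractional in [0, 1] — the fraction of the window's frames that lie
    inside an SMM segment.  With fractional labels the fitted score
    estimates the window's *SMM content* rather than a saturated class
    probability, which is what frame-wise max aggregation followed by a high
    threshold needs: a window must be mostly SMM to clear the threshold, so
    detected events hug the true episode boundaries.  Fractional targets are
    fit by cross-entropy via the standard two-copy sample-weight expansion
    (each window enters once with label 1 and weight y, once with label 0
    and weight 1 - y).

    Training is deterministic for a fixed seed and input order (L-BFGS on a
    convex objective from a fixed start).  Raises
    :class:`DegenerateTrainingError` unless both classes are represented
    (some label < 1/2 and some label > 1/2).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.preprocessing import StandardScaler

    y = np.asarray(labels, dtype=float)
    if len(windows) != len(y):
        raise ValueError("windows and labels must have equal length")
    if y.size and ((y < 0).any() or (y > 1).any()):
        raise ValueError("labels must lie in [0, 1]")
    if not ((y > 0.5).any() and (y < 0.5).any()):
        raise DegenerateTrainingError("training needs both positive and negative windows")
    X = np.vstack([feature_vector(extract_window_features(w)) for w in windows])
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    X2 = np.vstack([Xs, Xs])
    y2 = np.concatenate([np.ones(len(y)), np.zeros(len(y))])
    w2 = np.concatenate([y, 1.0 - y])
    keep = w2 > 0
    lr = LogisticRegression(C=1.0, max_iter=2000, random_state=seed).fit(
        X2[keep], y2[keep], sample_weight=w2[keep]
    )
    return ScorerModel(
        coef=lr.coef_[0].astype(float),
        intercept=float(lr.intercept_[0]),
        scaler_mean=scaler.mean_.astype(float),
        scaler_scale=scaler.scale_.astype(float),
        seed=seed,
        n_windows=len(y),
    )


def score_window(m: ScorerModel, w: SkeletonWindow) -> float:
    """SMM confidence in [0, 1] for one window; deterministic."""
    if not m.fitted:
        raise UnfittedModelError("model has not been fitted or loaded")
    try:
        x = feature_vector(extract_window_features(w))
    except LowVisibilityError:
        return 0.0  # unscorable windows are treated as confident non-SMM
    z = m.decision(x)
    return float(1.0 / (1.0 + np.exp(-np.clip(z, -500, 500))))


WindowScorer = Callable[[SkeletonWindow], float]


def as_window_scorer(m: "ScorerModel | WindowScorer") -> WindowScorer:
    """Adapter: accept either a fitted ScorerModel or any window -> score callable."""
    if isinstance(m, ScorerModel):
        return lambda w: score_window(m, w)
    if callable(m):
        return m
    raise TypeError(f"cannot use {type(m).__name__} as a window scorer")


def window_from_dense(
    dense: np.ndarray, start: int, width: int, fps: float = 30.0
) -> SkeletonWindow:
    """Slice a (n_frames, 17, 3) dense child array into one window."""
    return SkeletonWindow(data=dense[start : start + width], fps=fps, start_frame=start)


def windows_from_segments(
    track: Track,
    segments: Sequence[AnnotatedSegment],
    width: int = DEFAULT_WINDOW_WIDTH,
    n_frames: int | None = None,
    fractional_labels: bool = True,
    offsets: Sequence[float] = (-0.5, -0.25, 0.0, 0.25, 0.5),
) -> tuple[list[SkeletonWindow], list[float]]:
    """Build labeled training windows around each annotated segment.

    For every segment, one window is placed at the segment midpoint plus
    each of ``offsets`` (in units of the window width) and clamped to the
    recording bounds.  With ``fractional_labels`` (the default) each
    window's label is the fraction of its frames inside any SMM segment of
    the assessment; the off-center windows therefore provide the
    partial-content exemplars (labels strictly between 0 and 1) that anchor
    the score's calibration — the fitted score then tracks a window's SMM
    content instead of saturating, so a high detection threshold keeps
    detected events close to the true episode boundaries.  With binary
    labels, only the centered window per segment is used and labeled with
    the segment class.
    """
    dense = track_dense_array(track, n_frames)
    return windows_from_segments_dense(
        dense, track.fps, segments, width=width,
        fractional_labels=fractional_labels, offsets=offsets,
    )


def windows_from_segments_dense(
    dense: np.ndarray,
    fps: float,
    segments: Sequence[AnnotatedSegment],
    width: int = DEFAULT_WINDOW_WIDTH,
    fractional_labels: bool = True,
    offsets: Sequence[float] = (-0.5, -0.25, 0.0, 0.25, 0.5),
) -> tuple[list[SkeletonWindow], list[float]]:
    """Array-backed core of :func:`windows_from_segments`."""
    from .annotations import rasterize_segments

    n = dense.shape[0]
    if n < width:
        raise ValueError(f"recording ({n} frames) shorter than window ({width})")
    smm_mask = rasterize_segments([s for s in segments if s.is_smm], fps, n)
    if not fractional_labels:
        offsets = (0.0,)
    windows, labels = [], []
    for seg in segments:
        mid = 0.5 * (seg.start_s + seg.end_s) * fps
        for off in offsets if seg.is_smm else (0.0,):
            start = int(round(mid - width / 2 + off * width))
            start = min(max(start, 0), n - width)
            windows.append(window_from_dense(dense, start, width, fps=fps))
            if fractional_labels:
                labels.append(float(smm_mask[start : start + width].mean()))
            else:
                labels.append(float(seg.is_smm))
    return windows, labels


def save_model(m: ScorerModel, path) -> None:
    if not m.fitted:
        raise UnfittedModelError("refusing to serialize an unfitted model")
    payload = {
        "format": "smmkit-scorer",
        "version": m.version,
        "feature_names": list(m.feature_names),
        "coef": m.coef.tolist(),
        "intercept": m.intercept,
        "scaler_mean": m.scaler_mean.tolist(),
        "scaler_scale": m.scaler_scale.tolist(),
        "seed": m.seed,
        "n_windows": m.n_windows,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ScorerModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "smmkit-scorer":
        raise ValueError(f"{path} is not a smmkit scorer model file")
    return ScorerModel(
        coef=np.asarray(payload["coef"], dtype=float),
        intercept=float(payload["intercept"]),
        scaler_mean=np.asarray(payload["scaler_mean"], dtype=float),
        scaler_scale=np.asarray(payload["scaler_scale"], dtype=float),
        feature_names=tuple(payload["feature_names"]),
        seed=int(payload["seed"]),
        n_windows=int(payload["n_windows"]),
        version=int(payload["version"]),
    )
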