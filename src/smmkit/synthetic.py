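"""Seeded generator of multi-person skeleton streams with known SMM episodes.

The generator emulates the statistical structure of pose-tracked
behavioral-assessment recordings: a small child skeleton and one or more
larger adult skeletons move smoothly and aperiodically (mean-reverting
drift), and the child occasionally produces a stereotypical motor movement
(SMM) episode — a sustained sinusoidal oscillation of type-specific joints
(wrist flapping at 2-4 Hz, torso rocking at 0.5-1.5 Hz, whole-body vertical
jumping at 1-3 Hz) superposed on the background motion.  Episode lengths
follow a lognormal distribution moment-matched to a mean of 9.89 s and SD
of 9.56 s (strong right skew, as the SD ~ mean implies); episodes are
placed uniformly at random without overlap.  Joint detections drop out
(confidence 0) independently at a configurable rate.

Everything is reproducible from a single integer seed; a corpus spawns
per-assessment child seeds from it, so corpora are byte-identical across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
from scipy.signal import lfilter

from .annotations import (
    AnnotatedSegment,
    CapacityError,
    DatasetSplit,
    sample_negative_segments,
    write_annotations_csv,
)
from .pose_io import N_KEYPOINTS, Keypoint, SkeletonFrame, Track, write_skeleton_stream

__all__ = [
    "SimConfig",
    "SimResult",
    "Corpus",
    "CorpusAssessment",
    "lognormal_params",
    "easy_preset",
    "simulate_assessment",
    "make_benchmark_corpus",
    "build_training_segments",
]

# Canonical standing pose: (x, y) offsets from the mid-hip in units of the
# shoulder-ankle extent H; y grows downward (image convention).
_TEMPLATE = np.array(
    [
        (0.00, -0.50),  # nose
        (0.03, -0.53), (-0.03, -0.53),  # eyes
        (0.06, -0.51), (-0.06, -0.51),  # ears
        (0.14, -0.35), (-0.14, -0.35),  # shoulders
        (0.20, -0.15), (-0.20, -0.15),  # elbows
        (0.24, 0.02), (-0.24, 0.02),  # wrists
        (0.09, 0.00), (-0.09, 0.00),  # hips
        (0.10, 0.33), (-0.10, 0.33),  # knees
        (0.11, 0.65), (-0.11, 0.65),  # ankles
    ]
)

# Per-type oscillation recipe: frequency band (Hz) and per-joint
# (x-amplitude, y-amplitude) multipliers of cfg.amplitude_px.
_WRISTS, _ELBOWS = (9, 10), (7, 8)
_HEAD = (0, 1, 2, 3, 4)
_SHOULDERS, _HIPS = (5, 6), (11, 12)

_SMM_RECIPES: dict[str, dict] = {
    "flapping": {
        "band": (2.0, 4.0),
        "joints": {j: (0.3, 1.0) for j in _WRISTS} | {j: (0.15, 0.5) for j in _ELBOWS},
    },
    "rocking": {
        "band": (0.5, 1.5),
        "joints": {j: (1.0, 0.0) for j in _HEAD + _SHOULDERS}
        | {j: (0.3, 0.0) for j in _HIPS},
    },
    "jumping": {
        "band": (1.0, 3.0),
        "joints": {j: (0.0, 1.0) for j in range(N_KEYPOINTS)},
    },
}

_SMM_LABELS = {"flapping": "hand_flapping", "rocking": "body_rocking", "jumping": "jumping"}


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal with the given mean and SD (moment matching)."""
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be > 0")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(mu), float(np.sqrt(sigma2))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated assessment.

    Defaults mirror the annotated corpus the generator emulates: 30 fps
    recordings, rare episodes (0.2/min x mean 9.89 s ~ 3.3% of the
    timeline), child skeletons ~0.6x adult height.
    """

    fps: float = 30.0
    duration_s: float = 600.0
    n_persons: int = 2
    child_scale: float = 0.6
    adult_height_px: float = 420.0
    smm_rate_per_min: float = 0.2
    event_len_mean_s: float = 9.89
    event_len_sd_s: float = 9.56
    smm_types: tuple[str, ...] = ("flapping", "rocking", "jumping")
    amplitude_px: float = 35.0
    drift_px: float = 40.0  # stationary SD of whole-body mean-reverting drift
    drift_tau_s: float = 8.0  # drift time constant; >> 2 s keeps it out of band
    jitter_px: float = 1.5  # per-joint tracking noise (fast, small)
    jitter_tau_s: float = 0.15
    joint_dropout: float = 0.02
    adversarial_adults: bool = False  # adults also oscillate (stress test)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0 or self.n_persons < 1:
            raise ValueError("fps, duration_s and n_persons must be positive")
        if not 0 < self.child_scale:
            raise ValueError("child_scale must be > 0")
        if not 0 <= self.joint_dropout <= 1:
            raise ValueError("joint_dropout must be in [0, 1]")
        unknown = set(self.smm_types) - set(_SMM_RECIPES)
        if unknown:
            raise ValueError(f"unknown SMM types: {sorted(unknown)}")


def easy_preset(**overrides) -> SimConfig:
    """High-amplitude, low-dropout conditions: clearly visible SMMs."""
    base = dict(amplitude_px=55.0, joint_dropout=0.005, jitter_px=1.0)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class SimResult:
    """One simulated assessment: per-person arrays, ground truth, true child id.

    Motion is stored densely as one ``(n_frames, 17, 3)`` array of
    ``(x, y, confidence)`` per person (long recordings as per-keypoint
    objects would dominate memory); :attr:`tracks` materializes the
    object-level view on demand and does not cache it.
    """

    person_arrays: dict[int, np.ndarray]
    segments: list[AnnotatedSegment]
    child_person_id: int
    config: SimConfig

    @property
    def tracks(self) -> list[Track]:
        return _tracks_from_dense(self.person_arrays, self.config.fps)


def _ou_series(rng: np.random.Generator, n: int, sd: float, tau_s: float, fps: float,
               shape: tuple = ()) -> np.ndarray:
    """Stationary AR(1) (discretized mean-reverting) noise, shape (n, *shape)."""
    if sd == 0:
        return np.zeros((n, *shape))
    a = np.exp(-1.0 / (tau_s * fps))
    eps = rng.standard_normal((n, *shape)) * sd * np.sqrt(1.0 - a * a)
    eps[0] = rng.standard_normal(shape) * sd  # stationary start
    return lfilter([1.0], [1.0, -a], eps, axis=0)


def _place_episodes(
    rng: np.random.Generator, lengths: np.ndarray, duration_s: float, margin_s: float = 1.0
) -> np.ndarray:
    """Uniform non-overlapping placement; returns start times (sorted)."""
    total = lengths.sum() + 2 * margin_s
    free = duration_s - total
    if free <= 0:
        raise CapacityError(
            f"cannot place {lengths.size} episodes totalling {lengths.sum():.1f} s "
            f"in {duration_s:.1f} s",
            achieved=0,
        )
    gaps = np.sort(rng.uniform(0.0, free, size=lengths.size))
    starts = margin_s + gaps + np.concatenate([[0.0], np.cumsum(lengths[:-1])])
    return starts


def _tracks_from_dense(per_person: dict[int, np.ndarray], fps: float) -> list[Track]:
    tracks = []
    for pid in sorted(per_person):
        arr = per_person[pid]
        frames = []
        for t in range(arr.shape[0]):
            kps = tuple(
                Keypoint(float(arr[t, j, 0]), float(arr[t, j, 1]), float(arr[t, j, 2]))
                for j in range(N_KEYPOINTS)
            )
            frames.append(SkeletonFrame(frame_index=t, person_id=pid, keypoints=kps))
        tracks.append(Track(person_id=pid, frames=frames, fps=fps))
    return tracks


def _oscillation(
    rng: np.random.Generator,
    n_frames: int,
    fps: float,
    start_f: int,
    end_f: int,
    band: tuple[float, float],
    joints: dict[int, tuple[float, float]],
    amplitude_px: float,
) -> np.ndarray:
    """(n_frames, 17, 2) additive sinusoidal displacement with cosine ramps."""
    out = np.zeros((n_frames, N_KEYPOINTS, 2))
    freq = rng.uniform(*band)
    phase = rng.uniform(0.0, 2 * np.pi)
    t = np.arange(start_f, end_f) / fps
    wave = np.sin(2 * np.pi * freq * t + phase)
    # raised-cosine on/off ramps (up to 0.5 s) avoid discontinuities
    seg_len = end_f - start_f
    ramp_n = min(int(fps * 0.5), seg_len // 2)
    env = np.ones(seg_len)
    if ramp_n > 0:
        r = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
        env[:ramp_n] = r
        env[seg_len - ramp_n :] = r[::-1]
    for j, (ax, ay) in joints.items():
        out[start_f:end_f, j, 0] = amplitude_px * ax * wave * env
        out[start_f:end_f, j, 1] = amplitude_px * ay * wave * env
    return out


def simulate_assessment(
    cfg: SimConfig, assessment_id: str = "A000", child_id: str = "C000"
) -> SimResult:
    """Generate one assessment: multi-person tracks plus ground-truth segments.

    The number of episodes is deterministic, ``floor(rate x minutes)``;
    their lengths, types, frequencies, placements and all motion noise come
    from the seeded generator.  Raises :class:`~smmkit.annotations.CapacityError`
    when the requested episodes cannot fit in the recording.
    """
    rng = np.random.default_rng(cfg.seed)
    n_frames = int(round(cfg.duration_s * cfg.fps))
    n_events = int(np.floor(cfg.smm_rate_per_min * cfg.duration_s / 60.0))
    mu, sigma = lognormal_params(cfg.event_len_mean_s, cfg.event_len_sd_s)

    child_pid = int(rng.integers(cfg.n_persons))
    # lay people out left to right with jittered centers
    frame_w = 1920.0
    centers_x = (np.arange(cfg.n_persons) + 0.5) / cfg.n_persons * frame_w
    centers_x = centers_x + rng.uniform(-60, 60, cfg.n_persons)
    floor_y = 900.0

    segments: list[AnnotatedSegment] = []
    per_person: dict[int, np.ndarray] = {}
    for pid in range(cfg.n_persons):
        is_child = pid == child_pid
        height = cfg.adult_height_px * (
            cfg.child_scale if is_child else float(rng.uniform(0.95, 1.1))
        )
        base = _TEMPLATE * height  # (17, 2)
        center = np.array([centers_x[pid], floor_y - 0.65 * height])
        pose = base + center  # ankles near floor_y

        drift = _ou_series(rng, n_frames, cfg.drift_px, cfg.drift_tau_s, cfg.fps, (2,))
        jitter = _ou_series(
            rng, n_frames, cfg.jitter_px, cfg.jitter_tau_s, cfg.fps, (N_KEYPOINTS, 2)
        )
        xy = pose[None, :, :] + drift[:, None, :] + jitter

        if is_child and n_events > 0:
            lengths = rng.lognormal(mu, sigma, size=n_events)
            starts = _place_episodes(rng, lengths, cfg.duration_s)
            for st, ln in zip(starts, lengths):
                smm_type = str(rng.choice(list(cfg.smm_types)))
                recipe = _SMM_RECIPES[smm_type]
                sf = int(round(st * cfg.fps))
                ef = min(int(round((st + ln) * cfg.fps)), n_frames)
                xy += _oscillation(
                    rng, n_frames, cfg.fps, sf, ef, recipe["band"],
                    recipe["joints"], cfg.amplitude_px,
                )
                segments.append(
                    AnnotatedSegment(
                        assessment_id=assessment_id,
                        child_id=child_id,
                        camera_id="cam0",
                        start_s=float(st),
                        end_s=float(st + ln),
                        label=_SMM_LABELS[smm_type],
                        skeleton_id=pid,
                        annotator_id="ground_truth",
                    )
                )
        elif not is_child and cfg.adversarial_adults and n_events > 0:
            # adults occasionally oscillate too, to stress child selection
            ln = float(rng.lognormal(mu, sigma))
            st = float(rng.uniform(1.0, max(cfg.duration_s - ln - 1.0, 1.5)))
            recipe = _SMM_RECIPES[str(rng.choice(list(cfg.smm_types)))]
            xy += _oscillation(
                rng, n_frames, cfg.fps,
                int(st * cfg.fps), min(int((st + ln) * cfg.fps), n_frames),
                recipe["band"], recipe["joints"], cfg.amplitude_px,
            )

        conf = rng.uniform(0.5, 1.0, size=(n_frames, N_KEYPOINTS))
        conf[rng.random((n_frames, N_KEYPOINTS)) < cfg.joint_dropout] = 0.0
        per_person[pid] = np.concatenate([xy, conf[:, :, None]], axis=2)

    segments.sort(key=lambda s: s.start_s)
    return SimResult(
        person_arrays=per_person,
        segments=segments,
        child_person_id=child_pid,
        config=cfg,
    )


@dataclass
class CorpusAssessment:
    assessment_id: str
    child_id: str
    result: SimResult


@dataclass
class Corpus:
    """A set of simulated assessments with distinct children and a child split."""

    assessments: list[CorpusAssessment]
    split: DatasetSplit

    @property
    def segments(self) -> list[AnnotatedSegment]:
        return [s for a in self.assessments for s in a.result.segments]

    def write_to(self, directory) -> None:
        """Write skeleton-stream JSON files and the ground-truth annotation CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for a in self.assessments:
            write_skeleton_stream(
                directory / f"{a.assessment_id}_cam0.json", a.result.tracks
            )
        write_annotations_csv(directory / "annotations.csv", self.segments)


def make_benchmark_corpus(
    n_assessments: int,
    template: SimConfig,
    seed: int = 0,
    n_test_children: int = 0,
    rate_dispersion: float = 0.96,
    max_smm_fraction: float = 0.3,
) -> Corpus:
    """Simulate ``n_assessments`` single-child assessments and split by child.

    Each assessment gets a distinct child and its own SMM rate drawn from a
    lognormal centered on the template rate with log-SD ``rate_dispersion``
    (children differ widely in SMM burden; the default dispersion matches an
    interquartile ratio of ~2x around the median rate).  Drawn rates are
    truncated so the expected SMM time stays below ``max_smm_fraction`` of
    the recording — SMMs are rare events, and an untruncated heavy-tailed
    draw could otherwise overfill a recording.  The last
    ``n_test_children`` children form the held-out test side.
    """
    if n_assessments < 2:
        raise ValueError("need at least 2 assessments")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_assessments)
    rate_rng = np.random.default_rng(ss.spawn(1)[0])
    rate_cap = max_smm_fraction * 60.0 / template.event_len_mean_s
    assessments = []
    for i in range(n_assessments):
        rate = min(
            float(template.smm_rate_per_min * rate_rng.lognormal(0.0, rate_dispersion)),
            rate_cap,
        )
        cfg = replace(
            template,
            smm_rate_per_min=rate,
            seed=int(child_seeds[i].generate_state(1)[0] % (2**31)),
        )
        aid, cid = f"A{i:03d}", f"C{i:03d}"
        assessments.append(CorpusAssessment(aid, cid, simulate_assessment(cfg, aid, cid)))
    segs = [s for a in assessments for s in a.result.segments]
    # ensure every child appears in the split even if it produced no episodes
    all_children = {a.child_id: [] for a in assessments}
    for s in segs:
        all_children[s.child_id].append(s)
    test_ids = [a.child_id for a in assessments[n_assessments - n_test_children :]] if n_test_children else []
    split = DatasetSplit(
        train={c: v for c, v in all_children.items() if c not in set(test_ids)},
        test={c: all_children[c] for c in test_ids},
    )
    return Corpus(assessments=assessments, split=split)


def build_training_segments(
    corpus: Corpus, neg_per_pos: int = 4, seed: int = 0
) -> list[AnnotatedSegment]:
    """Ground-truth positives plus length-matched sampled negatives.

    For each training-side assessment with at least one episode, negatives
    are drawn with the empirical positive-length distribution, disjoint from
    every episode (ratio ``neg_per_pos``, mirroring the ~4:1 non-SMM:SMM
    segment ratio of annotated corpora).
    """
    ss = np.random.SeedSequence(seed)
    out: list[AnnotatedSegment] = []
    train_children = set(corpus.split.train)
    for a, sub_ss in zip(corpus.assessments, ss.spawn(len(corpus.assessments))):
        if a.child_id not in train_children:
            continue
        positives = a.result.segments
        out.extend(positives)
        if positives:
            try:
                negs = sample_negative_segments(
                    positives,
                    a.result.config.duration_s,
                    n=neg_per_pos * len(positives),
                    seed=int(sub_ss.generate_state(1)[0] % (2**31)),
                )
            except CapacityError as exc:
                # dense short assessments may not fit the full quota;
                # keep whatever could be placed
                negs = exc.partial
            out.extend(negs)
    return out
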