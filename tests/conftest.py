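"""Shared fixtures: hand-built skeleton windows and a small seeded corpus."""

from __future__ import annotations

import numpy as np
import pytest

from smmkit.pose_io import N_KEYPOINTS, JOINT_INDEX, Keypoint, SkeletonFrame, Track
from smmkit.pipeline import fit_baseline_from_corpus
from smmkit.synthetic import _TEMPLATE, easy_preset, make_benchmark_corpus

FPS = 30.0


def standing_pose(height_px: float = 300.0, center=(500.0, 400.0)) -> np.ndarray:
    """(17, 2) canonical standing pose in pixels."""
    return _TEMPLATE * height_px + np.asarray(center)


def make_window_array(
    kind: str = "static",
    width: int = 200,
    freq_hz: float = 2.0,
    amp_px: float = 40.0,
    joints: tuple[int, ...] = (JOINT_INDEX["left_wrist"], JOINT_INDEX["right_wrist"]),
    seed: int = 0,
    fps: float = FPS,
) -> np.ndarray:
    """(width, 17, 3) window: static pose, sinusoidal joints, or white noise."""
    rng = np.random.default_rng(seed)
    pose = standing_pose()
    xy = np.repeat(pose[None, :, :], width, axis=0)
    t = np.arange(width) / fps
    if kind == "sine":
        for j in joints:
            xy[:, j, 1] += amp_px * np.sin(2 * np.pi * freq_hz * t)
    elif kind == "noise":
        for j in joints:
            xy[:, j, :] += rng.standard_normal((width, 2)) * amp_px / np.sqrt(2)
    elif kind != "static":
        raise ValueError(kind)
    conf = np.full((width, N_KEYPOINTS, 1), 0.9)
    return np.concatenate([xy, conf], axis=2)


def track_from_array(arr: np.ndarray, person_id: int = 0, fps: float = FPS) -> Track:
    frames = []
    for i in range(arr.shape[0]):
        kps = tuple(
            Keypoint(float(arr[i, j, 0]), float(arr[i, j, 1]), float(arr[i, j, 2]))
            for j in range(N_KEYPOINTS)
        )
        frames.append(SkeletonFrame(frame_index=i, person_id=person_id, keypoints=kps))
    return Track(person_id=person_id, frames=frames, fps=fps)


@pytest.fixture(scope="session")
def small_corpus():
    """Six 4-minute assessments (4 train / 2 test children), easy preset."""
    template = easy_preset(duration_s=240.0, smm_rate_per_min=0.75)
    return make_benchmark_corpus(6, template, seed=20, n_test_children=2)


@pytest.fixture(scope="session")
def small_model(small_corpus):
    return fit_baseline_from_corpus(small_corpus, seed=20)

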