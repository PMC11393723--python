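"""Skeleton-stream serialization, bounding-box geometry, and box matching."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smmkit.pose_io import (
    BBox,
    DegenerateSkeletonError,
    Keypoint,
    SkeletonFrame,
    SkeletonStreamError,
    Track,
    bbox_from_skeleton,
    iou,
    match_boxes_to_skeletons,
    read_skeleton_stream,
    track_dense_array,
    write_skeleton_stream,
)


def _frame(points, frame_index=0, person_id=0, fill_conf=0.0):
    """17-keypoint frame with the given visible (x, y) points first."""
    kps = [Keypoint(x, y, 0.9) for x, y in points]
    kps += [Keypoint(0.0, 0.0, fill_conf)] * (17 - len(kps))
    return SkeletonFrame(frame_index=frame_index, person_id=person_id, keypoints=tuple(kps))


def _random_frame(rng, frame_index=0, person_id=0):
    pts = rng.uniform(0, 1000, size=(17, 2))
    conf = rng.uniform(0.1, 1.0, size=17)
    kps = tuple(Keypoint(float(x), float(y), float(c)) for (x, y), c in zip(pts, conf))
    return SkeletonFrame(frame_index=frame_index, person_id=person_id, keypoints=kps)


class TestStreamIO:
    def test_round_trip_preserves_keypoints(self, tmp_path):
        rng = np.random.default_rng(0)
        tracks = [
            Track(person_id=p, frames=[_random_frame(rng, i, p) for i in range(3)])
            for p in (0, 1)
        ]
        path = tmp_path / "stream.json"
        write_skeleton_stream(path, tracks)
        back = read_skeleton_stream(path)
        assert [t.person_id for t in back] == [0, 1]
        for orig, rt in zip(tracks, back):
            for fo, fr in zip(orig.frames, rt.frames):
                for ko, kr in zip(fo.keypoints, fr.keypoints):
                    assert abs(ko.x - kr.x) < 1e-6
                    assert abs(ko.y - kr.y) < 1e-6
                    assert abs(ko.confidence - kr.confidence) < 1e-6

    def test_interleaved_persons_record_count(self, tmp_path):
        rng = np.random.default_rng(1)
        tracks = [
            Track(person_id=0, frames=[_random_frame(rng, i, 0) for i in range(100)]),
            Track(person_id=7, frames=[_random_frame(rng, i, 7) for i in range(0, 100, 2)]),
        ]
        path = tmp_path / "stream.json"
        write_skeleton_stream(path, tracks)
        # independent line-scan oracle: count raw records in the file
        with open(path) as fh:
            n_records = len(json.load(fh))
        back = read_skeleton_stream(path)
        assert len(back) == 2
        assert sum(len(t) for t in back) == n_records == 150

    def test_empty_stream(self, tmp_path):
        path = tmp_path / "empty.json"
        path.write_text("[]")
        assert read_skeleton_stream(path) == []

    def test_malformed_file_names_record(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('[{"frame": 0, "person_id": 0}]')
        with pytest.raises(SkeletonStreamError, match="record 0"):
            read_skeleton_stream(path)

    def test_wrong_keypoint_count_is_schema_error(self, tmp_path):
        path = tmp_path / "short.json"
        path.write_text(json.dumps([{"frame": 0, "person_id": 0, "keypoints": [[1, 2, 0.5]] * 5}]))
        with pytest.raises(SkeletonStreamError, match="5 keypoints"):
            read_skeleton_stream(path)

    def test_unknown_fields_ignored(self, tmp_path):
        rec = {"frame": 0, "person_id": 3, "keypoints": [[1.0, 2.0, 0.5]] * 17, "extra": "x"}
        path = tmp_path / "extra.json"
        path.write_text(json.dumps([rec]))
        (track,) = read_skeleton_stream(path)
        assert track.person_id == 3

    def test_dense_array_fills_missing_frames(self):
        rng = np.random.default_rng(2)
        track = Track(person_id=0, frames=[_random_frame(rng, i, 0) for i in (0, 2, 5)])
        dense = track_dense_array(track)
        assert dense.shape == (6, 17, 3)
        assert (dense[1, :, 2] == 0).all() and (dense[2, :, 2] > 0).all()


class TestBBox:
    def test_min_max_with_padding(self):
        fr = _frame([(10, 10), (20, 30)])
        assert bbox_from_skeleton(fr, pad=0) == BBox(10, 10, 20, 30)
        assert bbox_from_skeleton(fr, pad=5) == BBox(5, 5, 25, 35)

    def test_matches_exhaustive_minmax_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            fr = _random_frame(rng)
            pad = float(rng.uniform(0, 10))
            box = bbox_from_skeleton(fr, pad=pad)
            xs = [k.x for k in fr.keypoints if k.confidence > 0]
            ys = [k.y for k in fr.keypoints if k.confidence > 0]
            assert box.x_min == pytest.approx(min(xs) - pad)
            assert box.x_max == pytest.approx(max(xs) + pad)
            assert box.y_min == pytest.approx(min(ys) - pad)
            assert box.y_max == pytest.approx(max(ys) + pad)

    def test_degenerate_skeleton_raises(self):
        with pytest.raises(DegenerateSkeletonError):
            bbox_from_skeleton(_frame([(5, 5)]))

    def test_missing_keypoints_excluded_from_geometry(self):
        kps = [Keypoint(10, 10, 0.9), Keypoint(20, 30, 0.9), Keypoint(999, 999, 0.0)]
        kps += [Keypoint(0, 0, 0.0)] * 14
        fr = SkeletonFrame(0, 0, tuple(kps))
        assert bbox_from_skeleton(fr) == BBox(10, 10, 20, 30)


boxes = st.builds(
    lambda x, y, w, h: BBox(x, y, x + w, y + h),
    st.floats(-100, 100),
    st.floats(-100, 100),
    st.floats(0.1, 200),
    st.floats(0.1, 200),
)


class TestIoU:
    def test_identity_disjoint_and_hand_case(self):
        a = BBox(0, 0, 2, 2)
        assert iou(a, a) == 1.0
        assert iou(a, BBox(10, 10, 12, 12)) == 0.0
        # intersection area 1, union 4 + 4 - 1 = 7
        assert iou(a, BBox(1, 1, 3, 3)) == pytest.approx(1 / 7)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(a=boxes, b=boxes)
    def test_symmetric_and_bounded(self, a, b):
        v = iou(a, b)
        assert 0.0 <= v <= 1.0 + 1e-12
        assert iou(b, a) == pytest.approx(v)
        assert iou(a, a) == pytest.approx(1.0)


class TestMatching:
    def test_single_pair(self):
        fr = _frame([(10, 10), (20, 30)])
        m = match_boxes_to_skeletons([BBox(10, 10, 20, 30)], [fr])
        assert m.pairs[0][:2] == (0, 0)
        assert m.unmatched_boxes == () and m.unmatched_persons == ()

    def test_two_boxes_two_skeletons_maximizes_total_iou(self):
        f0 = _frame([(0, 0), (10, 10)], person_id=0)
        f1 = _frame([(100, 100), (110, 110)], person_id=1)
        given_boxes = [BBox(99, 99, 111, 111), BBox(0, 0, 10, 10)]
        m = match_boxes_to_skeletons(given_boxes, [f0, f1])
        # brute force over both possible one-to-one assignments
        skels = [bbox_from_skeleton(f) for f in (f0, f1)]
        best = max(
            [(0, 1), (1, 0)],
            key=lambda perm: sum(iou(given_boxes[i], skels[j]) for i, j in enumerate(perm)),
        )
        assert {p[:2] for p in m.pairs} == {(i, j) for i, j in enumerate(best)}

    def test_more_boxes_than_skeletons(self):
        fr = _frame([(0, 0), (10, 10)], person_id=5)
        near, far = BBox(0, 0, 10, 10), BBox(5, 5, 15, 15)
        m = match_boxes_to_skeletons([far, near], [fr])
        assert m.pairs == ((1, 5, pytest.approx(1.0)),)
        assert m.unmatched_boxes == (0,)

    def test_zero_iou_left_unassigned(self):
        fr = _frame([(0, 0), (10, 10)])
        m = match_boxes_to_skeletons([BBox(500, 500, 600, 600)], [fr])
        assert m.pairs == ()
        assert m.unmatched_boxes == (0,) and m.unmatched_persons == (0,)
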