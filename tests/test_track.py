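"""Abandonment filtering, sexing rules and cosine label stability."""

import numpy as np
import pytest

from pnquant.track import (
    IndistinguishablePNError,
    Trajectory,
    assign_sex,
    build_area_trajectories,
    enforce_label_stability,
    filter_two_pn_frames,
    track_embryo,
)
from tests.conftest import make_detection


def _frames(counts, t0=10.0, dt=0.25, sep=30.0):
    """Detections with the given per-frame PN counts; the first two
    detections of a frame sit at stable, well-separated positions."""
    dets = []
    for fi, n in enumerate(counts):
        t = t0 + fi * dt
        positions = [(50.0, 50.0), (50.0 + sep, 50.0), (90.0, 120.0), (10.0, 110.0)]
        for k in range(n):
            dets.append(
                make_detection("E1", fi, t, positions[k], 900.0 + 40 * k)
            )
    return dets


class TestAbandonment:
    def test_non_2pn_frames_discarded_with_reason(self):
        track = filter_two_pn_frames(_frames([1, 2, 2, 3, 2]), min_retained_frames=3)
        assert [f.frame_index for f in track.frames] == [1, 2, 4]
        assert track.discarded_frames == [(0, "1PN"), (3, "3PN")]
        assert track.analyzable

    def test_all_2pn_nothing_discarded(self):
        track = filter_two_pn_frames(_frames([2] * 6))
        assert len(track.frames) == 6
        assert track.discarded_frames == []

    def test_all_0pn_unanalyzable(self):
        track = filter_two_pn_frames(_frames([0, 0, 0, 0]))
        assert not track.analyzable

    def test_too_few_retained_frames_unanalyzable(self):
        track = filter_two_pn_frames(_frames([2, 2, 2, 1]))
        assert not track.analyzable  # 3 retained < default minimum of 4


class TestAssignSex:
    def test_earlier_appearance_is_male(self):
        track = filter_two_pn_frames(_frames([2] * 5))
        # identity 0 first seen at 7.0 h, identity 1 at 8.5 h
        assign_sex(track, (7.0, 8.5))
        assert track.sexed
        # frame order is (female, male): identity 0 became male
        assert track.frames[0].detections[1].center_px == (50.0, 50.0)

    def test_simultaneous_appearance_larger_early_mean_is_male(self):
        dets = []
        for fi in range(5):
            t = 10.0 + 0.25 * fi
            dets.append(make_detection("E1", fi, t, (50.0, 50.0), 520.0 / 0.3275**2))
            dets.append(make_detection("E1", fi, t, (90.0, 50.0), 480.0 / 0.3275**2))
        track = filter_two_pn_frames(dets)
        assign_sex(track, (8.0, 8.0))
        male = track.frames[0].detections[1]
        assert male.area_um2 == pytest.approx(520.0)

    def test_identical_times_and_areas_indistinguishable(self):
        dets = []
        for fi in range(5):
            t = 10.0 + 0.25 * fi
            dets.append(make_detection("E1", fi, t, (50.0, 50.0), 900.0))
            dets.append(make_detection("E1", fi, t, (90.0, 50.0), 900.0))
        track = filter_two_pn_frames(dets)
        with pytest.raises(IndistinguishablePNError):
            assign_sex(track, (8.0, 8.0))

    def test_input_order_permutation_invariant(self, rng):
        dets = _frames([2] * 6)
        track_a = filter_two_pn_frames(list(dets))
        shuffled = list(dets)
        rng.shuffle(shuffled)
        track_b = filter_two_pn_frames(shuffled)
        assign_sex(track_a, (7.0, 8.5))
        assign_sex(track_b, (7.0, 8.5))
        for fa, fb in zip(track_a.frames, track_b.frames):
            assert [d.sex for d in fa.detections] == [d.sex for d in fb.detections]
            assert [d.center_px for d in fa.detections] == [d.center_px for d in fb.detections]


def _labelled_frames(vectors, t0=10.0):
    """One frame per female->male vector, labels as given."""
    dets = []
    for fi, (fx, fy, mx, my) in enumerate(vectors):
        t = t0 + 0.25 * fi
        dets.append(make_detection("E", fi, t, (fx, fy), 900.0, sex="female"))
        dets.append(make_detection("E", fi, t, (mx, my), 1000.0, sex="male"))
    return dets


class TestLabelStability:
    def test_consistent_labels_no_swaps(self):
        vecs = [(0, 0, 30, 0), (1, 0, 31, 1), (2, 1, 32, 1), (3, 1, 33, 2)]
        track = filter_two_pn_frames(_labelled_frames(vecs))
        assert track.sexed
        enforce_label_stability(track)
        assert track.swap_events == []
        assert len(track.frames) == 4

    def test_reversed_frame_swapped_back(self):
        vecs = [(0, 0, 30, 0), (1, 0, 31, 0), (32, 0, 2, 0), (3, 0, 33, 0)]
        track = filter_two_pn_frames(_labelled_frames(vecs))
        enforce_label_stability(track)
        assert track.swap_events == [2]
        # after the swap every consecutive pair satisfies cos > 0
        for a, b in zip(track.frames, track.frames[1:]):
            va = np.subtract(a.detections[1].center_px, a.detections[0].center_px)
            vb = np.subtract(b.detections[1].center_px, b.detections[0].center_px)
            assert np.dot(va, vb) > 0

    def test_perpendicular_vector_discarded(self):
        # second frame's inter-PN vector is orthogonal: cos = 0 under both
        # labelings, violating the strict > 0 rule
        vecs = [(0, 0, 30, 0), (0, 0, 0, 30), (2, 0, 32, 0), (3, 0, 33, 0)]
        track = filter_two_pn_frames(_labelled_frames(vecs))
        enforce_label_stability(track)
        assert (1, "stability") in track.discarded_frames
        assert len(track.frames) == 3

    def test_coincident_centers_discarded(self):
        vecs = [(0, 0, 30, 0), (5, 5, 5, 5), (2, 0, 32, 0), (3, 0, 33, 0)]
        track = filter_two_pn_frames(_labelled_frames(vecs))
        enforce_label_stability(track)
        assert (1, "coincident") in track.discarded_frames

    def test_unsexed_track_rejected(self):
        track = filter_two_pn_frames(_frames([2] * 4))
        with pytest.raises(ValueError, match="sexed"):
            enforce_label_stability(track)


class TestTrajectories:
    def test_lengths_match_retained_frames(self):
        track = filter_two_pn_frames(_frames([2] * 40))
        assign_sex(track, (7.0, 8.5))
        female, male = build_area_trajectories(track)
        assert len(female) == len(male) == 40

    def test_discarded_frames_excluded_from_lengths(self):
        counts = [2] * 43
        counts[0], counts[10], counts[20] = 1, 3, 0
        track = filter_two_pn_frames(_frames(counts))
        assign_sex(track, (7.0, 8.5))
        female, _ = build_area_trajectories(track)
        assert len(female) == 40

    def test_empty_track_rejected(self):
        track = filter_two_pn_frames(_frames([0, 0]))
        with pytest.raises(ValueError):
            build_area_trajectories(track)

    def test_trajectory_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            Trajectory("e", "female", [(10.0, 5.0), (10.0, 6.0)])
        with pytest.raises(ValueError, match="positive"):
            Trajectory("e", "female", [(10.0, 5.0), (11.0, -1.0)])


def test_track_embryo_full_chain():
    dets = _frames([1, 1, 2, 2, 2, 2, 2])
    track, female, male = track_embryo(dets)
    assert track.sexed
    assert len(female) == len(male) == 5
    # without appearance times the early-size rule applies: the larger PN
    # (second position, area 940 px) is called male
    assert track.frames[0].detections[1].area_px == pytest.approx(940.0)
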