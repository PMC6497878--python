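"""Segment decomposition, scaling curves, shape and border analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicomm import analysis as ana
from hicomm import community as comm
from hicomm import polymer as poly


def part_of(labels, gamma=0.5):
    return comm.Partition(np.asarray(labels), gamma=gamma)


class TestSegments:
    def test_simple_runs(self):
        dec = ana.decompose_segments(part_of([0, 0, 1, 1, 1]))
        assert dec.segments == [(0, 1, 0), (2, 4, 1)]
        assert dec.non_contiguous_communities == []

    def test_alternating_pattern_is_non_contiguous(self):
        # A-B-C-A-B: communities A and B recur along the chain
        dec = ana.decompose_segments(part_of([0, 1, 2, 0, 1]))
        assert len(dec.segments) == 5
        assert dec.non_contiguous_communities == [0, 1]

    def test_mask_splits_runs(self):
        dec = ana.decompose_segments(part_of([0, 0, -1, 0, 0]))
        assert dec.segments == [(0, 1, 0), (3, 4, 0)]
        assert dec.n_segments_per_community[0] == 2

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=-1, max_value=3), min_size=1,
                    max_size=40))
    def test_round_trip_identity(self, labels):
        dec = ana.decompose_segments(part_of(labels))
        back = ana.segments_to_labels(dec, len(labels))
        assert list(back) == labels


class TestEndToEnd:
    def test_straight_chain_exact(self):
        chain = poly.Conformation(
            np.column_stack([np.arange(100), np.zeros(100), np.zeros(100)]))
        curve = ana.end_to_end_curve([chain], "all")
        np.testing.assert_allclose(curve.mean_R, curve.s)
        assert curve.fitted_exponent == pytest.approx(1.0, abs=1e-9)

    def test_segment_curve_uses_boundary_monomers(self):
        chain = poly.Conformation(
            np.column_stack([np.arange(10), np.zeros(10), np.zeros(10)]))
        part = part_of([0] * 5 + [1] * 5)
        curve = ana.end_to_end_curve([chain], "community_segments",
                                     partitions=[part])
        # two segments of 4 bonds each, straight: R = 4
        assert list(curve.s) == [4.0]
        assert curve.mean_R[0] == pytest.approx(4.0)
        assert curve.n_obs[0] == 2

    def test_requires_partitions(self):
        chain = poly.Conformation(np.zeros((5, 3)) + np.arange(5)[:, None])
        with pytest.raises(ValueError, match="partitions"):
            ana.end_to_end_curve([chain], "community_segments")


class TestShapeDescriptors:
    def test_rg_two_points(self):
        coords = np.array([[0.0, 0, 0], [3.0, 0, 0]])
        assert ana.radius_of_gyration(coords) == pytest.approx(1.5)

    def test_rg_coincident_points(self):
        assert ana.radius_of_gyration(np.ones((7, 3))) == 0.0

    def test_rg_matches_pair_sum_identity(self, rng):
        coords = rng.normal(size=(20, 3))
        n = 20
        pair = 0.0
        for i in range(n):
            for j in range(n):
                pair += np.sum((coords[i] - coords[j]) ** 2)
        expected = np.sqrt(pair / (2 * n * n))
        assert ana.radius_of_gyration(coords) == pytest.approx(expected)

    def test_normalize_by_rg(self):
        curve = ana.ScalingCurve(np.array([1.0, 2.0]), np.array([4.0, 8.0]),
                                 np.array([0.1, 0.2]), 1.0, (1, 2))
        out = ana.normalize_by_rg(curve, rg=2.0)
        np.testing.assert_allclose(out.mean_R, [1.0, 2.0])

    def test_asphericity_sphere_surface(self, rng):
        v = rng.normal(size=(5000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert ana.asphericity(v) < 0.02

    def test_asphericity_collinear(self):
        coords = np.column_stack([np.arange(10), np.zeros(10), np.zeros(10)])
        assert ana.asphericity(coords) == pytest.approx(1.0)

    def test_asphericity_bounds(self, rng):
        for _ in range(20):
            b = ana.asphericity(rng.normal(size=(30, 3)))
            assert 0.0 <= b <= 1.0


class TestBorders:
    def test_identical_sets_give_one(self):
        part = part_of([0] * 5 + [1] * 5 + [0] * 5)
        ref = ana.predicted_borders(part)
        fwd, rev = ana.border_overlap(part, ref, window=0)
        assert fwd == 1.0 and rev == 1.0

    def test_empty_reference_gives_zero(self):
        part = part_of([0] * 5 + [1] * 5)
        fwd, rev = ana.border_overlap(part, [], window=1)
        assert fwd == 0.0 and rev == 0.0

    def test_hand_enumerated_window_match(self):
        labels = np.zeros(60, dtype=int)
        labels[10:20] = 1
        labels[20:30] = 2
        labels[30:] = 3
        part = part_of(labels)
        assert list(ana.predicted_borders(part)) == [10, 20, 30]
        fwd, _ = ana.border_overlap(part, [11, 29, 50], window=1)
        assert fwd == pytest.approx(2.0 / 3.0)

    def test_chain_start_and_mask_edges_excluded(self):
        labels = np.array([0, 0, -1, 1, 1, 2, 2])
        part = part_of(labels)
        # bin 3 follows the mask, so only bin 5 is a border
        assert list(ana.predicted_borders(part)) == [5]

    def test_symmetric_at_window_zero(self):
        part = part_of([0] * 4 + [1] * 4 + [2] * 4)
        ref = [4, 8]
        fwd, rev = ana.border_overlap(part, ref, window=0)
        assert fwd == rev == 1.0


class TestCommunitySummaries:
    def test_tads_per_community_alternating(self):
        out = ana.tads_per_community(part_of([0, 1, 2, 0, 1]))
        assert out["n_communities"] == 3
        assert out["mean_segments_per_community"] == pytest.approx(5 / 3)

    def test_tads_per_community_single(self):
        out = ana.tads_per_community(part_of([0] * 10))
        assert out["n_communities"] == 1
        assert out["mean_segments_per_community"] == 1.0

    def test_tads_per_community_two_interleaved(self):
        labels = [0, 1] * 8
        out = ana.tads_per_community(part_of(labels))
        assert out["n_communities"] == 2
        assert out["mean_segments_per_community"] == 8.0

    def test_constant_track(self):
        part = part_of([0] * 60 + [1] * 60)
        table = ana.signal_by_community(part, np.full(120, 2.5), min_size=50)
        assert list(table["median"]) == [2.5, 2.5]

    def test_disjoint_ranges_ordered(self, rng):
        part = part_of([0] * 70 + [1] * 50)
        track = np.concatenate([rng.uniform(0, 1, 70),
                                rng.uniform(5, 6, 50)])
        table = ana.signal_by_community(part, track, min_size=10)
        by_comm = table.set_index("community")["median"]
        assert by_comm[0] < by_comm[1]

    def test_small_communities_omitted(self, rng):
        part = part_of([0] * 60 + [1] * 10)
        table = ana.signal_by_community(part, rng.normal(size=70),
                                        min_size=50)
        assert list(table["community"]) == [0]

    def test_mean_recovery(self, rng):
        means = {0: -2.0, 1: 3.0}
        labels = np.array([0] * 200 + [1] * 200)
        track = np.concatenate([
            rng.normal(means[0], 0.5, 200), rng.normal(means[1], 0.5, 200)])
        table = ana.signal_by_community(part_of(labels), track)
        by_comm = table.set_index("community")["median"]
        assert by_comm[0] == pytest.approx(means[0], abs=0.2)
        assert by_comm[1] == pytest.approx(means[1], abs=0.2)


class TestGenomicHelpers:
    def test_bed_to_bins(self, tmp_path):
        bed = tmp_path / "tads.bed"
        bed.write_text("chr1\t100000\t400000\nchr1\t400000\t900000\n")
        bins = ana.bed_to_bins(bed, bin_size=100000, use="start")
        assert list(bins) == [1, 4]
        mids = ana.bed_to_bins(bed, bin_size=100000, use="midpoint")
        assert list(mids) == [2, 6]

    def test_bedgraph_mean_per_bin(self, tmp_path):
        bg = tmp_path / "sig.bedGraph"
        bg.write_text("chr1\t0\t50\t2.0\nchr1\t50\t100\t4.0\n"
                      "chr1\t100\t200\t1.0\n")
        track = ana.bedgraph_to_track(bg, bin_size=100, n_bins=3)
        assert track[0] == pytest.approx(3.0)
        assert track[1] == pytest.approx(1.0)
        assert np.isnan(track[2])
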