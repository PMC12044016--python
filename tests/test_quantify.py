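import numpy as np
import pytest

from atquant.quantify import (PairingCriteria, average_region_burden, colocalize,
                              compute_burden, compute_density, pair_synapses,
                              percent_synapses_with_ab, quantify_roi)
from atquant.segmentation import Object3D, label_objects
from atquant.stack_io import VoxelGeometry

from conftest import make_seg
from oracles import greedy_pairing_oracle, optimal_pairing_oracle, overlap_fraction_oracle


def _point_object(obj_id, centroid, n_voxels=1, voxel_index=None):
    return Object3D(object_id=obj_id, channel="SYP", n_voxels=n_voxels,
                    volume_um3=n_voxels * 7e-4, centroid_um=tuple(centroid),
                    section_span=(0, 1), bbox=(0, 2, 0, 1, 0, 1),
                    voxel_index=np.asarray(voxel_index if voxel_index is not None else [0]))


class TestBurdenAndDensity:
    def test_burden_arithmetic(self):
        mask = np.zeros(70_000, bool)
        mask[:350] = True
        assert compute_burden(make_seg(mask.reshape(7, 100, 100))) == pytest.approx(0.5)

    def test_burden_bounds(self):
        assert compute_burden(make_seg(np.zeros((4, 5, 5), bool))) == 0.0
        assert compute_burden(make_seg(np.ones((4, 5, 5), bool))) == 100.0

    def test_zero_volume_field_rejected(self):
        with pytest.raises(ValueError):
            compute_burden(make_seg(np.zeros((0, 5, 5), bool)))

    def test_density_unit_conversion(self):
        objects = [_point_object(i, (0, 0, 0)) for i in range(7)]
        assert compute_density(objects, 3500.0) == pytest.approx(2.0e6)

    def test_zero_objects_zero_density(self):
        assert compute_density([], 3500.0) == 0.0

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError):
            compute_density([], 0.0)


class TestColocalize:
    @staticmethod
    def _object_with_overlap(n_total, n_overlap, shape=(4, 10, 10)):
        mask_a = np.zeros(shape, bool).reshape(-1)
        mask_a[:n_total] = True
        mask_b = np.zeros(shape, bool).reshape(-1)
        mask_b[:n_overlap] = True
        obj = _point_object(1, (0.5, 0.5, 0.1), n_voxels=n_total,
                            voxel_index=np.arange(n_total))
        return obj, make_seg(mask_b.reshape(shape))

    def test_25_percent_overlap_is_colocalized_inclusive(self):
        obj, seg_b = self._object_with_overlap(100, 25, (4, 10, 10))
        flags, pct = colocalize([obj], seg_b)
        assert flags[0] and pct == 100.0

    def test_24_percent_overlap_is_not_colocalized(self):
        obj, seg_b = self._object_with_overlap(100, 24, (4, 10, 10))
        flags, _ = colocalize([obj], seg_b)
        assert not flags[0]

    def test_own_channel_gives_full_colocalization(self, rng):
        mask = rng.random((4, 12, 12)) < 0.3
        seg = make_seg(mask)
        objects = label_objects(seg)
        if objects:
            _, pct = colocalize(objects, seg)
            assert pct == 100.0

    def test_field_mismatch_rejected(self):
        obj, _ = self._object_with_overlap(100, 25, (4, 10, 10))
        with pytest.raises(ValueError, match="mismatch"):
            colocalize([obj], make_seg(np.zeros((2, 5, 5), bool)))

    def test_asymmetric_by_construction(self):
        """A small object inside a big one: A->B full, B->A partial."""
        shape = (4, 10, 10)
        small = np.zeros(shape, bool)
        small[1, 4:6, 4:6] = True        # 4 voxels
        big = np.zeros(shape, bool)
        big[1:3, 3:8, 3:8] = True        # 50 voxels, contains the small one
        (a,) = label_objects(make_seg(small))
        (b,) = label_objects(make_seg(big))
        _, pct_ab = colocalize([a], make_seg(big))
        _, pct_ba = colocalize([b], make_seg(small))
        assert pct_ab == 100.0
        assert pct_ba == 0.0  # 4/50 = 8% < 25%

    def test_overlap_fraction_matches_voxelwise_oracle(self, rng):
        shape = (4, 12, 12)
        for _ in range(25):
            mask_a = rng.random(shape) < 0.25
            mask_b = rng.random(shape) < 0.25
            objects = label_objects(make_seg(mask_a))
            if not objects:
                continue
            flags, _ = colocalize(objects, make_seg(mask_b))
            for obj, flag in zip(objects, flags):
                vox = set(zip(*np.unravel_index(obj.voxel_index, shape)))
                frac = overlap_fraction_oracle(vox, mask_b)
                assert flag == (frac >= 0.25)


class TestPairing:
    def test_within_criterion_paired(self):
        pre = [_point_object(1, (1.0, 1.0, 0.5))]
        post = [_point_object(1, (1.4, 1.0, 0.5))]
        assert len(pair_synapses(pre, post)) == 1

    def test_exactly_half_micron_paired_inclusive(self):
        pre = [_point_object(1, (1.0, 1.0, 0.5))]
        post = [_point_object(1, (1.5, 1.0, 0.5))]
        pairs = pair_synapses(pre, post)
        assert len(pairs) == 1 and pairs[0][2] == pytest.approx(0.5)

    def test_just_over_half_micron_not_paired(self):
        pre = [_point_object(1, (1.0, 1.0, 0.5))]
        post = [_point_object(1, (1.51, 1.0, 0.5))]
        assert pair_synapses(pre, post) == []

    def test_closest_of_three_pres_wins_single_post(self):
        pre = [_point_object(i, (1.0 + 0.1 * i, 1.0, 0.5)) for i in (1, 2, 3)]
        post = [_point_object(7, (1.35, 1.0, 0.5))]
        pairs = pair_synapses(pre, post)
        assert len(pairs) == 1
        assert pairs[0][0] == 3  # pre at x=1.3 is nearest to 1.35

    def test_each_object_in_at_most_one_pair(self, rng):
        pre = [_point_object(i, rng.uniform(0, 2, 3)) for i in range(10)]
        post = [_point_object(i, rng.uniform(0, 2, 3)) for i in range(10)]
        pairs = pair_synapses(pre, post)
        assert len({p for p, _, _ in pairs}) == len(pairs)
        assert len({q for _, q, _ in pairs}) == len(pairs)

    def test_invariant_under_input_permutation(self, rng):
        pre = [_point_object(i, rng.uniform(0, 2, 3)) for i in range(8)]
        post = [_point_object(i, rng.uniform(0, 2, 3)) for i in range(8)]
        ref = set((p, q) for p, q, _ in pair_synapses(pre, post))
        for _ in range(5):
            pre_shuf = [pre[i] for i in rng.permutation(8)]
            post_shuf = [post[i] for i in rng.permutation(8)]
            got = set((p, q) for p, q, _ in pair_synapses(pre_shuf, post_shuf))
            assert got == ref

    def test_matches_greedy_oracle(self, rng):
        for _ in range(50):
            n, m = rng.integers(1, 9, 2)
            pre_pts = [(i + 1, tuple(rng.uniform(0, 1.5, 3))) for i in range(n)]
            post_pts = [(j + 1, tuple(rng.uniform(0, 1.5, 3))) for j in range(m)]
            pre = [_point_object(pid, c) for pid, c in pre_pts]
            post = [_point_object(pid, c) for pid, c in post_pts]
            got = set((p, q) for p, q, _ in pair_synapses(pre, post))
            assert got == greedy_pairing_oracle(pre_pts, post_pts, 0.5)

    def test_greedy_matches_optimal_at_biological_density(self, rng):
        """At realistic puncta spacing greedy pairing attains the exact
        maximum-cardinality minimum-distance matching."""
        agree = total = 0
        for _ in range(60):
            n, m = rng.integers(1, 7, 2)
            pre_pts = [(i + 1, tuple(rng.uniform(0, 2.5, 3))) for i in range(n)]
            post_pts = [(j + 1, tuple(rng.uniform(0, 2.5, 3))) for j in range(m)]
            pre = [_point_object(pid, c) for pid, c in pre_pts]
            post = [_point_object(pid, c) for pid, c in post_pts]
            pairs = pair_synapses(pre, post)
            card, weight = optimal_pairing_oracle(pre_pts, post_pts, 0.5)
            total += 1
            greedy_weight = sum(d for _, _, d in pairs)
            if len(pairs) == card and greedy_weight <= weight + 1e-12:
                agree += 1
        assert agree == total


class TestSynapseAbPercentage:
    def test_empty_ab_mask_gives_zero(self):
        objs = [_point_object(1, (0.5, 0.5, 0.1), n_voxels=4, voxel_index=np.arange(4))]
        assert percent_synapses_with_ab(objs, make_seg(np.zeros((4, 10, 10), bool))) == 0.0

    def test_fully_covered_gives_hundred(self):
        objs = [_point_object(1, (0.5, 0.5, 0.1), n_voxels=4, voxel_index=np.arange(4))]
        assert percent_synapses_with_ab(objs, make_seg(np.ones((4, 10, 10), bool))) == 100.0

    def test_empty_object_list_is_an_error_not_zero(self):
        with pytest.raises(ValueError, match="undefined"):
            percent_synapses_with_ab([], make_seg(np.zeros((4, 10, 10), bool)))


class TestRegionAveraging:
    def test_mean_of_four_regions(self):
        assert average_region_burden([1, 2, 3, 4]) == pytest.approx(2.5)

    def test_single_region_is_itself(self):
        assert average_region_burden([0.7]) == pytest.approx(0.7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_region_burden([])


class TestQuantifyRoi:
    def test_invariants_on_random_masks(self, rng):
        shape = (16, 24, 24)
        segs, objects = {}, {}
        for ch in ("SYP", "PSD95", "OC"):
            from atquant.segmentation import remove_single_section_objects
            seg = remove_single_section_objects(make_seg(rng.random(shape) < 0.1, channel=ch))
            segs[ch] = seg
            objects[ch] = label_objects(seg)
        res = quantify_roi(segs, objects, case_id="t")
        for ch in segs:
            assert 0.0 <= res.burden_pct[ch] <= 100.0
            assert res.density_per_mm3[ch] >= 0.0
        assert res.pair_count <= min(res.object_count["SYP"], res.object_count["PSD95"])
        for (a, b), pct in res.coloc_pct.items():
            if not np.isnan(pct):
                assert 0.0 <= pct <= 100.0

    def test_criteria_defaults_match_protocol(self):
        c = PairingCriteria()
        assert c.overlap_fraction_min == 0.25
        assert c.pairing_distance_max == 0.5
        assert c.fold_increase == 2.0
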