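"""Morphometry tests: binarization, thickness phantoms, overlays, metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from boneadapt import (
    DegenerateInputError,
    Volume3D,
    binarize,
    dice,
    dynamic_morphometry,
    local_thickness,
    overlay,
    static_morphometry,
    symmetric_distance,
)
from boneadapt import common_voi, phantom

from conftest import SPACING, sphere_binary


def _ones_mask(shape):
    return Volume3D(np.ones(shape, np.uint8), SPACING)


class TestBinarize:
    def test_uniform_above_threshold_all_bone(self):
        gray = Volume3D(np.full((10, 10, 10), 400.0), SPACING)
        out = binarize(gray, _ones_mask((10, 10, 10)))
        assert out.bone_voxels() == 1000

    def test_uniform_below_threshold_empty(self):
        gray = Volume3D(np.full((10, 10, 10), 100.0), SPACING)
        out = binarize(gray, _ones_mask((10, 10, 10)))
        assert out.bone_voxels() == 0

    def test_largest_component_survives(self):
        gray = np.zeros((20, 20, 20))
        gray[2:7, 2:7, 2:6] = 400.0    # 100-voxel blob
        gray[12:17, 12:16, 12] = 400.0  # 20-voxel blob
        out = binarize(Volume3D(gray, SPACING), _ones_mask((20, 20, 20)), sigma=0.2)
        assert out.data[3, 3, 3] == 1
        assert out.data[13, 13, 12] == 0

    def test_empty_mask_raises(self):
        gray = Volume3D(np.full((6, 6, 6), 400.0), SPACING)
        with pytest.raises(DegenerateInputError):
            binarize(gray, Volume3D(np.zeros((6, 6, 6), np.uint8), SPACING))


class TestCommonVOI:
    def test_intersection_and_union(self):
        m1 = np.zeros((6, 6, 6), np.uint8)
        m2 = np.zeros((6, 6, 6), np.uint8)
        m1[:4] = 1
        m2[2:] = 1
        inter = common_voi([Volume3D(m1, SPACING), Volume3D(m2, SPACING)])
        union = common_voi([Volume3D(m1, SPACING), Volume3D(m2, SPACING)], mode="union")
        assert inter.bone_voxels() == 2 * 36
        assert union.bone_voxels() == 6 * 36

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            common_voi([Volume3D(np.ones((4, 4, 4), np.uint8), SPACING),
                        Volume3D(np.ones((5, 5, 5), np.uint8), SPACING)])


class TestLocalThickness:
    def test_plate_thickness(self):
        plate = phantom("plate", (50, 30, 30), SPACING, thickness=10, offset=20)
        tau = local_thickness(plate, "bone")
        interior = np.zeros(plate.shape, bool)
        interior[22:28, 5:-5, 5:-5] = True
        assert np.allclose(tau[interior], 610.0, atol=SPACING)

    def test_ball_center_diameter(self):
        # odd grid so the ball center sits on a voxel
        R = 8
        ball = sphere_binary(25, R)
        tau = local_thickness(ball, "bone")
        c = (ball.shape[0] - 1) // 2
        assert tau[c, c, c] == pytest.approx(2 * R * SPACING, abs=SPACING)

    def test_rod_diameter(self):
        rod = phantom("rod", (30, 31, 31), SPACING, radius=6)
        tau = local_thickness(rod, "bone")
        axis = tau[5:-5, 15, 15]
        assert np.allclose(axis, 2 * 6 * SPACING, atol=SPACING)

    def test_empty_phase_raises(self):
        empty = Volume3D(np.zeros((8, 8, 8), np.uint8), SPACING)
        with pytest.raises(DegenerateInputError):
            local_thickness(empty, "bone")


class TestStaticMorphometry:
    def test_plate_phantom_oracle(self):
        plate = phantom("plate", (50, 30, 30), SPACING, thickness=10, offset=20)
        sm = static_morphometry(plate)
        assert sm.bvtv == pytest.approx(20.0)
        assert sm.tb_th == pytest.approx(0.61, abs=0.061)

    def test_all_bone_flags_separation(self):
        vol = Volume3D(np.ones((10, 10, 10), np.uint8), SPACING)
        sm = static_morphometry(vol)
        assert sm.bvtv == pytest.approx(100.0)
        assert "no_background" in sm.flags

    def test_empty_bone_flagged(self):
        vol = Volume3D(np.zeros((10, 10, 10), np.uint8), SPACING)
        sm = static_morphometry(vol)
        assert sm.bvtv == 0.0
        assert "empty_bone" in sm.flags
        assert np.isnan(sm.tb_th)

    def test_translation_invariance(self):
        sm = []
        for off in (15, 20):
            plate = phantom("plate", (50, 30, 30), SPACING, thickness=10, offset=off)
            sm.append(static_morphometry(plate))
        assert sm[0].bvtv == pytest.approx(sm[1].bvtv)
        assert sm[0].tb_th == pytest.approx(sm[1].tb_th, abs=1e-9)

    def test_inverse_sum_model(self, grf_small):
        sm = static_morphometry(grf_small, tbn_model="inverse-sum")
        assert sm.tb_n == pytest.approx(1.0 / (sm.tb_th + sm.tb_sp))


class TestOverlay:
    def test_identity_all_quiescent(self, grf_small):
        ov = overlay(grf_small, grf_small, 100.0)
        counts = ov.counts()
        assert counts["formed"] == 0
        assert counts["resorbed"] == 0
        assert counts["quiescent"] == grf_small.bone_voxels()

    def test_voxel_coding(self):
        b0 = np.zeros((4, 4, 4), np.uint8)
        b1 = np.zeros((4, 4, 4), np.uint8)
        b0[1, 1, 1] = 1  # baseline only -> resorbed
        b1[2, 2, 2] = 1  # follow-up only -> formed
        b0[3, 3, 3] = b1[3, 3, 3] = 1  # both -> quiescent
        ov = overlay(Volume3D(b0, SPACING), Volume3D(b1, SPACING), 10.0)
        assert ov.data[1, 1, 1] == 1
        assert ov.data[2, 2, 2] == 2
        assert ov.data[3, 3, 3] == 3
        assert ov.data[0, 0, 0] == 0

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            overlay(Volume3D(np.zeros((4, 4, 4)), SPACING),
                    Volume3D(np.zeros((5, 5, 5)), SPACING), 10.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_partition_conservation(self, seed):
        rng = np.random.default_rng(seed)
        b0 = Volume3D((rng.random((10, 10, 10)) > 0.5).astype(np.uint8), SPACING)
        b1 = Volume3D((rng.random((10, 10, 10)) > 0.5).astype(np.uint8), SPACING)
        ov = overlay(b0, b1, 50.0)
        c = ov.counts()
        assert c["resorbed"] + c["quiescent"] == b0.bone_voxels()
        assert c["formed"] + c["quiescent"] == b1.bone_voxels()


class TestDynamicMorphometry:
    def test_hand_counted_rates(self):
        # 100 baseline voxels; +10 formed, -5 resorbed over 100 days
        b0 = np.zeros((20, 20, 20), np.uint8)
        b0[5:9, 5:10, 5:10] = 1  # 4*5*5 = 100
        b1 = b0.copy()
        b1[9, 5:10, 5:7] = 1   # +10
        b1[5, 5:10, 5] = 0     # -5
        ov = overlay(Volume3D(b0, SPACING), Volume3D(b1, SPACING), 100.0)
        dm = dynamic_morphometry(ov)
        assert dm.bfr == pytest.approx(0.10)
        assert dm.brr == pytest.approx(0.05)
        # integer identity of the rate definition
        assert dm.bfr * 100.0 * 100 / 100.0 == pytest.approx(10.0)

    def test_identical_pair_zero_rates_flagged(self, grf_small):
        ov = overlay(grf_small, grf_small, 90.0)
        dm = dynamic_morphometry(ov)
        assert dm.bfr == 0 and dm.brr == 0
        assert dm.mar == 0 and dm.mrr == 0
        assert dm.ms == 0 and dm.es == 0
        assert {"no_formed", "no_resorbed"} <= dm.flags

    def test_mar_from_formed_slab_thickness(self):
        # 6-voxel-thick slab appended to a plate surface over 108 days:
        # MAR = slab local thickness / days
        b0 = np.zeros((30, 20, 20), np.uint8)
        b0[5:15] = 1
        b1 = b0.copy()
        b1[15:21] = 1
        ov = overlay(Volume3D(b0, SPACING), Volume3D(b1, SPACING), 108.0)
        dm = dynamic_morphometry(ov)
        assert dm.mar == pytest.approx(6 * SPACING / 108.0, rel=0.2)

    def test_zero_baseline_raises(self):
        b0 = Volume3D(np.zeros((6, 6, 6), np.uint8), SPACING)
        b1 = Volume3D(np.ones((6, 6, 6), np.uint8), SPACING)
        with pytest.raises(DegenerateInputError):
            dynamic_morphometry(overlay(b0, b1, 10.0))


class TestDice:
    def test_identity(self, grf_small):
        assert dice(grf_small, grf_small) == 1.0

    def test_disjoint(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[:4] = 1
        b[4:] = 1
        assert dice(Volume3D(a, SPACING), Volume3D(b, SPACING)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((8, 8, 8), np.uint8)
        b = np.zeros((8, 8, 8), np.uint8)
        a[0:4] = 1   # 256
        b[2:6] = 1   # 256, overlap 128
        assert dice(Volume3D(a, SPACING), Volume3D(b, SPACING)) == pytest.approx(0.5)

    def test_symmetry(self, grf_small):
        shifted = Volume3D(np.roll(grf_small.data, 2, axis=0), SPACING)
        assert dice(grf_small, shifted) == dice(shifted, grf_small)

    def test_both_empty_flagged_one(self):
        e = Volume3D(np.zeros((5, 5, 5), np.uint8), SPACING)
        with pytest.warns(UserWarning):
            assert dice(e, e) == 1.0


class TestSymmetricDistance:
    def test_identity_zero(self, grf_small):
        assert symmetric_distance(grf_small, grf_small) == 0.0

    def test_plate_offset_two_voxels(self):
        p0 = phantom("plate", (40, 20, 20), SPACING, thickness=8, offset=10)
        p1 = phantom("plate", (40, 20, 20), SPACING, thickness=8, offset=12)
        d = symmetric_distance(p0, p1)
        assert d == pytest.approx(2 * SPACING, abs=SPACING)

    def test_dilated_sphere_one_voxel(self):
        b0 = sphere_binary(32, 9)
        b1 = sphere_binary(32, 10)
        assert symmetric_distance(b0, b1) == pytest.approx(SPACING, abs=SPACING)

    def test_symmetry(self, grf_small):
        shifted = Volume3D(np.roll(grf_small.data, 1, axis=1), SPACING)
        assert symmetric_distance(grf_small, shifted) == pytest.approx(
            symmetric_distance(shifted, grf_small))

    def test_empty_phase_raises(self):
        e = Volume3D(np.zeros((6, 6, 6), np.uint8), SPACING)
        with pytest.raises(DegenerateInputError):
            symmetric_distance(e, sphere_binary(6, 2))
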