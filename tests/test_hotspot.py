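import numpy as np
import pytest

import oracles
from conftest import digitized_sphere
from petstab import (
    LesionMask,
    PetVolume,
    centroid,
    compute_hotspot_features,
    equivalent_sphere_radius_mm,
    find_suvmax,
    nhoc,
    nhop,
    suv_peak,
)
from petstab.hotspot import boundary_face_centers


class TestFindSuvmax:
    def test_single_spike(self):
        vals = np.ones((8, 8, 8))
        vals[3, 4, 5] = 20.0
        vol = PetVolume(vals)
        mask = LesionMask(np.ones((8, 8, 8), dtype=bool) & (vals >= 0))
        coord, value = find_suvmax(vol, mask)
        assert value == 20.0
        assert np.allclose(coord, (3.0, 4.0, 5.0))

    def test_constant_mask_tie_break(self):
        vol = PetVolume(np.full((4, 4, 4), 2.0))
        mask = LesionMask(np.ones((4, 4, 4), dtype=bool))
        coord, _ = find_suvmax(vol, mask)
        assert np.allclose(coord, (0.0, 0.0, 0.0))

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(10):
            vals = rng.random((6, 6, 6))
            flat = rng.choice(216, size=100, replace=False)
            ind = np.zeros(216, dtype=bool)
            ind[flat] = True
            mask = LesionMask(ind.reshape(6, 6, 6))
            vol = PetVolume(vals)
            coord, value = find_suvmax(vol, mask)
            idx, brute_val = oracles.brute_suvmax(vals, mask.indicator)
            assert value == brute_val
            assert np.allclose(coord, idx)

    def test_empty_mask_rejected(self):
        vol = PetVolume(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="empty"):
            find_suvmax(vol, LesionMask(np.zeros((4, 4, 4), dtype=bool)))


class TestSuvPeak:
    def test_constant_region_gives_constant(self):
        mask = digitized_sphere(5.0, spacing=(2.0, 2.0, 2.0))
        vol = PetVolume(np.full(mask.shape, 7.0), spacing=(2.0, 2.0, 2.0))
        result = suv_peak(vol, mask)
        assert result is not None
        assert result[1] == pytest.approx(7.0)

    def test_sub_milliliter_lesion_flagged_not_errored(self):
        ind = np.zeros((20, 20, 20), dtype=bool)
        ind[5:15, 5:15, 5:14] = True  # 900 voxels at 1 mm^3 = 0.9 mL
        vol = PetVolume(np.ones((20, 20, 20)))
        assert suv_peak(vol, LesionMask(ind)) is None

    def test_gaussian_hotspot_peak_below_max(self):
        g = np.arange(24) * 2.0
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        vals = 0.5 + 8.0 * np.exp(
            -((xx - 23) ** 2 + (yy - 23) ** 2 + (zz - 23) ** 2) / (2 * 5.0**2)
        )
        vol = PetVolume(vals, spacing=(2.0, 2.0, 2.0))
        mask = LesionMask(vals > 2.0, spacing=(2.0, 2.0, 2.0))
        _, speak = suv_peak(vol, mask)
        _, smax = find_suvmax(vol, mask)
        assert 0.5 < speak < smax

    def test_clipped_sphere_names_axis(self):
        vals = np.ones((12, 12, 4))
        vals[6, 6, 2] = 5.0
        vol = PetVolume(vals, spacing=(2.0, 2.0, 2.0))
        mask = LesionMask(np.ones((12, 12, 4), dtype=bool), spacing=(2.0, 2.0, 2.0))
        with pytest.raises(ValueError, match="'z'"):
            suv_peak(vol, mask)


class TestCentroid:
    def test_symmetric_sphere_centered(self):
        mask = digitized_sphere(8.0)
        center = (np.asarray(mask.shape) - 1) / 2.0
        assert np.all(np.abs(centroid(mask) - center) < 0.5)

    def test_two_voxel_mean(self):
        ind = np.zeros((3, 3, 11), dtype=bool)
        ind[1, 1, 0] = ind[1, 1, 10] = True
        assert centroid(LesionMask(ind))[2] == pytest.approx(5.0)

    def test_matches_brute_force(self, rng):
        ind = np.zeros(6 * 6 * 6, dtype=bool)
        ind[rng.choice(216, size=50, replace=False)] = True
        mask = LesionMask(ind.reshape(6, 6, 6), spacing=(2.73, 2.73, 2.79))
        assert np.allclose(
            centroid(mask), oracles.brute_centroid(mask.indicator, mask.spacing)
        )


class TestNhocNhop:
    def test_hotspot_at_centroid_gives_zero(self, sphere_mask_r12):
        assert nhoc(centroid(sphere_mask_r12), sphere_mask_r12) == pytest.approx(0.0)

    def test_sphere_surface_hotspot_near_one(self, sphere_mask_r12):
        hot = centroid(sphere_mask_r12) + np.array([12.0, 0.0, 0.0])
        assert nhoc(hot, sphere_mask_r12) == pytest.approx(1.0, abs=0.1)

    def test_sphere_center_nhop_near_one(self, sphere_mask_r12):
        assert nhop(centroid(sphere_mask_r12), sphere_mask_r12) == pytest.approx(
            1.0, abs=0.1
        )

    def test_hotspot_on_surface_gives_zero(self, rng):
        mask = digitized_sphere(6.0)
        faces = boundary_face_centers(mask)
        face = faces[rng.integers(len(faces))]
        assert nhop(face, mask) == pytest.approx(0.0, abs=1e-12)

    def test_hotspot_on_boundary_voxel_within_half_diagonal(self):
        mask = digitized_sphere(6.0)
        from petstab.hotspot import boundary_voxel_coordinates

        vox = boundary_voxel_coordinates(mask)[0]
        half_diag = np.linalg.norm(mask.spacing) / 2.0
        assert nhop(vox, mask) <= half_diag / equivalent_sphere_radius_mm(mask)

    def test_matches_exhaustive_surface_minimum(self, rng):
        for _ in range(5):
            ind = np.zeros(6 * 6 * 6, dtype=bool)
            ind[rng.choice(216, size=60, replace=False)] = True
            mask = LesionMask(ind.reshape(6, 6, 6), spacing=(2.0, 2.0, 2.0))
            point = rng.uniform(0, 10, size=3)
            expected = oracles.brute_surface_min_distance(
                point, mask.indicator, mask.spacing
            ) / equivalent_sphere_radius_mm(mask)
            assert nhop(point, mask) == pytest.approx(expected, abs=1e-12)

    def test_full_grid_mask_rejected(self):
        mask = LesionMask(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError, match="boundary"):
            nhop(np.zeros(3), mask)


class TestFeatureSetInvariants:
    def make_phantom(self, shift=(0, 0, 0)):
        g = np.arange(28) * 2.0
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        c = np.array([27.0, 27.0, 27.0]) + 2.0 * np.asarray(shift)
        vals = 0.5 + 8.0 * np.exp(
            -((xx - c[0] - 4) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2)
            / (2 * 6.0**2)
        )
        sphere = (xx - c[0]) ** 2 + (yy - c[1]) ** 2 + (zz - c[2]) ** 2 <= 14.0**2
        vol = PetVolume(np.where(sphere, vals, 0.4), spacing=(2.0, 2.0, 2.0))
        return vol, LesionMask(sphere, spacing=(2.0, 2.0, 2.0))

    def test_translation_invariance(self):
        base = compute_hotspot_features(*self.make_phantom())
        shifted = compute_hotspot_features(*self.make_phantom(shift=(1, -1, 1)))
        for attr in ("suv_max", "suv_peak", "mtv_ml", "nhoc_max", "nhop_max",
                     "nhoc_peak", "nhop_peak"):
            assert getattr(base, attr) == pytest.approx(getattr(shifted, attr),
                                                        abs=1e-12)

    def test_peak_never_exceeds_max(self):
        feats = compute_hotspot_features(*self.make_phantom())
        assert feats.suv_peak <= feats.suv_max

    def test_scale_invariance_of_normalized_distances(self):
        def sphere_with_offset_hotspot(radius, offset):
            mask = digitized_sphere(radius)
            hot = centroid(mask) + np.array([offset, 0.0, 0.0])
            return nhoc(hot, mask), nhop(hot, mask)

        nhoc_small, nhop_small = sphere_with_offset_hotspot(6.0, 3.0)
        nhoc_large, nhop_large = sphere_with_offset_hotspot(12.0, 6.0)
        assert nhoc_large == pytest.approx(nhoc_small, rel=0.05)
        assert nhop_large == pytest.approx(nhop_small, rel=0.05)

    def test_sphere_identity_for_interior_hotspots(self, rng, sphere_mask_r12):
        center = centroid(sphere_mask_r12)
        for _ in range(20):
            h = rng.uniform(-12, 12, 3)
            while np.linalg.norm(h) > 12:
                h = rng.uniform(-12, 12, 3)
            total = nhoc(center + h, sphere_mask_r12) + nhop(
                center + h, sphere_mask_r12
            )
            assert 0.93 <= total <= 1.07
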