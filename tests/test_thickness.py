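"""Geometry core: signed distances, gradients, boundary classification,
and thickness recovery on phantoms with analytically known shells."""

import numpy as np
import pytest

import carthick as ct
from carthick.thickness import (
    boundary_voxels,
    classify_boundary,
    compute_thickness,
    gradient,
    per_region_thickness,
    signed_distance,
    thickness_at_inner_points,
    BoundaryPointSet,
    SignedDistanceField,
)
from carthick.volume import DegenerateGeometryError, InputError, LabelMask

from conftest import brute_force_signed_distance


def _mask(voxels, spacing=(1.0, 1.0, 1.0), structure="femoral_cartilage"):
    return LabelMask(np.asarray(voxels, bool), structure, spacing)


class TestSignedDistance:
    @pytest.mark.parametrize(
        "shape,spacing,seed",
        [
            ((5, 5, 5), (1, 1, 1), 0),
            ((8, 6, 4), (0.5, 0.5, 3.0), 1),
            ((10, 10, 10), (1, 2, 3), 2),
            ((7, 9, 5), (0.7, 1.1, 2.3), 3),
        ],
    )
    def test_matches_brute_force_exactly(self, shape, spacing, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random(shape) < 0.4
        if not mask.any() or mask.all():
            mask.flat[0] = True
            mask.flat[-1] = False
        sdf = signed_distance(_mask(mask, spacing))
        oracle = brute_force_signed_distance(mask, spacing)
        np.testing.assert_allclose(sdf.values, oracle, rtol=1e-12, atol=1e-12)

    def test_single_voxel(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        sdf = signed_distance(_mask(mask)).values
        assert sdf[2, 2, 2] == -1.0  # nearest outside voxel is face-adjacent
        assert sdf[3, 2, 2] == pytest.approx(1.0)

    def test_half_space_is_linear_ramp(self):
        mask = np.zeros((10, 4, 4), bool)
        mask[:5] = True
        sdf = signed_distance(_mask(mask, (2.0, 1.0, 1.0))).values
        # distance to the nearest opposite-class voxel centre along axis 0
        expected = np.where(
            mask, -(5 - np.arange(10)[:, None, None]) * 2.0,
            (np.arange(10)[:, None, None] - 4) * 2.0,
        )
        np.testing.assert_allclose(sdf, np.broadcast_to(expected, sdf.shape))

    def test_sphere_center_depth(self):
        shape = (21, 21, 21)
        idx = np.indices(shape)
        r = np.sqrt(((idx - 10.0) ** 2).sum(axis=0))
        mask = r <= 8
        sdf = signed_distance(_mask(mask)).values
        assert sdf[10, 10, 10] == pytest.approx(-8.0, abs=1.0)

    def test_empty_and_full_masks_raise(self):
        with pytest.raises(DegenerateGeometryError):
            signed_distance(_mask(np.zeros((4, 4, 4), bool)))
        with pytest.raises(DegenerateGeometryError):
            signed_distance(_mask(np.ones((4, 4, 4), bool)))

    def test_boundary_voxel_magnitude_bounded(self):
        rng = np.random.default_rng(4)
        mask = rng.random((12, 12, 6)) < 0.5
        mask.flat[0], mask.flat[-1] = True, False
        spacing = (0.5, 0.5, 3.0)
        sdf = signed_distance(_mask(mask, spacing)).values
        bnd = boundary_voxels(mask)
        assert np.all(np.abs(sdf[bnd]) <= max(spacing) + 1e-12)


class TestGradient:
    def test_linear_ramp(self):
        x = np.arange(8)[:, None, None] * np.ones((1, 6, 5))
        f = SignedDistanceField(x * 0.5, "femur", (0.5, 1.0, 1.0))
        g = gradient(f).components
        np.testing.assert_allclose(g[0], 1.0)
        np.testing.assert_allclose(g[1], 0.0)
        np.testing.assert_allclose(g[2], 0.0)

    def test_constant_field(self):
        f = SignedDistanceField(np.full((5, 5, 5), 3.0), "femur", (1, 1, 1))
        np.testing.assert_allclose(gradient(f).components, 0.0)

    def test_spherical_field_is_radial(self):
        shape = (25, 25, 25)
        idx = np.indices(shape).astype(float)
        r = np.sqrt(((idx - 12.0) ** 2).sum(axis=0))
        f = SignedDistanceField(r, "femur", (1, 1, 1))
        g = gradient(f).components
        interior = (r > 4) & (r < 10)
        radial = (idx - 12.0) / np.where(r == 0, 1, r)
        cosang = np.einsum("a...,a...->...", g, radial) / np.maximum(
            np.linalg.norm(g, axis=0), 1e-12
        )
        assert cosang[interior].min() > 0.99

    def test_degenerate_axis_zeroed(self):
        f = SignedDistanceField(np.random.default_rng(0).random((6, 6, 1)),
                                "femur", (1, 1, 3))
        g = gradient(f).components
        np.testing.assert_array_equal(g[2], 0.0)


class TestClassifyBoundary:
    def test_1d_stack_bone_cartilage_background(self):
        # bone | cartilage | background along axis 0
        shape = (12, 1, 1)
        data = np.zeros(shape, bool)
        bone = data.copy()
        bone[:5] = True
        cart = data.copy()
        cart[5:8] = True
        bm = _mask(bone, structure="femur")
        cm = _mask(cart)
        pts = classify_boundary(signed_distance(bm), signed_distance(cm), cm,
                                smooth_sigma_vox=0.0)
        assert [tuple(p) for p in pts.inner_idx] == [(5, 0, 0)]
        assert [tuple(p) for p in pts.outer_idx] == [(7, 0, 0)]

    def test_annulus_rings_correctly_signed(self, annulus3):
        vol, _ = annulus3
        bm = vol.mask("femur")
        cm = vol.mask("femoral_cartilage")
        pts = classify_boundary(signed_distance(bm), signed_distance(cm), cm)
        sp = np.asarray(vol.spacing_mm)
        center = (np.asarray(vol.shape) - 1) * sp / 2
        r_in = np.linalg.norm(pts.inner_mm[:, :2] - center[:2], axis=1)
        r_out = np.linalg.norm(pts.outer_mm[:, :2] - center[:2], axis=1)
        mid = 15.0 + 3.0 / 2  # annulus inner radius 15, shell 3 mm
        frac_ok = ((r_in < mid).sum() + (r_out > mid).sum()) / (
            len(r_in) + len(r_out)
        )
        assert frac_ok >= 0.95

    def test_every_boundary_voxel_classified_once(self, annulus3):
        vol, _ = annulus3
        cm = vol.mask("femoral_cartilage")
        pts = classify_boundary(
            signed_distance(vol.mask("femur")), signed_distance(cm), cm
        )
        bnd = boundary_voxels(cm.voxels)
        inner = set(map(tuple, pts.inner_idx))
        outer = set(map(tuple, pts.outer_idx))
        assert not inner & outer
        assert inner | outer == set(map(tuple, np.argwhere(bnd)))

    def test_nested_nonadjacent_shell_classified_by_facing(self):
        # shell around the bone with a gap: the bone-facing ring is inner
        # even though it never touches the bone
        shape, sp = (120, 120, 4), (0.5, 0.5, 3.0)
        si, apg, _ = np.meshgrid(*[np.arange(n) * s for n, s in zip(shape, sp)],
                                 indexing="ij")
        c = ((shape[0] - 1) * sp[0] / 2, (shape[1] - 1) * sp[1] / 2)
        r = np.hypot(si - c[0], apg - c[1])
        bm = _mask(r <= 8, sp, "femur")
        cm = _mask((r > 11) & (r <= 13), sp)
        pts = classify_boundary(signed_distance(bm), signed_distance(cm), cm)
        r_in = np.hypot(pts.inner_mm[:, 0] - c[0], pts.inner_mm[:, 1] - c[1])
        r_out = np.hypot(pts.outer_mm[:, 0] - c[0], pts.outer_mm[:, 1] - c[1])
        assert np.mean(r_in < 12.0) > 0.95
        assert np.mean(r_out > 12.0) > 0.95

    def test_no_boundary_raises(self):
        bone = np.zeros((4, 4, 4), bool)
        bone[0, 0, 0] = True
        # a grid-filling cartilage mask has no 6-conn boundary voxels
        cm = _mask(np.ones((4, 4, 4), bool))
        cart_sdf = SignedDistanceField(np.full((4, 4, 4), -1.0),
                                       "femoral_cartilage", (1, 1, 1))
        with pytest.raises(DegenerateGeometryError):
            classify_boundary(signed_distance(_mask(bone, structure="femur")),
                              cart_sdf, cm)


class TestThickness:
    @pytest.mark.parametrize("true_t", [1.5, 2.0, 3.0, 4.0])
    def test_annulus_recovery_within_one_voxel(self, true_t):
        vol, _ = ct.annulus_phantom(true_t)
        pts = compute_thickness(vol, "femur")
        assert abs(pts.thickness_mm.mean() - true_t) <= 0.5

    def test_matches_brute_force_nearest_outer(self, annulus3):
        vol, _ = annulus3
        cm = vol.mask("femoral_cartilage")
        pts = classify_boundary(
            signed_distance(vol.mask("femur")), signed_distance(cm), cm
        )
        filled = thickness_at_inner_points(pts, cm, surface_correction=False)
        sub = np.random.default_rng(0).choice(len(filled.inner_idx), 50,
                                              replace=False)
        inner = filled.inner_mm[sub]
        outer = filled.outer_mm
        oracle = np.sqrt(
            ((inner[:, None, :] - outer[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        np.testing.assert_allclose(filled.thickness_mm[sub], oracle, rtol=1e-9)

    def test_one_voxel_shell_bounded_by_diagonal(self):
        vol, _ = ct.annulus_phantom(1.0, spacing_mm=(1, 1, 1),
                                    grid_shape=(80, 80, 8))
        pts = compute_thickness(vol, "femur", smooth_sigma_vox=1.0)
        # inner and outer coincide in a one-voxel shell only after ties;
        # the centre-to-centre reading can never exceed the voxel diagonal
        raw = thickness_at_inner_points(
            BoundaryPointSet(pts.inner_idx, pts.outer_idx, vol.spacing_mm,
                             "femoral_cartilage"),
            vol.mask("femoral_cartilage"), surface_correction=False,
        )
        assert np.all(raw.thickness_mm <= np.sqrt(3) + 1e-9)

    def test_doubling_shell_doubles_recovery(self):
        m1 = compute_thickness(ct.annulus_phantom(1.5)[0], "femur").thickness_mm.mean()
        m2 = compute_thickness(ct.annulus_phantom(3.0)[0], "femur").thickness_mm.mean()
        assert abs(m2 - 2 * m1) <= 0.5

    def test_thickness_nonnegative(self, knee_volume):
        for bone in ("femur", "tibia", "patella"):
            pts = compute_thickness(knee_volume, bone)
            assert np.all(pts.thickness_mm >= 0)

    def test_invariant_to_bone_relabeling(self, annulus3):
        vol, _ = annulus3
        ref = compute_thickness(vol, "femur").thickness_mm.mean()
        swapped_codes = dict(vol.codes)
        swapped_codes["femur"], swapped_codes["tibia"] = (
            swapped_codes["tibia"], swapped_codes["femur"],
        )
        swapped_codes["femoral_cartilage"], swapped_codes["tibial_cartilage"] = (
            swapped_codes["tibial_cartilage"], swapped_codes["femoral_cartilage"],
        )
        vol2 = ct.LabelVolume(vol.data, vol.spacing_mm, swapped_codes)
        alt = compute_thickness(vol2, "tibia").thickness_mm.mean()
        assert alt == pytest.approx(ref, abs=1e-12)

    def test_invariant_to_inplane_rotation(self, annulus3):
        vol, _ = annulus3
        ref = compute_thickness(vol, "femur").thickness_mm.mean()
        rot = ct.LabelVolume(np.rot90(vol.data, axes=(0, 1)).copy(),
                             vol.spacing_mm, vol.codes)
        alt = compute_thickness(rot, "femur").thickness_mm.mean()
        assert alt == pytest.approx(ref, abs=0.5)

    def test_2d_slice_mode_close_to_3d_on_cylinder(self, annulus3):
        vol, _ = annulus3
        m3 = compute_thickness(vol, "femur", mode="3d").thickness_mm.mean()
        m2 = compute_thickness(vol, "femur", mode="2d-slice").thickness_mm.mean()
        assert abs(m2 - m3) <= 0.5

    def test_empty_outer_set_raises(self):
        pts = BoundaryPointSet(np.array([[1, 1, 1]]), np.empty((0, 3), int),
                               (1, 1, 1), "femoral_cartilage")
        with pytest.raises(DegenerateGeometryError):
            thickness_at_inner_points(pts, _mask(np.ones((3, 3, 3), bool)))


class TestPerRegionThickness:
    def _points(self, thicknesses):
        n = len(thicknesses)
        return BoundaryPointSet(
            np.zeros((n, 3), int), np.zeros((1, 3), int), (1, 1, 1),
            "femoral_cartilage", thickness_mm=np.asarray(thicknesses, float),
        )

    def test_single_region_others_missing(self):
        pts = self._points([2.0, 2.0, 2.0])
        out = per_region_thickness(pts, ["FMA"] * 3, ["FMA", "FMC"])
        assert out["FMA"] == 2.0 and np.isnan(out["FMC"])

    def test_two_region_means(self):
        pts = self._points([1.0, 3.0, 2.0])
        out = per_region_thickness(pts, ["FMA", "FMA", "FMC"], ["FMA", "FMC"])
        assert out == {"FMA": 2.0, "FMC": 2.0}

    def test_all_unassigned_raises(self):
        with pytest.raises(InputError):
            per_region_thickness(self._points([1.0]), [""], ["FMA"])

    def test_sector_profile_recovered(self):
        # piecewise shell: 2.0 mm anterior of AP=40 mm, 1.5 mm beyond
        from carthick.synthetic import (BoneGeometry, PhantomSpec,
                                        ap_step_profile, make_phantom)
        spec = PhantomSpec(
            grid_shape=(160, 160, 8),
            bones={"femur": BoneGeometry("cylinder", (40.0, 40.0, 10.5), 15.0)},
            profiles={"femur": ap_step_profile([40.0], [2.0, 1.5])},
        )
        vol, truth = make_phantom(spec)
        pts = compute_thickness(vol, "femur")
        ap = pts.inner_mm[:, 1]
        anterior = ap < 40.0 - 2.0  # exclude the step neighbourhood
        posterior = ap > 40.0 + 2.0
        assert abs(pts.thickness_mm[anterior].mean() - 2.0) <= 0.5
        assert abs(pts.thickness_mm[posterior].mean() - 1.5) <= 0.5
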