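"""Demons forces, regularisation, intensity remapping and registration."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from doseacc.core_image import Volume, VectorField, warp_volume
from doseacc.registration_demons import (
    DemonsConfig,
    demons_force,
    demons_register,
    gaussian_regularize,
    mi_intensity_remap,
)


def step_volume():
    """1-D step profile 0,0,...,1,1,... replicated in y and z."""
    arr = np.zeros((12, 4, 4))
    arr[6:] = 1.0
    return Volume(arr, unit="unitless")


class TestDemonsForce:
    def test_zero_where_images_match(self, rng):
        vol = Volume(rng.normal(size=(6, 6, 6)))
        upd = demons_force(vol, vol)
        np.testing.assert_allclose(upd.displacements, 0.0, atol=1e-12)

    def test_zero_in_flat_region_despite_difference(self):
        f = Volume(np.zeros((6, 6, 6)))
        m = Volume(np.full((6, 6, 6), 5.0))
        upd = demons_force(f, m)
        np.testing.assert_allclose(upd.displacements, 0.0, atol=1e-12)

    def test_shifted_step_pulls_toward_edge_with_hand_values(self):
        fixed = step_volume()
        moving = Volume(np.roll(fixed.voxels, 1, axis=0), unit="unitless")
        upd = demons_force(fixed, moving).displacements
        # hand evaluation at the voxel just before the fixed edge (i = 5):
        # f=0, m(warped)=0 -> no force; at i = 6: f=1, m=0, grad_f = 0.5 ->
        # u = (1-0)*0.5 / (0.25 + 1) = 0.4 voxels along +x
        assert upd[6, 2, 2, 0] == pytest.approx(0.4)
        assert np.all(np.abs(upd[..., 0]) <= 1.0 + 1e-12)
        assert np.all(upd[..., 0] >= -1e-12)  # points toward the fixed edge

    def test_magnitude_capped(self):
        f = Volume(np.linspace(0, 100, 12 * 4 * 4).reshape(12, 4, 4))
        m = Volume(f.voxels + 1e-3)
        upd = demons_force(f, m, cap=0.05)
        assert np.linalg.norm(upd.displacements / np.asarray(f.spacing), axis=-1).max() <= 0.05 + 1e-12


class TestGaussianRegularize:
    def test_constant_field_unchanged(self):
        fld = VectorField(np.tile([1.0, -2.0, 0.5], (8, 8, 8, 1)))
        out = gaussian_regularize(fld, 2.0)
        np.testing.assert_allclose(out.displacements, fld.displacements, atol=1e-9)

    def test_impulse_matches_separable_kernel_oracle(self):
        disp = np.zeros((15, 15, 15, 3))
        disp[7, 7, 7, 0] = 1.0
        out = gaussian_regularize(VectorField(disp), 1.2).displacements[..., 0]
        oracle = gaussian_filter(disp[..., 0], 1.2, mode="nearest")
        np.testing.assert_allclose(out, oracle, atol=1e-12)

    def test_tiny_sigma_approaches_identity(self, rng):
        disp = rng.normal(size=(8, 8, 8, 3))
        out = gaussian_regularize(VectorField(disp), 0.1)
        np.testing.assert_allclose(out.displacements, disp, atol=1e-3)

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            gaussian_regularize(VectorField(np.zeros((4, 4, 4, 3))), 0.0)


class TestIntensityRemap:
    def test_identity_when_images_match(self, rng):
        base = gaussian_filter(rng.uniform(0, 100, (32, 32, 32)), 2.0)
        a = Volume(base)
        rem, lut, edges = mi_intensity_remap(a, a, bins=64)
        # populated bins map close to themselves (within a bin width)
        width = edges[1] - edges[0]
        assert np.abs(rem.voxels - a.voxels).max() <= 2 * width

    def test_linear_relation_recovered(self, rng):
        base = gaussian_filter(rng.uniform(0, 100, (32, 32, 32)), 4.0)
        fixed = Volume(base)
        moving = Volume(2.0 * base + 10.0)
        rem, _, edges = mi_intensity_remap(
            fixed, moving, bins=64, identity_gate_frac=None, flat_gradient_frac=None
        )
        width = edges[1] - edges[0]
        assert np.abs(rem.voxels - fixed.voxels).max() <= 2 * width

    def test_one_sided_enhancement_reduces_mse(self, nc_spec, ct_study, nc_study):
        # planning-only contrast in the glands: after remapping the weekly
        # image onto the planning intensity scale, the in-gland mismatch
        # must shrink
        fixed = ct_study.planning_image
        moving = ct_study.weekly_images[0]
        fsm = fixed.with_voxels(gaussian_filter(fixed.voxels, 0.5, mode="nearest"))
        msm = moving.with_voxels(gaussian_filter(moving.voxels, 0.5, mode="nearest"))
        rem, _, _ = mi_intensity_remap(fsm, msm)
        par = np.isin(ct_study.planning_labels.voxels, (2, 3))
        before = np.mean((fsm.voxels[par] - msm.voxels[par]) ** 2)
        after = np.mean((fsm.voxels[par] - rem.voxels[par]) ** 2)
        assert after < before

    def test_geometry_mismatch_rejected(self, rng):
        a = Volume(rng.normal(size=(4, 4, 4)))
        b = Volume(rng.normal(size=(5, 4, 4)))
        with pytest.raises(ValueError):
            mi_intensity_remap(a, b)


class TestDemonsRegister:
    def test_identical_images_give_zero_field(self, nc_study):
        img = nc_study.planning_image
        res = demons_register(img, img, DemonsConfig(iterations=(30, 20, 10)))
        vox = np.asarray(img.spacing).mean()
        assert res.field.magnitude().mean() / vox < 0.1

    def test_recovers_smooth_bump_deformation(self, rng):
        # in-model check on a miniature anatomy: two contrasted blobs on a
        # textured background (coarse structure for the pyramid, texture
        # for the fine level), deformed by a smooth Gaussian-bump field
        base = gaussian_filter(rng.normal(0, 300, (40, 40, 40)), 2.0)  # ~19 SD texture
        img = Volume(base, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), unit="unitless")
        pts = img.grid_points()
        for center, amp in (((40.0, 40.0, 40.0), 80.0), ((24.0, 52.0, 40.0), -60.0)):
            r = np.linalg.norm(pts - np.asarray(center), axis=-1)
            img.voxels[r < 14.0] += amp
        w = np.exp(-np.sum((pts - 40.0) ** 2, axis=-1) / (2 * 20.0**2))
        gt = VectorField(np.stack([5 * w, 3 * w, 0 * w], -1), (2.0, 2.0, 2.0))
        fixed = warp_volume(img, gt)
        res = demons_register(fixed, img, DemonsConfig(iterations=(100, 80, 60)))
        err = np.linalg.norm(res.field.displacements - gt.displacements, axis=-1)
        pre = gt.magnitude()
        inner = np.s_[4:-4, 4:-4, 4:-4]
        assert err[inner].mean() < 0.5 * pre[inner].mean()

    def test_metric_non_increasing_across_levels(self, nc_study):
        res = demons_register(
            nc_study.planning_image,
            nc_study.weekly_images[0],
            DemonsConfig(iterations=(40, 30, 20)),
        )
        # each level's best metric is measured on its own resolution, so
        # compare the final level sequence monotonically per level history
        assert res.level_metrics[-1] <= res.level_metrics[0]

    def test_non_finite_input_rejected(self):
        bad = Volume(np.zeros((8, 8, 8)))
        bad.voxels[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            demons_register(bad, Volume(np.zeros((8, 8, 8))))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DemonsConfig(sigma=0.0)
        with pytest.raises(ValueError):
            DemonsConfig(force="nope")
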