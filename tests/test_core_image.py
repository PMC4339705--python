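"""Volume model, trilinear sampling, warping and file round-trips."""

import numpy as np
import pytest

from doseacc.core_image import (
    Volume,
    VectorField,
    read_volume,
    sample_volume,
    trilinear_sample,
    warp_labels,
    warp_volume,
    write_volume,
)


def affine_volume(shape=(12, 10, 8), spacing=(1.5, 2.0, 1.0), origin=(3.0, -2.0, 5.0)):
    """v(x, y, z) = 2x + 3y - z evaluated at voxel centres."""
    vol = Volume(np.zeros(shape), spacing, origin, unit="unitless")
    p = vol.grid_points()
    return vol.with_voxels(2 * p[..., 0] + 3 * p[..., 1] - p[..., 2])


def brute_force_trilinear(vol, point):
    """Direct 8-corner weighted sum, independent of scipy."""
    idx = vol.world_to_index(np.asarray(point))
    base = np.floor(idx).astype(int)
    t = idx - base
    total = 0.0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (t[0] if dx else 1 - t[0])
                    * (t[1] if dy else 1 - t[1])
                    * (t[2] if dz else 1 - t[2])
                )
                total += w * vol.voxels[base[0] + dx, base[1] + dy, base[2] + dz]
    return total


class TestTrilinearSample:
    def test_voxel_center_returns_voxel_value(self, rng):
        vol = Volume(rng.normal(size=(6, 5, 4)), (2.0, 2.0, 2.0), (1.0, 1.0, 1.0))
        assert trilinear_sample(vol, vol.index_to_world((3, 2, 1))) == pytest.approx(
            vol.voxels[3, 2, 1]
        )

    def test_cube_center_is_corner_mean(self):
        vox = np.zeros((2, 2, 2))
        vox[1, 1, 1] = 8.0
        vol = Volume(vox, (1.0, 1.0, 1.0), (0.0, 0.0, 0.0), unit="unitless")
        assert trilinear_sample(vol, (0.5, 0.5, 0.5)) == pytest.approx(1.0)

    def test_exact_on_affine_field(self, rng):
        vol = affine_volume()
        lo = np.asarray(vol.origin) + 0.6
        hi = np.asarray(vol.origin) + (np.asarray(vol.shape) - 1.6) * np.asarray(vol.spacing)
        pts = rng.uniform(lo, hi, size=(50, 3))
        expected = 2 * pts[:, 0] + 3 * pts[:, 1] - pts[:, 2]
        np.testing.assert_allclose(sample_volume(vol, pts), expected, atol=1e-9)

    def test_agrees_with_corner_sum_oracle(self, rng):
        vol = Volume(rng.normal(size=(9, 8, 7)), (1.3, 0.9, 2.1), (-4.0, 2.0, 0.0))
        lo = np.asarray(vol.origin)
        hi = lo + (np.asarray(vol.shape) - 1.001) * np.asarray(vol.spacing)
        pts = rng.uniform(lo, hi, size=(1000, 3))
        got = sample_volume(vol, pts)
        expected = np.array([brute_force_trilinear(vol, p) for p in pts])
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-12)

    def test_outside_returns_unit_fill(self):
        vol = Volume(np.ones((3, 3, 3)) * 50.0, unit="HU")
        assert trilinear_sample(vol, (100.0, 0.0, 0.0)) == -1024.0
        gy = Volume(np.ones((3, 3, 3)), unit="Gy")
        assert trilinear_sample(gy, (100.0, 0.0, 0.0)) == 0.0

    def test_non_finite_point_rejected(self):
        vol = Volume(np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            trilinear_sample(vol, (np.nan, 0.0, 0.0))


class TestWarpVolume:
    def test_zero_field_is_identity(self, rng):
        vol = Volume(rng.normal(size=(7, 6, 5)), (2.0, 2.0, 2.0))
        out = warp_volume(vol, VectorField.zeros_like(vol))
        np.testing.assert_array_equal(out.voxels, vol.voxels)
        assert out.unit == vol.unit

    def test_constant_field_shifts_affine_exactly(self):
        vol = affine_volume(shape=(16, 14, 12))
        disp = np.tile(np.array([5.0, 0.0, 0.0]), vol.shape + (1,))
        fld = VectorField(disp, spacing=vol.spacing, origin=vol.origin)
        out = warp_volume(vol, fld)
        p = vol.grid_points()
        expected = 2 * (p[..., 0] + 5.0) + 3 * p[..., 1] - p[..., 2]
        interior = np.s_[:-5, :, :]  # shifted points beyond the grid hit the fill
        np.testing.assert_allclose(out.voxels[interior], expected[interior], atol=1e-9)

    def test_constant_volume_stays_constant(self, rng):
        vol = Volume(np.full((10, 10, 10), 7.0), unit="Gy")
        disp = rng.uniform(-1.5, 1.5, size=(10, 10, 10, 3))
        mask = np.zeros((10, 10, 10, 1))
        mask[2:-2, 2:-2, 2:-2] = 1.0  # keep sampling strictly in bounds
        out = warp_volume(vol, VectorField(disp * mask, spacing=vol.spacing, origin=vol.origin))
        np.testing.assert_allclose(out.voxels, 7.0, atol=1e-12)

    def test_output_within_input_range_or_fill(self, rng):
        vol = Volume(rng.uniform(10, 20, size=(8, 8, 8)), unit="HU")
        disp = rng.uniform(-6, 6, size=(8, 8, 8, 3))
        out = warp_volume(vol, VectorField(disp, spacing=vol.spacing, origin=vol.origin))
        lo = min(vol.voxels.min(), vol.fill_value)  # border samples blend with fill
        assert out.voxels.min() >= lo - 1e-9
        assert out.voxels.max() <= vol.voxels.max() + 1e-9


class TestLabels:
    def test_one_hot_warp_keeps_codes_and_priority(self):
        lab = np.zeros((8, 8, 8))
        lab[2:5, 2:5, 2:5] = 2
        lab[4:7, 4:7, 4:7] = 5
        vol = Volume(lab, unit="label")
        out = warp_labels(vol, VectorField.zeros_like(vol))
        np.testing.assert_array_equal(out.voxels, lab)

    def test_requires_label_unit(self):
        vol = Volume(np.zeros((4, 4, 4)), unit="HU")
        with pytest.raises(ValueError):
            warp_labels(vol, VectorField.zeros_like(vol))


class TestVolumeValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"spacing": (0.0, 1.0, 1.0)},
            {"spacing": (-1.0, 1.0, 1.0)},
            {"unit": "furlong"},
        ],
    )
    def test_invalid_construction(self, kwargs):
        with pytest.raises(ValueError):
            Volume(np.zeros((4, 4, 4)), **kwargs)

    def test_too_small_axis(self):
        with pytest.raises(ValueError):
            Volume(np.zeros((1, 4, 4)))

    def test_field_must_be_finite(self):
        disp = np.zeros((4, 4, 4, 3))
        disp[0, 0, 0, 0] = np.inf
        with pytest.raises(ValueError):
            VectorField(disp)


class TestIO:
    @pytest.mark.parametrize("ext", [".mha", ".nii.gz"])
    def test_round_trip_bit_exact(self, tmp_path, rng, ext):
        vol = Volume(rng.normal(size=(16, 16, 16)), (1.0, 1.0, 1.0), (0.0, 0.0, 0.0))
        path = str(tmp_path / f"vol{ext}")
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.voxels, vol.voxels)

    def test_anisotropic_spacing_survives(self, tmp_path, rng):
        # typical planning-CT resolution: 1.10 x 1.10 mm in-plane, 2.4 mm slices
        vol = Volume(rng.normal(size=(8, 8, 8)), (1.10, 1.10, 2.4), (-10.0, 4.0, 0.0))
        path = str(tmp_path / "aniso.mha")
        write_volume(vol, path)
        back = read_volume(path)
        np.testing.assert_allclose(back.spacing, vol.spacing, atol=1e-6)
        np.testing.assert_allclose(back.origin, vol.origin, atol=1e-6)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_volume(str(tmp_path / "nope.mha"))

    def test_unknown_extension_rejected(self, tmp_path):
        vol = Volume(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            write_volume(vol, str(tmp_path / "vol.npy"))
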