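"""Volumes, dense displacement fields, sampling and warping.

The whole package works on regular 3-D scalar grids in *world millimetre*
coordinates.  Conventions (fixed once, used everywhere):

* arrays are indexed ``[i, j, k]`` along the (x, y, z) axes;
* world position of voxel ``(i, j, k)`` is ``origin + index * spacing``
  (0-based indices, spacing strictly positive, no rotation matrix);
* a :class:`VectorField` lives on a *reference* (planning) grid and maps a
  planning-space point ``p`` to the corresponding weekly-space point
  ``p + u(p)``.

Sampling is trilinear throughout; label images are warped through per-code
one-hot masks with a 0.5 threshold so that overlap scores stay stable under
sub-voxel displacements.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume",
    "VectorField",
    "FILL_VALUES",
    "trilinear_sample",
    "sample_volume",
    "warp_volume",
    "warp_labels",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
]

#: Out-of-grid fill value per unit tag: air for CT, zero dose, background label.
FILL_VALUES = {"HU": -1024.0, "Gy": 0.0, "label": 0.0, "unitless": 0.0}


@dataclass
class Volume:
    """A 3-D scalar grid with physical geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar samples, axis order (x, y, z).
    spacing : tuple of float
        Per-axis voxel size in mm, strictly positive.
    origin : tuple of float
        World position (mm) of voxel (0, 0, 0).
    unit : {"HU", "Gy", "label", "unitless"}
        Physical meaning of the samples; decides the out-of-bounds fill.
    """

    voxels: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)
    unit: str = "HU"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.voxels.ndim}")
        if any(n < 2 for n in self.voxels.shape):
            raise ValueError(f"each axis needs >= 2 voxels, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be length-3")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.unit not in FILL_VALUES:
            raise ValueError(f"unknown unit tag {self.unit!r}")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self):
        return self.voxels.shape

    @property
    def fill_value(self) -> float:
        return FILL_VALUES[self.unit]

    def same_geometry(self, other: "Volume | VectorField", tol: float = 1e-6) -> bool:
        return (
            self.shape[:3] == tuple(other.shape[:3])
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert world-mm points (..., 3) to fractional voxel indices."""
        points = np.asarray(points, dtype=np.float64)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices, dtype=np.float64)
        return np.asarray(self.origin) + indices * np.asarray(self.spacing)

    def grid_points(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (nx, ny, nz, 3)."""
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def with_voxels(self, voxels: np.ndarray, unit: str | None = None) -> "Volume":
        return replace(self, voxels=voxels, unit=unit or self.unit)


@dataclass
class VectorField:
    """Dense per-voxel displacement (mm) on a reference grid.

    A point ``p`` in reference (planning) space corresponds to ``p + u(p)``
    in target (weekly) space.
    """

    displacements: np.ndarray  # (nx, ny, nz, 3) mm
    spacing: tuple = (1.0, 1.0, 1.0)
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.ndim != 4 or self.displacements.shape[-1] != 3:
            raise ValueError("displacements must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @classmethod
    def zeros_like(cls, geom: "Volume | VectorField") -> "VectorField":
        return cls(
            np.zeros(tuple(geom.shape[:3]) + (3,)),
            spacing=geom.spacing,
            origin=geom.origin,
        )

    @property
    def shape(self):
        return self.displacements.shape

    def world_to_index(self, points):
        points = np.asarray(points, dtype=np.float64)
        return (points - np.asarray(self.origin)) / np.asarray(self.spacing)

    def grid_points(self) -> np.ndarray:
        axes = [
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        ]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinearly sample the displacement at world points (..., 3).

        Outside the grid the edge displacement is extended (mode="nearest"),
        so landmark propagation degrades gracefully at the border.
        """
        points = np.asarray(points, dtype=np.float64)
        idx = self.world_to_index(points)
        flat = idx.reshape(-1, 3).T
        out = np.empty((flat.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.displacements[..., c], flat, order=1, mode="nearest"
            )
        return out.reshape(points.shape)

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.displacements, axis=-1)

    def jacobian_determinant(self) -> np.ndarray:
        """Finite-difference Jacobian determinant of p -> p + u(p)."""
        jac = np.zeros(tuple(self.shape[:3]) + (3, 3))
        for c in range(3):
            grads = np.gradient(self.displacements[..., c], *self.spacing)
            for a in range(3):
                jac[..., c, a] = grads[a]
            jac[..., c, c] += 1.0
        return np.linalg.det(jac)


# -- sampling and warping --------------------------------------------------

def sample_volume(vol: Volume, points: np.ndarray, fill: float | None = None) -> np.ndarray:
    """Trilinear samples of ``vol`` at world points of shape (..., 3)."""
    points = np.asarray(points, dtype=np.float64)
    if not np.all(np.isfinite(points)):
        raise ValueError("sample points must be finite")
    fill = vol.fill_value if fill is None else float(fill)
    idx = vol.world_to_index(points)
    flat = idx.reshape(-1, 3).T
    vals = map_coordinates(vol.voxels, flat, order=1, mode="constant", cval=fill)
    return vals.reshape(points.shape[:-1])


def trilinear_sample(vol: Volume, point) -> float:
    """Trilinear blend of the 8 voxels surrounding a single world point."""
    return float(sample_volume(vol, np.asarray(point, dtype=np.float64)))


def warp_volume(vol: Volume, field: VectorField, fill: float | None = None) -> Volume:
    """Pull ``vol`` back onto the field's reference grid.

    ``output(p) = vol(p + u(p))`` for every voxel centre ``p`` of the field
    grid; the output inherits the field geometry and the input unit tag.
    """
    targets = field.grid_points() + field.displacements
    out = sample_volume(vol, targets, fill=fill)
    return Volume(out, spacing=field.spacing, origin=field.origin, unit=vol.unit)


def warp_labels(labels: Volume, field: VectorField) -> Volume:
    """Warp an integer label image through one-hot trilinear masks.

    Each nonzero code is warped as a soft indicator and re-thresholded at
    0.5; higher codes overwrite lower ones where soft masks overlap, which
    keeps organ codes on top of the skin code.
    """
    if labels.unit != "label":
        raise ValueError("warp_labels expects a Volume with unit='label'")
    codes = np.unique(labels.voxels.astype(int))
    out = np.zeros(tuple(field.shape[:3]))
    targets = field.grid_points() + field.displacements
    for code in codes[codes > 0]:
        onehot = labels.with_voxels((labels.voxels.astype(int) == code).astype(float))
        soft = sample_volume(onehot, targets, fill=0.0)
        out[soft >= 0.5] = code
    return Volume(out, spacing=field.spacing, origin=field.origin, unit="label")


# -- I/O -------------------------------------------------------------------

_EXTENSIONS = (".mha", ".mhd", ".nii", ".nii.gz")


def _check_path(path: str) -> str:
    p = str(path)
    low = p.lower()
    if not any(low.endswith(e) for e in _EXTENSIONS):
        raise ValueError(f"unsupported volume extension for {p!r}; use one of {_EXTENSIONS}")
    return p


def write_volume(vol: Volume, path: str) -> None:
    """Write a volume as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    import SimpleITK as sitk

    p = _check_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.voxels.T))  # (z, y, x)
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, p)


def read_volume(path: str, unit: str = "HU") -> Volume:
    import SimpleITK as sitk

    p = _check_path(path)
    if not os.path.exists(p):
        raise FileNotFoundError(p)
    img = sitk.ReadImage(p)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 3:
        raise ValueError(f"{p!r} is not a scalar 3-D volume")
    return Volume(
        arr.T.astype(np.float64),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
        unit=unit,
    )


def write_field(fld: VectorField, path: str) -> None:
    """Store a displacement field as a 3-channel vector image."""
    import SimpleITK as sitk

    p = _check_path(path)
    arr = np.ascontiguousarray(np.transpose(fld.displacements, (2, 1, 0, 3)))
    img = sitk.GetImageFromArray(arr, isVector=True)
    img.SetSpacing(fld.spacing)
    img.SetOrigin(fld.origin)
    sitk.WriteImage(img, p)


def read_field(path: str) -> VectorField:
    import SimpleITK as sitk

    p = _check_path(path)
    if not os.path.exists(p):
        raise FileNotFoundError(p)
    img = sitk.ReadImage(p)
    arr = sitk.GetArrayFromImage(img)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"{p!r} is not a 3-channel displacement field")
    return VectorField(
        np.transpose(arr, (2, 1, 0, 3)).astype(np.float64),
        spacing=tuple(img.GetSpacing()),
        origin=tuple(img.GetOrigin()),
    )
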