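"""Six-parameter rigid pre-alignment.

Every weekly image is first rigidly registered to the planning image
(three translations, three rotations about the image centre) by minimising
the mean squared intensity error with a multiresolution fixed-step gradient
descent; deformable registration then only has to explain residual,
genuinely anatomical motion.  The rigid stage is also kept as a baseline
method in the comparison matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core_image import Volume, VectorField, sample_volume

__all__ = ["RigidTransform", "RigidConfig", "RigidResult", "register_rigid", "rigid_to_field"]


def _rotation_matrix(angles) -> np.ndarray:
    """Rotation about x, then y, then z (intrinsic x-y-z composition)."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


@dataclass
class RigidTransform:
    """``T(p) = R (p - c) + c + t`` with Euler angles in radians."""

    translation: tuple = (0.0, 0.0, 0.0)
    angles: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return _rotation_matrix(self.angles)

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (points - c) @ self.matrix.T + c + t

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        """Exact inverse map, ``T^{-1}(q) = R^T (q - c - t) + c``."""
        points = np.asarray(points, dtype=np.float64)
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (points - c - t) @ self.matrix + c

    def to_dict(self) -> dict:
        return {
            "translation": list(self.translation),
            "angles": list(self.angles),
            "center": list(self.center),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(tuple(d["translation"]), tuple(d["angles"]), tuple(d["center"]))


def rigid_to_field(transform: RigidTransform, geometry: Volume | VectorField) -> VectorField:
    """Dense displacement ``u(p) = T(p) - p`` on the reference grid."""
    pts = geometry.grid_points()
    disp = transform.apply(pts.reshape(-1, 3)).reshape(pts.shape) - pts
    return VectorField(disp, spacing=geometry.spacing, origin=geometry.origin)


@dataclass
class RigidConfig:
    levels: int = 3
    iterations: int = 100
    step_mm: float = 2.0        # initial step in scaled parameter space
    min_step_mm: float = 0.01
    fd_eps: float = 0.05        # finite-difference probe, scaled units (~mm)
    max_samples: int = 30000    # voxel subsample per metric evaluation
    divergence_patience: int = 10


@dataclass
class RigidResult:
    transform: RigidTransform
    metric_history: list = field(default_factory=list)
    converged: bool = True

    @property
    def final_metric(self) -> float:
        return self.metric_history[-1] if self.metric_history else float("nan")

    def summary(self) -> str:
        t = self.transform
        deg = np.degrees(t.angles)
        return (
            "Rigid registration (MSE, gradient descent)\n"
            f"  translation [mm]: {np.round(t.translation, 3).tolist()}\n"
            f"  rotation  [deg] : {np.round(deg, 3).tolist()}\n"
            f"  center    [mm]  : {np.round(t.center, 3).tolist()}\n"
            f"  final MSE       : {self.final_metric:.4g}\n"
            f"  converged       : {self.converged}"
        )


def _pyramid(vol: Volume, levels: int):
    """Coarse-to-fine list of volumes, smoothing + stride-2 decimation."""
    from scipy.ndimage import gaussian_filter

    out = [vol]
    for _ in range(levels - 1):
        prev = out[0]
        sm = gaussian_filter(prev.voxels, 1.0, mode="nearest")
        dec = sm[::2, ::2, ::2]
        if any(n < 4 for n in dec.shape):
            break
        out.insert(
            0,
            Volume(
                dec,
                spacing=tuple(2 * s for s in prev.spacing),
                origin=prev.origin,
                unit=prev.unit,
            ),
        )
    return out


def register_rigid(fixed: Volume, moving: Volume, cfg: RigidConfig | None = None) -> RigidResult:
    """Estimate the rigid transform minimising MSE(fixed, moving o T).

    Fixed-step gradient descent on the six parameters with central
    finite-difference gradients, step halving on non-improvement, and a
    three-level image pyramid.  Rotations are internally scaled so that one
    parameter unit moves a point at the image radius by about one mm.
    """
    cfg = cfg or RigidConfig()
    center = np.asarray(fixed.origin) + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing) / 2.0
    radius = float(np.linalg.norm((np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing))) / 2.0
    scales = np.array([1.0, 1.0, 1.0, radius, radius, radius])  # mm per unit

    rng = np.random.default_rng(0)  # fixed probe pattern; the method is deterministic
    theta = np.zeros(6)
    history: list[float] = []
    converged = True

    for level_fixed in _pyramid(fixed, cfg.levels):
        pts = level_fixed.grid_points().reshape(-1, 3)
        fvals = level_fixed.voxels.ravel()
        if pts.shape[0] > cfg.max_samples:
            sel = rng.choice(pts.shape[0], cfg.max_samples, replace=False)
            pts, fvals = pts[sel], fvals[sel]

        def metric(par):
            tr = RigidTransform(tuple(par[:3]), tuple(par[3:] / radius), tuple(center))
            mv = sample_volume(moving, tr.apply(pts))
            keep = mv != moving.fill_value
            if not keep.any():
                return float("inf")
            return float(np.mean((mv[keep] - fvals[keep]) ** 2))

        par = np.concatenate([theta[:3], theta[3:] * radius])  # scaled space (mm-ish)
        step = cfg.step_mm
        best = metric(par)
        history.append(best)
        worse_streak = 0
        for _ in range(cfg.iterations):
            grad = np.zeros(6)
            for i in range(6):
                probe = np.zeros(6)
                probe[i] = cfg.fd_eps
                grad[i] = (metric(par + probe) - metric(par - probe)) / (2 * cfg.fd_eps)
            gn = np.linalg.norm(grad)
            if gn == 0 or not np.isfinite(gn):
                break
            trial = par - step * grad / gn
            m = metric(trial)
            if m < best:
                par, best = trial, m
                worse_streak = 0
                step = min(step * 1.2, cfg.step_mm)  # recover after halvings
            else:
                step *= 0.5
                worse_streak += 1
                if worse_streak >= cfg.divergence_patience:
                    converged = False
                    break
            history.append(best)
            if step < cfg.min_step_mm:
                break
        theta = np.concatenate([par[:3], par[3:] / radius])

    transform = RigidTransform(tuple(theta[:3]), tuple(theta[3:]), tuple(center))
    return RigidResult(transform, history, converged)
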