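"""B-spline free-form deformation registration.

The deformation is parameterised by displacements attached to a regular
control-point lattice; the dense field is the tensor-product cubic
B-spline blend of the 4x4x4 surrounding control displacements.  The grid
is refined over a coarse-to-fine schedule (30, 20, 10, 5 mm by default)
with a matched image pyramid.

The optimiser is stochastic and force-based: every iteration draws a
fresh random voxel subsample, computes per-sample damped Gauss-Newton
steps (the displacement that would locally explain the residual; the
MSE metric uses a gradient-floored step, the MI variant works on
remapped intensities with Thirion damping) and scatters them onto the
lattice through the B-spline weights, mass-normalised.  The step size
follows the adaptive gain schedule

    a_k = a / (t_k + A)^alpha        (a = 1e4, A = 51, alpha = 0.602)

whose decay time advances with the correlation of successive gradients;
only the shape of the schedule is used (the raw amplitude presumes a
particular metric scale).  Updates are smoothed on the lattice, capped
per control point, accepted only when they reduce the same-sample cost,
and the whole lattice is lightly smoothed each iteration - the
force/diffusion equilibrium that also regularises demons.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates, spline_filter

from .core_image import Volume, VectorField

__all__ = [
    "BSplineGrid",
    "AsgdSchedule",
    "FFDConfig",
    "FFDResult",
    "cubic_bspline_weights",
    "bspline_displacement",
    "asgd_gain",
    "ffd_register",
]


def cubic_bspline_weights(t: np.ndarray) -> np.ndarray:
    """Weights of the 4 nodes floor(x)-1 .. floor(x)+2 for fraction t in [0,1).

    Uniform cubic B-spline basis; the four weights sum to 1 (partition of
    unity) and the central value at a node is B(0) = 2/3.
    """
    t = np.asarray(t, dtype=np.float64)
    t2, t3 = t * t, t * t * t
    return np.stack(
        [
            (1 - t) ** 3 / 6.0,
            (3 * t3 - 6 * t2 + 4) / 6.0,
            (-3 * t3 + 3 * t2 + 3 * t + 1) / 6.0,
            t3 / 6.0,
        ],
        axis=-1,
    )


@dataclass
class BSplineGrid:
    """Control-point lattice with per-node displacements (mm).

    ``coeffs`` has shape (ncx, ncy, ncz, 3); node ``(i, j, k)`` sits at
    ``origin + (i, j, k) * spacing``.  The lattice must extend at least two
    cells beyond the image so every interior point has full cubic support.
    """

    coeffs: np.ndarray
    spacing: tuple
    origin: tuple

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.ndim != 4 or self.coeffs.shape[-1] != 3:
            raise ValueError("coeffs must have shape (ncx, ncy, ncz, 3)")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be strictly positive")

    @classmethod
    def for_image(cls, geom: Volume | VectorField, spacing_mm: float) -> "BSplineGrid":
        """Zero-displacement lattice covering ``geom`` plus cubic support margin."""
        sp = np.full(3, float(spacing_mm))
        extent = (np.asarray(geom.shape[:3]) - 1) * np.asarray(geom.spacing)
        origin = np.asarray(geom.origin) - 2.0 * sp
        n = np.floor(extent / sp).astype(int) + 6
        return cls(np.zeros(tuple(n) + (3,)), tuple(sp), tuple(origin))

    @property
    def shape(self):
        return self.coeffs.shape

    def grid_coords(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points, dtype=np.float64) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def node_points(self) -> np.ndarray:
        axes = [self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Cubic B-spline displacement at world points (..., 3), in mm."""
        points = np.asarray(points, dtype=np.float64)
        g = self.grid_coords(points).reshape(-1, 3).T
        out = np.empty((g.shape[1], 3))
        for c in range(3):
            out[:, c] = map_coordinates(
                self.coeffs[..., c], g, order=3, prefilter=False, mode="nearest"
            )
        return out.reshape(points.shape)

    def dense_field(self, geom: Volume | VectorField) -> VectorField:
        pts = (
            geom.grid_points()
            if hasattr(geom, "grid_points")
            else np.asarray(geom)
        )
        return VectorField(
            self.displacement_at(pts), spacing=geom.spacing, origin=geom.origin
        )

    def _subdivided(self) -> "BSplineGrid":
        """Exact dyadic refinement (Lane-Riesenfeld knot insertion)."""
        c = self.coeffs
        for axis in range(3):
            c = np.moveaxis(c, axis, 0)
            even = (c[:-2] + 6.0 * c[1:-1] + c[2:]) / 8.0
            odd = (c[1:-1] + c[2:]) / 2.0
            out = np.empty((2 * even.shape[0] - 1,) + c.shape[1:])
            out[0::2] = even
            out[1::2] = odd[:-1]
            c = np.moveaxis(out, 0, axis)
        spacing = tuple(s / 2.0 for s in self.spacing)
        origin = tuple(o + s for o, s in zip(self.origin, self.spacing))
        return BSplineGrid(c, spacing, origin)

    def refined(self, geom: Volume | VectorField, spacing_mm: float) -> "BSplineGrid":
        """New lattice at a finer spacing reproducing the current field.

        Halving the spacing uses exact B-spline subdivision (basis
        nesting); other ratios sample the displacement at the new node
        positions and recover coefficients with a cubic spline prefilter,
        which is only approximate near the lattice boundary.
        """
        if np.allclose(np.asarray(self.spacing) / 2.0, spacing_mm):
            return self._subdivided()
        new = BSplineGrid.for_image(geom, spacing_mm)
        vals = self.displacement_at(new.node_points())
        coeffs = np.stack(
            [spline_filter(vals[..., c], order=3, mode="mirror") for c in range(3)],
            axis=-1,
        )
        return BSplineGrid(coeffs, new.spacing, new.origin)


def bspline_displacement(grid: BSplineGrid, point) -> np.ndarray:
    """Displacement at one world point via explicit 4x4x4 basis summation."""
    point = np.asarray(point, dtype=np.float64)
    g = grid.grid_coords(point)
    base = np.floor(g).astype(int)
    if np.any(base - 1 < 0) or np.any(base + 2 >= np.asarray(grid.shape[:3])):
        raise ValueError(f"point {point.tolist()} outside the supported lattice domain")
    w = [cubic_bspline_weights(g[a] - base[a]) for a in range(3)]
    neigh = grid.coeffs[
        base[0] - 1 : base[0] + 3,
        base[1] - 1 : base[1] + 3,
        base[2] - 1 : base[2] + 3,
        :,
    ]
    return np.einsum("i,j,k,ijkc->c", w[0], w[1], w[2], neigh)


@dataclass
class AsgdSchedule:
    """Gain constants of the decaying step-size law ``a/(k + A)^alpha``.

    The *adaptive* flavour advances the decay time by a sigmoid of the
    inner product of successive stochastic gradients instead of by 1 per
    iteration: anti-correlated (noise-dominated) gradients age the gain
    quickly, correlated ones keep it large.
    """

    a: float = 1.0e4
    A: float = 51.0
    alpha: float = 0.602
    f_max: float = 1.0
    f_min: float = -0.5
    omega: float = 0.2

    def __post_init__(self):
        if self.a <= 0 or self.A < 1 or not (0 < self.alpha <= 1):
            raise ValueError("require a > 0, A >= 1, 0 < alpha <= 1")

    def time_step(self, g: np.ndarray, g_prev: np.ndarray | None) -> float:
        """Decay-time increment from successive gradient correlation."""
        if g_prev is None:
            return 1.0
        denom = float(np.linalg.norm(g) * np.linalg.norm(g_prev))
        x = 0.0 if denom == 0 else -float(np.vdot(g, g_prev)) / denom
        return self.f_min + (self.f_max - self.f_min) / (1.0 + np.exp(-x / self.omega))


def asgd_gain(k: int, sched: AsgdSchedule | None = None) -> float:
    """Step-size gain at iteration k >= 0."""
    s = sched or AsgdSchedule()
    if k < 0:
        raise ValueError("iteration index must be >= 0")
    return s.a / (k + s.A) ** s.alpha


@dataclass
class FFDConfig:
    grid_spacings: tuple = (30.0, 20.0, 10.0, 5.0)
    image_factors: tuple = (4, 2, 2, 1)   # image downsampling per grid level
    iterations: tuple = (120, 150, 200, 300)  # per grid level, coarse to fine
    samples: int = 8192                   # voxel subsample redrawn each iteration
    metric: str = "mse"                   # "mse" | "mi"
    bins: int = 384
    asgd: AsgdSchedule = dfield(default_factory=AsgdSchedule)
    learning_rate: float = 1.0            # fraction of the damped per-sample step
    update_sigma: float = 0.7             # update smoothing on the lattice (cells)
    field_sigma: float = 0.4              # per-iteration smoothing of the total
                                          # lattice (cells): the demons-style
                                          # force/diffusion equilibrium
    step_cap_mm: float = 2.0              # per-iteration trust cap per control point
    guard: bool = True                    # same-sample accept/reject of each step
    presmooth_sigma: float = 1.0          # image smoothing (voxels) per level
    diff_threshold_frac: float = 0.002    # MSE residual deadzone, fraction of range
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_spacings) != len(self.image_factors):
            raise ValueError("grid_spacings and image_factors must have equal length")
        if self.metric not in ("mse", "mi"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class FFDResult:
    field: VectorField
    grid: BSplineGrid
    metric_history: list = dfield(default_factory=list)
    level_metrics: list = dfield(default_factory=list)  # full-volume metric per level

    def summary(self) -> str:
        mag = self.field.magnitude()
        return (
            "FFD (B-spline) registration\n"
            f"  final grid spacing [mm]: {self.grid.spacing}\n"
            f"  control points         : {tuple(self.grid.shape[:3])}\n"
            f"  mean |u| [mm]          : {mag.mean():.3f}\n"
            f"  max  |u| [mm]          : {mag.max():.3f}\n"
            f"  full-volume metric/lvl : {[round(m, 5) for m in self.level_metrics]}"
        )


def _downsample(vol: Volume, times: int) -> Volume:
    out = vol
    for _ in range(times):
        sm = gaussian_filter(out.voxels, 1.0, mode="nearest")
        out = Volume(
            sm[::2, ::2, ::2],
            spacing=tuple(2 * s for s in out.spacing),
            origin=out.origin,
            unit=out.unit,
        )
    return out


def _sample_image(vol: Volume, pts: np.ndarray, cval: float) -> np.ndarray:
    idx = (pts - np.asarray(vol.origin)) / np.asarray(vol.spacing)
    return map_coordinates(vol.voxels, idx.T, order=1, mode="constant", cval=cval)


def ffd_register(fixed: Volume, moving: Volume, cfg: FFDConfig | None = None) -> FFDResult:
    """Coarse-to-fine B-spline FFD registration of ``moving`` onto ``fixed``.

    Returns the dense displacement field on the fixed grid (planning
    points map to ``p + u(p)`` in moving space), the final control grid and
    per-iteration sampled-metric history.
    """
    cfg = cfg or FFDConfig()
    rng = np.random.default_rng(cfg.seed)
    grid = BSplineGrid.for_image(fixed, cfg.grid_spacings[0])
    history: list[float] = []
    level_metrics: list[float] = []

    raw_moving = moving
    if cfg.metric == "mi":
        # mutual-information matching realised as histogram-based
        # intensity remapping: the lookup (conditional median of the fixed
        # intensity given the moving bin) is estimated at full resolution,
        # first at the rigidly pre-aligned correspondence and again at
        # every level with the improving field; MSE forces on the
        # remapped intensities drive the rest
        from .registration_demons import _apply_lut, mi_intensity_remap

        sm = cfg.presmooth_sigma
        fsm = fixed.with_voxels(
            gaussian_filter(fixed.voxels, sm, mode="nearest") if sm > 0 else fixed.voxels
        )
        msm = moving.with_voxels(
            gaussian_filter(moving.voxels, sm, mode="nearest") if sm > 0 else moving.voxels
        )
        # remap the smoothed moving image (noise cannot then flip across
        # lookup transitions) and skip its per-level re-smoothing below
        _, lut, edges = mi_intensity_remap(fsm, msm, bins=cfg.bins)
        moving = moving.with_voxels(_apply_lut(msm.voxels, lut, edges))
        best_pair_mse = float(np.mean((fsm.voxels - msm.voxels) ** 2))

    n_levels = len(cfg.grid_spacings)
    fixed_cache: dict[int, Volume] = {}

    for li in range(n_levels):
        times = int(np.log2(cfg.image_factors[li]))
        if li > 0:
            grid = grid.refined(fixed, cfg.grid_spacings[li])
            if cfg.metric == "mi":
                # refresh the lookup with the improved correspondence, but
                # only when the current field genuinely pairs the images
                # better at full resolution than the previous estimate
                pts_full = fixed.grid_points()
                u_full = grid.displacement_at(pts_full)
                warped_full = fsm.with_voxels(
                    _sample_image(
                        msm, (pts_full + u_full).reshape(-1, 3), msm.fill_value
                    ).reshape(fixed.shape)
                )
                pair_mse = float(np.mean((fsm.voxels - warped_full.voxels) ** 2))
                if pair_mse < best_pair_mse:
                    best_pair_mse = pair_mse
                    _, lut, edges = mi_intensity_remap(fsm, warped_full, bins=cfg.bins)
                    moving = raw_moving.with_voxels(
                        _apply_lut(msm.voxels, lut, edges)
                    )
        if times not in fixed_cache:
            fixed_cache[times] = _downsample(fixed, times)
        flev = fixed_cache[times]
        mlev = _downsample(moving, times)
        if cfg.presmooth_sigma > 0:
            flev = flev.with_voxels(gaussian_filter(flev.voxels, cfg.presmooth_sigma, mode="nearest"))
            if cfg.metric != "mi":  # the MI remap already smoothed the moving image
                mlev = mlev.with_voxels(gaussian_filter(mlev.voxels, cfg.presmooth_sigma, mode="nearest"))

        # fixed-image gradient (per mm) at the sample positions: using the
        # fixed gradient in the force (Thirion's passive force) keeps flat
        # bright regions that exist only in one image from exerting drive
        fgrads = np.stack(
            [g / flev.spacing[a] for a, g in enumerate(np.gradient(flev.voxels))],
            axis=-1,
        )
        # candidate sample positions: interior voxel centres of the fixed level
        margin = 1
        nx, ny, nz = flev.shape
        fvox = flev.voxels

        lo, hi = np.percentile(fvox, (1, 99))
        deadzone = cfg.diff_threshold_frac * float(hi - lo)

        gain0 = asgd_gain(0, cfg.asgd)
        gshape = grid.shape
        ncx, ncy, ncz = gshape[:3]
        ntot = ncx * ncy * ncz
        t_decay = 0.0
        g_prev = None
        scale, scale0 = 1.0, 1.0  # relative learning rate, adapted by the guard

        def _basis_at(pts):
            g = grid.grid_coords(pts)
            base = np.floor(g).astype(int)
            frac = g - base
            wx = cubic_bspline_weights(frac[:, 0])
            wy = cubic_bspline_weights(frac[:, 1])
            wz = cubic_bspline_weights(frac[:, 2])
            offs = np.arange(-1, 3)
            ix = base[:, 0, None] + offs
            iy = base[:, 1, None] + offs
            iz = base[:, 2, None] + offs
            w = wx[:, :, None, None] * wy[:, None, :, None] * wz[:, None, None, :]
            flat = (
                (ix[:, :, None, None] * ncy + iy[:, None, :, None]) * ncz
                + iz[:, None, None, :]
            ).reshape(-1)
            return w, ix, iy, iz, flat

        def _draw(n):
            si = rng.integers(margin, nx - margin, n)
            sj = rng.integers(margin, ny - margin, n)
            sk = rng.integers(margin, nz - margin, n)
            spts = np.stack(
                [
                    flev.origin[0] + flev.spacing[0] * si,
                    flev.origin[1] + flev.spacing[1] * sj,
                    flev.origin[2] + flev.spacing[2] * sk,
                ],
                axis=-1,
            ).astype(np.float64)
            return spts, fvox[si, sj, sk], fgrads[si, sj, sk]

        # force normalisation scales: Thirion damping constant (bounds the
        # damped step at half a voxel), the MSE gradient floor, and a hard
        # per-sample step bound of one voxel
        force_k = float(np.mean(mlev.spacing)) ** 2
        grad_floor2 = (0.02 * (hi - lo) / float(np.mean(mlev.spacing))) ** 2
        step_bound = float(np.mean(mlev.spacing))

        n_iter = (
            cfg.iterations[min(li, len(cfg.iterations) - 1)]
            if isinstance(cfg.iterations, (tuple, list))
            else cfg.iterations
        )
        zero_streak = 0
        for k in range(n_iter):
            pts, fvals, mgrad = _draw(cfg.samples)
            w, ix, iy, iz, flat = _basis_at(pts)
            neigh = grid.coeffs[
                ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :], :
            ]
            u = np.einsum("sijk,sijkc->sc", w, neigh)
            q = pts + u
            mval = _sample_image(mlev, q, mlev.fill_value)
            valid = mval != mlev.fill_value
            nval = int(valid.sum())
            if nval == 0:
                raise FloatingPointError("no in-bounds samples; fields diverged")

            r = np.where(valid, mval - fvals, 0.0)
            metric = float(np.sum(r * r) / nval)
            if deadzone > 0:  # ignore residuals at the noise floor
                r = np.where(np.abs(r) < deadzone, 0.0, r)
            history.append(metric)
            if not np.isfinite(metric):
                raise FloatingPointError(f"non-finite metric at level {li}, iteration {k}")

            # per-sample Gauss-Newton step: the displacement that would
            # explain the residual locally.  The MSE metric uses a plain
            # gradient-floored step and therefore responds in full to
            # residuals the gradient cannot explain (it is as fragile to
            # one-sided contrast as a least-squares criterion should be);
            # the MI variant works on remapped intensities and adds
            # Thirion's r^2 damping so leftover unexplainable residuals
            # (e.g. enhanced vessels) cannot drag geometry
            gnorm2 = np.sum(mgrad * mgrad, axis=-1)
            if cfg.metric == "mi":
                denom = gnorm2 + (r * r) / force_k
            else:
                denom = gnorm2 + grad_floor2
            fstep = np.where(
                (denom > 1e-12) & valid, (fvals - mval) / np.maximum(denom, 1e-12), 0.0
            )
            fvec = fstep[:, None] * mgrad  # (S, 3) mm
            fmag = np.linalg.norm(fvec, axis=-1)
            over_s = fmag > step_bound
            if over_s.any():
                fvec[over_s] *= (step_bound / fmag[over_s])[:, None]

            contrib = (w[..., None] * fvec[:, None, None, None, :]).reshape(-1, 3)
            fcoef = np.stack(
                [np.bincount(flat, weights=contrib[:, c], minlength=ntot) for c in range(3)],
                axis=-1,
            ).reshape(ncx, ncy, ncz, 3)
            mass = np.bincount(flat, weights=w.reshape(-1), minlength=ntot).reshape(
                ncx, ncy, ncz
            )
            gmax = float(np.max(np.abs(fcoef)))
            if not np.isfinite(gmax):
                continue  # spoiled draw
            if gmax == 0.0:
                zero_streak += 1
                if zero_streak >= 5:  # perfectly matched (e.g. identical images)
                    break
                continue
            zero_streak = 0
            # mass-normalised scatter: a control point moves by the
            # weighted mean force over its support; sparse support is damped
            delta_raw = fcoef / (mass[..., None] + 0.5)
            gcoef = fcoef  # decay-time bookkeeping uses the raw scatter
            # smooth the update across the lattice: a control point cannot
            # chase an individual noisy sample, coherent motion passes
            if cfg.update_sigma > 0:
                delta_raw = np.stack(
                    [
                        gaussian_filter(delta_raw[..., c], cfg.update_sigma, mode="nearest")
                        for c in range(3)
                    ],
                    axis=-1,
                )
            t_decay = max(0.0, t_decay + cfg.asgd.time_step(gcoef, g_prev))
            g_prev = gcoef
            delta = (
                cfg.learning_rate
                * scale
                * (asgd_gain(t_decay, cfg.asgd) / gain0)
                * delta_raw
            )
            dnorm = np.linalg.norm(delta, axis=-1)  # per-control-point trust cap
            over = dnorm > cfg.step_cap_mm
            if over.any():
                delta[over] *= (cfg.step_cap_mm / dnorm[over])[..., None]
            # the force is the displacement increment that reduces the
            # residual, so it is added to the control displacements; the
            # total lattice is then lightly smoothed (regularisation):
            # persistent unmatchable dents diffuse away, genuine alignment
            # is continually re-driven by its forces
            new_coeffs = grid.coeffs + delta
            if cfg.field_sigma > 0:
                new_coeffs = np.stack(
                    [
                        gaussian_filter(new_coeffs[..., c], cfg.field_sigma, mode="nearest")
                        for c in range(3)
                    ],
                    axis=-1,
                )
            trial = BSplineGrid(new_coeffs, grid.spacing, grid.origin)

            if not cfg.guard:
                grid = trial
                continue
            # guarded step: re-evaluate on the same subsample; reject steps
            # that worsen it and halve the learning rate (recovers on
            # success) - insurance against noise-driven drift
            neigh2 = trial.coeffs[
                ix[:, :, None, None], iy[:, None, :, None], iz[:, None, None, :], :
            ]
            u2 = np.einsum("sijk,sijkc->sc", w, neigh2)
            mval2 = _sample_image(mlev, pts + u2, mlev.fill_value)
            valid2 = mval2 != mlev.fill_value
            r2 = np.where(valid2, mval2 - fvals, 0.0)
            metric2 = float(np.sum(r2 * r2) / max(int(valid2.sum()), 1))
            if metric2 <= metric:
                grid = trial
                scale = min(scale * 1.2, scale0)
            else:
                scale *= 0.5

        # full-volume metric at the end of the level (diagnostic)
        dense = grid.dense_field(fixed)
        from .core_image import warp_volume
        from . import similarity as _sim

        warped_full = warp_volume(moving, dense)
        if cfg.metric == "mse":
            level_metrics.append(_sim.mse(fixed, warped_full))
        else:
            level_metrics.append(-_sim.mutual_information(fixed, warped_full, bins=64))

    return FFDResult(grid.dense_field(fixed), grid, history, level_metrics)
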