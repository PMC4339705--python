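"""Demons dense-field deformable registration.

Classical demons iterates three steps on a coarse-to-fine pyramid: compute
per-voxel forces from the intensity difference and the fixed-image
gradient, add them to the displacement field, and smooth the field with a
Gaussian (the regulariser).  The force is Thirion's normalised form

    u = (m - f) grad(f) / (||grad(f)||^2 + (m - f)^2)

evaluated in voxel units, zeroed where the denominator vanishes and capped
per iteration for stability.

Two force variants exist:

* ``intensity`` - the plain monomodal force above (an MSE-type criterion);
* ``mi`` - a mutual-information-flavoured variant for images whose
  intensities disagree (e.g. a contrast agent present in only one scan):
  the moving image is remapped through a conditional-median lookup
  estimated from the joint histogram at full resolution (refreshed per
  pyramid level whenever the current field improves the pairing), after
  which the plain intensity force applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core_image import Volume, VectorField

__all__ = [
    "DemonsConfig",
    "DemonsResult",
    "demons_force",
    "gaussian_regularize",
    "mi_intensity_remap",
    "demons_register",
]


@dataclass
class DemonsConfig:
    """Knobs of the demons loop.

    ``sigma`` is the Gaussian regularisation width in voxels of the current
    pyramid level (1 suits CT intensities, 2.5 the piecewise-constant
    delineation maps); ``iterations`` gives the per-level counts from
    coarsest to finest.
    """

    sigma: float = 1.0
    levels: int = 3
    iterations: tuple = (200, 150, 100)
    force: str = "intensity"  # "intensity" | "mi"
    bins: int = 384
    step_cap_voxels: float = 1.25
    denom_eps: float = 1e-9
    early_tol: float = 1e-4
    early_patience: int = 5
    mi_refresh: bool = True            # re-estimate the MI lookup per level
    presmooth_sigma: float = 1.0       # image smoothing (voxels) before forces
    mi_presmooth_sigma: float = 0.5    # lighter smoothing for the MI pathway:
                                       # heavy blur merges small organs into
                                       # their surroundings before the lookup
                                       # can tell them apart
    diff_threshold_frac: float = 0.005  # zero force below this fraction of the
                                        # fixed-image robust intensity range

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.force not in ("intensity", "mi"):
            raise ValueError(f"unknown force variant {self.force!r}")


@dataclass
class DemonsResult:
    field: VectorField
    metric_history: list = field(default_factory=list)
    level_metrics: list = field(default_factory=list)  # best MSE per level

    @property
    def final_metric(self) -> float:
        return self.level_metrics[-1] if self.level_metrics else float("nan")

    def summary(self) -> str:
        mag = self.field.magnitude()
        return (
            "Demons registration\n"
            f"  field grid        : {tuple(self.field.shape[:3])}\n"
            f"  mean |u| [mm]     : {mag.mean():.3f}\n"
            f"  max  |u| [mm]     : {mag.max():.3f}\n"
            f"  per-level best MSE: {[round(m, 4) for m in self.level_metrics]}"
        )


def _force_arrays(
    fixed: np.ndarray,
    warped: np.ndarray,
    grad_f,
    eps: float,
    cap: float,
    diff_threshold: float = 0.0,
) -> np.ndarray:
    """Thirion force in voxel units given precomputed fixed-image gradients."""
    # move the sampling point so the warped moving intensity approaches the
    # fixed one: first order, u += (f - m) grad f / (|grad f|^2 + (f - m)^2)
    diff = fixed - warped
    if diff_threshold > 0:
        diff = np.where(np.abs(diff) < diff_threshold, 0.0, diff)
    gnorm2 = sum(g * g for g in grad_f)
    denom = gnorm2 + diff * diff
    scale = np.where(denom > eps, diff / np.maximum(denom, eps), 0.0)
    upd = np.stack([scale * g for g in grad_f], axis=-1)
    mag = np.linalg.norm(upd, axis=-1)
    over = mag > cap
    if over.any():
        upd[over] *= (cap / mag[over])[..., None]
    return upd


def demons_force(fixed: Volume, warped: Volume, eps: float = 1e-9, cap: float = 1.25) -> VectorField:
    """One demons force evaluation as a displacement update in mm."""
    if not fixed.same_geometry(warped):
        raise ValueError("fixed and warped volumes must share geometry")
    grad_f = np.gradient(fixed.voxels)  # voxel units
    upd = _force_arrays(fixed.voxels, warped.voxels, grad_f, eps, cap)
    return VectorField(upd * np.asarray(fixed.spacing), spacing=fixed.spacing, origin=fixed.origin)


def gaussian_regularize(fld: VectorField, sigma: float) -> VectorField:
    """Per-component Gaussian smoothing with a normalised kernel (sigma in voxels)."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sm = np.stack(
        [gaussian_filter(fld.displacements[..., c], sigma, mode="nearest") for c in range(3)],
        axis=-1,
    )
    return VectorField(sm, spacing=fld.spacing, origin=fld.origin)


def mi_intensity_remap(
    fixed: Volume,
    moving: Volume,
    bins: int = 256,
    how: str = "median",
    identity_gate_frac: float | None = 0.012,
    flat_gradient_frac: float | None = 0.012,
):
    """Remap moving intensities onto the fixed scale via the joint histogram.

    Each moving-intensity bin is replaced by a summary of the fixed
    intensities observed at the same (approximately aligned) positions:
    the conditional *median* by default, which tracks the majority tissue
    class of the bin instead of averaging distinct classes together, or
    the conditional mean (``how="mean"``).  Empty bins inherit the nearest
    populated bin's value.  Returns ``(remapped_volume, lut, edges)`` so
    the lookup can be reapplied to other samples of the same image.
    """
    if not fixed.same_geometry(moving):
        raise ValueError("volumes must share geometry")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    mv_all = moving.voxels.ravel()
    edges = np.linspace(mv_all.min(), mv_all.max() + 1e-9, bins + 1)
    which_all = np.clip(np.digitize(mv_all, edges) - 1, 0, bins - 1)
    # thresholds scale with the fixed image's robust intensity range, so
    # the same fractions serve raw HU and filtered intensity scales
    lo, hi = np.percentile(fixed.voxels, (1, 99))
    span = float(hi - lo)
    flat_gradient = (flat_gradient_frac or 0.0) * span
    if flat_gradient > 0:
        # estimate the lookup from locally flat voxels only: partial-volume
        # voxels at strong interfaces sweep the whole intensity range and
        # would otherwise flood the bins of genuinely low-intensity tissue
        gm = np.linalg.norm(np.stack(np.gradient(moving.voxels), axis=-1), axis=-1)
        gf = np.linalg.norm(np.stack(np.gradient(fixed.voxels), axis=-1), axis=-1)
        flat = ((gm < flat_gradient) & (gf < flat_gradient)).ravel()
        if flat.sum() < 100 * bins:  # fall back when the mask is too sparse
            flat = np.ones(mv_all.size, dtype=bool)
    else:
        flat = np.ones(mv_all.size, dtype=bool)
    mv = mv_all[flat]
    fv = fixed.voxels.ravel()[flat]
    which = which_all[flat]
    counts = np.bincount(which, minlength=bins)
    pop = counts > 0
    lut = np.full(bins, np.nan)
    if how == "mean":
        sums = np.bincount(which, weights=fv, minlength=bins)
        lut[pop] = sums[pop] / counts[pop]
    elif how == "median":
        order = np.lexsort((fv, which))
        starts = np.concatenate([[0], np.cumsum(counts)])
        fsorted = fv[order]
        for i in np.flatnonzero(pop):
            lo, hi = starts[i], starts[i + 1]
            lut[i] = fsorted[(lo + hi - 1) // 2]
    else:
        raise ValueError(f"unknown remap summary {how!r}")
    # count-weighted smoothing across moving bins: keeps sampling jitter
    # in the per-bin summaries from turning image noise into structure,
    # without letting empty neighbours dilute sparse but genuine bins
    wgt = counts.astype(float)
    num = gaussian_filter(np.where(pop, lut, 0.0) * wgt, 1.0, mode="nearest")
    den = gaussian_filter(wgt, 1.0, mode="nearest")
    centers = 0.5 * (edges[:-1] + edges[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        lut = np.where(den > 1e-12, num / den, centers)
    # bins with no (flat-voxel) observations keep their intensity: they
    # are typically partial-volume interface values for which an inherited
    # tissue value would repaint entire boundary shells
    gate_width = (identity_gate_frac or 0.0) * span
    if gate_width > 0:
        # shrink toward the identity unless the correction is large: small
        # corrections are dominated by mixed-tissue bin bias, large ones
        # are genuine systematic transforms (e.g. contrast enhancement)
        centers = 0.5 * (edges[:-1] + edges[1:])
        corr = lut - centers
        gate = corr**2 / (corr**2 + gate_width**2)
        lut = centers + corr * gate
    out = lut[which_all].reshape(moving.shape)
    return moving.with_voxels(out), lut, edges


def _apply_lut(arr: np.ndarray, lut: np.ndarray, edges: np.ndarray) -> np.ndarray:
    which = np.clip(np.digitize(arr.ravel(), edges) - 1, 0, lut.size - 1)
    return lut[which].reshape(arr.shape)


def _downsample(vol: Volume) -> Volume:
    sm = gaussian_filter(vol.voxels, 1.0, mode="nearest")
    return Volume(
        sm[::2, ::2, ::2],
        spacing=tuple(2 * s for s in vol.spacing),
        origin=vol.origin,
        unit=vol.unit,
    )


def _pyramid(vol: Volume, levels: int):
    out = [vol]
    for _ in range(levels - 1):
        nxt = _downsample(out[0])
        if any(n < 4 for n in nxt.shape):
            break
        out.insert(0, nxt)
    return out


def _warp_arr(moving: Volume, level_geom: Volume, disp_vox: np.ndarray) -> np.ndarray:
    """Sample ``moving`` at level grid + displacement (voxel units of level)."""
    sp = np.asarray(level_geom.spacing)
    org = np.asarray(level_geom.origin)
    idx = np.indices(level_geom.shape, dtype=np.float64)
    coords = []
    for a in range(3):
        world = org[a] + sp[a] * (idx[a] + disp_vox[..., a])
        coords.append((world - moving.origin[a]) / moving.spacing[a])
    return map_coordinates(
        moving.voxels, [c.ravel() for c in coords], order=1,
        mode="constant", cval=moving.fill_value,
    ).reshape(level_geom.shape)


def demons_register(fixed: Volume, moving: Volume, cfg: DemonsConfig | None = None) -> DemonsResult:
    """Multiresolution demons; returns the best-metric field on the fixed grid.

    The field is carried in voxel units of the current level, upsampled by
    trilinear interpolation between levels, and converted to mm at the end.
    Iterations stop early once the relative MSE improvement stays below
    ``early_tol`` for ``early_patience`` iterations.
    """
    cfg = cfg or DemonsConfig()
    if not np.all(np.isfinite(fixed.voxels)) or not np.all(np.isfinite(moving.voxels)):
        raise ValueError("input volumes contain non-finite values")
    raw_moving = moving
    if cfg.force == "mi":
        # estimate the intensity lookup at full resolution and the initial
        # (rigidly pre-aligned) correspondence; it is refreshed at every
        # pyramid level as the estimated field improves the pairing, and
        # after each remap the plain intensity force applies
        sm = cfg.mi_presmooth_sigma
        fsm_full = fixed.with_voxels(
            gaussian_filter(fixed.voxels, sm, mode="nearest") if sm > 0 else fixed.voxels
        )
        msm_full = moving.with_voxels(
            gaussian_filter(moving.voxels, sm, mode="nearest") if sm > 0 else moving.voxels
        )
        # remap the *smoothed* moving image: noise-driven crossings of the
        # lookup's tissue-flip intensities would otherwise speckle the
        # remapped image with spurious bright voxels
        _, lut, edges = mi_intensity_remap(fsm_full, msm_full, bins=cfg.bins)
        moving = moving.with_voxels(_apply_lut(msm_full.voxels, lut, edges))
        best_pair_mse = float(np.mean((fsm_full.voxels - msm_full.voxels) ** 2))
        # keep the blur budget of the two sides identical: the remapped
        # moving is built from the smoothed image, so the fixed pyramid
        # starts from the smoothed image as well and the per-level
        # smoothing below is skipped for both
        fixed = fsm_full
    fixed_levels = _pyramid(fixed, cfg.levels)
    iterations = tuple(cfg.iterations)
    if len(iterations) < len(fixed_levels):
        iterations = (iterations[0],) * (len(fixed_levels) - len(iterations)) + iterations

    disp = None  # (nx, ny, nz, 3) in voxel units of current level
    history: list[float] = []
    level_metrics: list[float] = []

    for li, flev in enumerate(fixed_levels):
        if disp is None:
            disp = np.zeros(flev.shape + (3,))
        else:
            prev = fixed_levels[li - 1]
            # resample each component onto the finer grid, rescale to its voxels
            idx = np.indices(flev.shape, dtype=np.float64)
            coords = [
                ((flev.origin[a] + flev.spacing[a] * idx[a]) - prev.origin[a]) / prev.spacing[a]
                for a in range(3)
            ]
            flat = [c.ravel() for c in coords]
            up = np.empty(flev.shape + (3,))
            for a in range(3):
                comp_mm = disp[..., a] * prev.spacing[a]
                up[..., a] = map_coordinates(comp_mm, flat, order=1, mode="nearest").reshape(flev.shape) / flev.spacing[a]
            disp = up

        if cfg.force == "mi" and cfg.mi_refresh and li > 0:
            # refresh the intensity lookup with the improved correspondence
            idxf = np.indices(fixed.shape, dtype=np.float64)
            lflat = [
                (
                    (fixed.origin[a] + fixed.spacing[a] * idxf[a]) - flev.origin[a]
                ).ravel()
                / flev.spacing[a]
                for a in range(3)
            ]
            disp_mm_full = np.stack(
                [
                    map_coordinates(
                        disp[..., a] * flev.spacing[a], lflat, order=1, mode="nearest"
                    ).reshape(fixed.shape)
                    for a in range(3)
                ],
                axis=-1,
            )
            mcoords = [
                (
                    (fixed.origin[a] + fixed.spacing[a] * idxf[a] + disp_mm_full[..., a])
                    - msm_full.origin[a]
                ).ravel()
                / msm_full.spacing[a]
                for a in range(3)
            ]
            warped_full = fsm_full.with_voxels(
                map_coordinates(
                    msm_full.voxels, mcoords, order=1, mode="constant",
                    cval=msm_full.fill_value,
                ).reshape(fixed.shape)
            )
            # guarded refresh: a coarse-level field can pair the images
            # *worse* at full resolution than the initial alignment did,
            # and re-estimating from such a pairing corrupts the lookup
            pair_mse = float(np.mean((fsm_full.voxels - warped_full.voxels) ** 2))
            if pair_mse < best_pair_mse:
                best_pair_mse = pair_mse
                _, lut, edges = mi_intensity_remap(fsm_full, warped_full, bins=cfg.bins)
                moving = raw_moving.with_voxels(_apply_lut(msm_full.voxels, lut, edges))

        # the moving image goes through the *same* downsampling chain as
        # the fixed one, so identical inputs produce identically zero
        # forces at every level (no pyramid-aliasing phantom forces)
        mov_lvl = moving
        for _ in range(len(fixed_levels) - 1 - li):
            mov_lvl = _downsample(mov_lvl)
        # mildly smooth both images before force computation so acquisition
        # noise does not masquerade as matching signal in flat regions
        # (the remapped moving of the MI variant is built from an already
        # smoothed image, so it skips the extra smoothing)
        if cfg.presmooth_sigma > 0 and cfg.force != "mi":
            flev = flev.with_voxels(gaussian_filter(flev.voxels, cfg.presmooth_sigma, mode="nearest"))
            mov_lvl = mov_lvl.with_voxels(
                gaussian_filter(mov_lvl.voxels, cfg.presmooth_sigma, mode="nearest")
            )

        lo, hi = np.percentile(flev.voxels, (1, 99))
        diff_threshold = cfg.diff_threshold_frac * float(hi - lo)
        grad_f = np.gradient(flev.voxels)
        best_disp = disp.copy()
        best_metric = np.inf
        stale = 0
        for _ in range(iterations[li]):
            warped = _warp_arr(mov_lvl, flev, disp)
            metric = float(np.mean((warped - flev.voxels) ** 2))
            history.append(metric)
            if not np.isfinite(metric):
                raise FloatingPointError(
                    f"non-finite demons metric at level {li}, iteration {len(history)}"
                )
            if metric < best_metric * (1 - cfg.early_tol):
                stale = 0
            else:
                stale += 1
            if metric < best_metric:
                best_metric = metric
                best_disp = disp.copy()
            if stale >= cfg.early_patience:
                break
            upd = _force_arrays(
                flev.voxels, warped, grad_f, cfg.denom_eps, cfg.step_cap_voxels, diff_threshold
            )
            disp = disp + upd
            for a in range(3):
                disp[..., a] = gaussian_filter(disp[..., a], cfg.sigma, mode="nearest")
        disp = best_disp
        level_metrics.append(best_metric)

    top = fixed_levels[-1]
    mm = disp * np.asarray(top.spacing)
    return DemonsResult(
        VectorField(mm, spacing=top.spacing, origin=top.origin),
        history,
        level_metrics,
    )
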