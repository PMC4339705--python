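"""Synthetic head-and-neck phantom with known ground truth.

The phantom stands in for a longitudinal patient dataset: a planning CT
plus weekly CTs showing the anatomical drift typical of a radiotherapy
course - parotid glands losing on average 28.3% of their volume over the
course, the neck thinning by about 7.9 mm, and an intravenous contrast
agent raising parotid/vessel intensities in the *planning* scan only.

Anatomy is analytic (ellipsoids, cylinders, a mandibular half-torus on a
soft-tissue body), so every weekly image is rendered exactly from the
planning anatomy transported by a known smooth, invertible displacement
field.  The ground truth therefore provides the reference role a human
expert plays on real data: per-week dense fields, landmark positions and
label maps, all consistent by construction.

Dose is analytic as well: a 70 Gy plateau in a spherical target abutting
the left parotid with a steep logistic fall-off (about 5 Gy/mm), fixed in
room coordinates; each weekly grid carries the per-fraction dose
(planned / 35) so anatomy moves through a static dose field, as delivered
treatments without replanning do.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np

from .core_image import Volume, VectorField
from .dose_accumulation import DoseGrid
from .evaluation import LandmarkSet

__all__ = [
    "PhantomSpec",
    "PlanningPhantom",
    "GroundTruth",
    "WeeklySample",
    "generate_planning_phantom",
    "generate_weekly_series",
    "generate_dose",
]


@dataclass
class PhantomSpec:
    """Phantom geometry, anatomy-change statistics and acquisition noise.

    The anatomy-change defaults are course totals reached at the final
    week with linear weekly progression.
    """

    shape: tuple = (96, 96, 64)
    spacing: tuple = (2.0, 2.0, 2.0)
    weeks: int = 6
    parotid_volume_loss: float = 0.283     # course-total fraction
    parotid_volume_loss_sd: float = 0.18   # across-patient spread (sampling helper)
    neck_reduction_mm: float = 7.9         # course-total thickness decrease
    parotid_drift_mm: tuple = (5.0, 0.0, -2.0)  # medial/inferior drift at course end
    contrast_offset_hu: float = 100.0      # planning-only enhancement of vessels
    parotid_contrast_offset_hu: float = 75.0  # enhancing gland: hyperdense vs muscle
    noise_sd_hu: float = 10.0
    texture_sd_hu: float = 15.0            # anatomical soft-tissue heterogeneity
    residual_bumps: int = 3
    residual_amplitude_mm: float = 2.0
    residual_sigma_mm: float = 25.0
    # residual patient setup error per weekly scan (in-room corrections
    # only removed offsets beyond a tolerance, so mm-scale offsets remain)
    setup_translation_sd_mm: float = 1.5
    setup_rotation_sd_deg: float = 0.5
    target_dose_gy: float = 70.0
    fractions: int = 35
    dose_gradient_gy_mm: float = 5.0
    target_radius_mm: float = 18.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.parotid_volume_loss < 1.0):
            raise ValueError("parotid_volume_loss must be in [0, 1)")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if len(self.shape) != 3 or any(n < 8 for n in self.shape):
            raise ValueError("shape must be 3-D with >= 8 voxels per axis")

    @property
    def extent(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing)


# -- analytic anatomy ------------------------------------------------------

_BODY_CENTER = np.array([96.0, 96.0, 64.0])
_BODY_SEMI = np.array([70.0, 60.0, 60.0])
_PAROTID_R_C = np.array([56.0, 100.0, 80.0])
_PAROTID_L_C = np.array([136.0, 100.0, 80.0])
_PAROTID_SEMI = np.array([14.0, 16.0, 18.0])
_CORD_XY = np.array([96.0, 130.0])
_TARGET_CENTER = np.array([112.0, 100.0, 78.0])

_LANDMARK_POSITIONS = np.array(
    [
        [96.0, 130.0, 98.0],   # 1 odontoid
        [96.0, 58.0, 102.0],   # 2 mandible, lower part
        [96.0, 66.0, 74.0],    # 3 thyroid notch
        [88.0, 78.0, 80.0],    # 4 hyoid lesser cornu (right)
        [104.0, 78.0, 80.0],   # 5 hyoid lesser cornu (left)
        [104.0, 74.0, 16.0],   # 6 sternum, superior-left
        [96.0, 140.0, 90.0],   # 7 C2-C3 disk, posterior
        [96.0, 80.0, 86.0],    # 8 vallecula
        [96.0, 50.0, 100.0],   # 9 philtrum
        [96.0, 97.0, 92.0],    # 10 palatine uvula, lower part
        [68.0, 108.0, 78.0],   # 11 carotid bifurcation (right)
        [124.0, 108.0, 78.0],  # 12 carotid bifurcation (left)
        [58.0, 106.0, 86.0],   # 13 right parotid
        [134.0, 94.0, 74.0],   # 14 left parotid
    ]
)


def _ellipsoid_rho(pts, center, semi):
    return np.sqrt(np.sum(((pts - center) / semi) ** 2, axis=-1))


class _Anatomy:
    """Analytic HU / label / mask model evaluated at arbitrary mm points."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        ext = spec.extent
        need = _BODY_CENTER + _BODY_SEMI
        if np.any(need > ext + 1e-6) or np.any(_BODY_CENTER - _BODY_SEMI < -1e-6):
            raise ValueError(
                f"phantom organs exceed the grid: body needs {need} mm, grid extent is {ext} mm"
            )
        # soft-tissue heterogeneity: a fixed random cosine series, so the
        # texture real CT tissue shows is part of the anatomy and moves
        # with it (it is what low-contrast registration locks onto)
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 99]))
        n_waves = 32
        wavelength = rng.uniform(10.0, 40.0, n_waves)
        direction = rng.normal(size=(n_waves, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        self._tex_k = 2.0 * np.pi * direction / wavelength[:, None]
        self._tex_phase = rng.uniform(0.0, 2.0 * np.pi, n_waves)
        self._tex_amp = np.full(n_waves, spec.texture_sd_hu * np.sqrt(2.0 / n_waves))

    def texture(self, p) -> np.ndarray:
        t = np.zeros(p.shape[:-1])
        for k, ph, a in zip(self._tex_k, self._tex_phase, self._tex_amp):
            t += a * np.cos(p @ k + ph)
        return t

    # geometry predicates -------------------------------------------------
    def body_rho(self, p):
        return _ellipsoid_rho(p, _BODY_CENTER, _BODY_SEMI)

    def in_body(self, p):
        return self.body_rho(p) <= 1.0

    def skin_shell(self, p):
        rho = self.body_rho(p)
        return (rho >= 0.93) & (rho <= 1.0)

    def parotid_r(self, p):
        return _ellipsoid_rho(p, _PAROTID_R_C, _PAROTID_SEMI) <= 1.0

    def parotid_l(self, p):
        return _ellipsoid_rho(p, _PAROTID_L_C, _PAROTID_SEMI) <= 1.0

    def vertebra(self, p):
        r = np.linalg.norm(p[..., :2] - _CORD_XY, axis=-1)
        return (r <= 10.0) & (r > 4.5) & (p[..., 2] >= 10.0) & (p[..., 2] <= 100.0)

    def cord(self, p):
        r = np.linalg.norm(p[..., :2] - _CORD_XY, axis=-1)
        return (r <= 3.5) & (p[..., 2] >= 10.0) & (p[..., 2] <= 100.0)

    def brainstem(self, p):
        r = np.linalg.norm(p[..., :2] - np.array([96.0, 124.0]), axis=-1)
        return (r <= 6.0) & (p[..., 2] > 100.0) & (p[..., 2] <= 122.0)

    def mandible(self, p):
        rel = p - np.array([96.0, 90.0, 104.0])
        ring = np.sqrt(rel[..., 0] ** 2 + rel[..., 1] ** 2) - 32.0
        tube = np.sqrt(ring**2 + rel[..., 2] ** 2)
        return (tube <= 5.0) & (rel[..., 1] <= 0.0)

    def thyroid_cartilage(self, p):
        return _ellipsoid_rho(p, np.array([96.0, 70.0, 72.0]), np.array([8.0, 4.0, 6.0])) <= 1.0

    def hyoid(self, p):
        a = _ellipsoid_rho(p, np.array([88.0, 78.0, 80.0]), np.array([3.0, 3.0, 3.0])) <= 1.0
        b = _ellipsoid_rho(p, np.array([104.0, 78.0, 80.0]), np.array([3.0, 3.0, 3.0])) <= 1.0
        return a | b

    def sternum(self, p):
        return _ellipsoid_rho(p, np.array([96.0, 78.0, 12.0]), np.array([16.0, 6.0, 8.0])) <= 1.0

    def carotids(self, p):
        ra = np.linalg.norm(p[..., :2] - np.array([68.0, 108.0]), axis=-1)
        rb = np.linalg.norm(p[..., :2] - np.array([124.0, 108.0]), axis=-1)
        inz = (p[..., 2] >= 20.0) & (p[..., 2] <= 78.0)
        return ((ra <= 3.0) | (rb <= 3.0)) & inz

    def airway(self, p):
        r = np.linalg.norm(p[..., :2] - np.array([96.0, 88.0]), axis=-1)
        return (r <= 7.0) & (p[..., 2] >= 30.0) & (p[..., 2] <= 110.0)

    # rendered fields ------------------------------------------------------
    def hu(self, p, contrast: bool) -> np.ndarray:
        out = np.full(p.shape[:-1], -1000.0)
        body = self.in_body(p)
        # muscle/fat neck tissue: heterogeneous (textured) with a gentle
        # gradient; the delineated organs below are homogeneous glands and
        # nervous tissue, so they overwrite the texture
        out[body] = 55.0 + 0.15 * (p[..., 1][body] - 96.0)
        if self.spec.texture_sd_hu > 0:
            out[body] += self.texture(p)[body]
        # parotid glands are fat-rich, well below muscle
        parotid = self.parotid_r(p) | self.parotid_l(p)
        out[parotid] = 0.0
        out[self.brainstem(p)] = 30.0
        out[self.cord(p)] = 35.0
        carotid = self.carotids(p)
        out[carotid] = 45.0
        if contrast:
            out[parotid] += self.spec.parotid_contrast_offset_hu
            out[carotid] += self.spec.contrast_offset_hu
        for bone, hu in (
            (self.vertebra(p), 700.0),
            (self.mandible(p), 700.0),
            (self.thyroid_cartilage(p), 400.0),
            (self.hyoid(p), 400.0),
            (self.sternum(p), 700.0),
        ):
            out[bone] = hu
        out[self.airway(p)] = -1000.0
        out[~body] = -1000.0
        return out

    def label(self, p) -> np.ndarray:
        """Delineation codes 1..5; organ codes override the skin shell."""
        out = np.zeros(p.shape[:-1])
        out[self.skin_shell(p)] = 1
        out[self.parotid_r(p)] = 2
        out[self.parotid_l(p)] = 3
        out[self.brainstem(p)] = 4
        out[self.cord(p)] = 5
        return out


# -- deformation model -----------------------------------------------------

def _neck_envelope(z):
    return 1.0 / (1.0 + np.exp((z - 75.0) / 8.0))


class _Deformation:
    """Analytic planning -> week displacement for one generated course."""

    def __init__(self, spec: PhantomSpec, rng: np.random.Generator):
        self.spec = spec
        self._terms_cache: dict = {}
        self._parotid_samples = {}
        # per-week residual setup transform (room-frame rigid offset)
        from .registration_rigid import RigidTransform

        self.setups = []
        for _ in range(spec.weeks):
            t = rng.normal(0.0, spec.setup_translation_sd_mm, 3)
            ang = np.deg2rad(rng.normal(0.0, spec.setup_rotation_sd_deg, 3))
            self.setups.append(
                RigidTransform(tuple(t), tuple(ang), tuple(_BODY_CENTER))
            )
        # residual smooth bumps, kept away from the parotids so the gland
        # volume change stays dominated by the prescribed shrinkage
        self.bumps = []
        for _ in range(spec.residual_bumps):
            for _try in range(100):
                c = np.array(
                    [
                        rng.uniform(40.0, 152.0),
                        rng.uniform(50.0, 142.0),
                        rng.uniform(15.0, 115.0),
                    ]
                )
                if (
                    np.linalg.norm(c - _PAROTID_R_C) >= 45.0
                    and np.linalg.norm(c - _PAROTID_L_C) >= 45.0
                ):
                    break
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            amp = rng.uniform(0.5, spec.residual_amplitude_mm)
            self.bumps.append((c, amp * direction))

    def _neck_coeff(self, frac):
        return (self.spec.neck_reduction_mm / 2.0) * frac / _BODY_SEMI[0]

    def _interior_samples(self, center) -> np.ndarray:
        """~1.5 mm lattice of points inside one parotid (volume probes)."""
        key = tuple(center)
        if key not in self._parotid_samples:
            axes = [
                np.arange(center[a] - _PAROTID_SEMI[a], center[a] + _PAROTID_SEMI[a], 1.5)
                for a in range(3)
            ]
            pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
            self._parotid_samples[key] = pts[_ellipsoid_rho(pts, center, _PAROTID_SEMI) <= 1.0]
        return self._parotid_samples[key]

    def _mapped_volume_factor(self, center, week) -> float:
        """Volume of the mapped parotid relative to planning, via the Jacobian."""
        pts = self._interior_samples(center)
        h = 0.5
        jac = np.zeros((pts.shape[0], 3, 3))
        for a in range(3):
            probe = np.zeros(3)
            probe[a] = h
            du = self.displacement(pts + probe, week) - self.displacement(pts - probe, week)
            jac[:, :, a] = du / (2.0 * h)
            jac[:, a, a] += 1.0
        return float(np.mean(np.linalg.det(jac)))

    def _terms(self, week):
        """Per-parotid (centre, shrink factor, drift), volume-calibrated.

        The shrink factor is solved numerically so the *composed* map
        (shrinkage + neck thinning + residual) realises the prescribed
        weekly volume loss, not just the isolated parotid term.
        """
        if week in self._terms_cache:
            return self._terms_cache[week]
        spec = self.spec
        frac = week / spec.weeks
        target = 1.0 - spec.parotid_volume_loss * frac
        lam0 = target ** (1.0 / 3.0)
        terms = []
        for center, medial in ((_PAROTID_R_C, +1.0), (_PAROTID_L_C, -1.0)):
            drift = frac * np.array(spec.parotid_drift_mm) * np.array([medial, 1.0, 1.0])
            terms.append([center, lam0, drift])
        self._terms_cache[week] = terms
        for _ in range(3):  # fixed-point refinement of each shrink factor
            for t in terms:
                v = self._mapped_volume_factor(t[0], week)
                t[1] *= (target / v) ** (1.0 / 3.0)
        return terms

    def displacement(self, points: np.ndarray, week: int) -> np.ndarray:
        """u(p) for planning points (..., 3) at the given week (1-based).

        The map composes the anatomical deformation with that week's
        residual setup transform: q = T_w(p + u_anat(p)).
        """
        p = np.asarray(points, dtype=np.float64)
        u = self._anatomical(p, week)
        setup = self.setups[week - 1]
        moved = setup.apply((p + u).reshape(-1, 3)).reshape(p.shape)
        return moved - p

    def _anatomical(self, p: np.ndarray, week: int) -> np.ndarray:
        spec = self.spec
        frac = week / spec.weeks
        u = np.zeros_like(p)
        # lateral neck thinning: centripetal xy contraction in the neck band
        a = self._neck_coeff(frac)
        env = _neck_envelope(p[..., 2])
        u[..., 0] -= a * env * (p[..., 0] - _BODY_CENTER[0])
        u[..., 1] -= a * env * (p[..., 1] - _BODY_CENTER[1])
        # parotid shrinkage toward (drifting) centres
        for center, lam, drift in self._terms(week):
            rho = _ellipsoid_rho(p, center, _PAROTID_SEMI)
            g = np.where(rho <= 1.0, 1.0, np.exp(-(((rho - 1.0) / 0.35) ** 2)))
            u += g[..., None] * ((lam - 1.0) * (p - center) + drift)
        # small random smooth residual
        for c, vec in self.bumps:
            w = np.exp(-np.sum((p - c) ** 2, axis=-1) / (2.0 * spec.residual_sigma_mm**2))
            u += frac * w[..., None] * vec
        return u


# -- generated artifacts ---------------------------------------------------

@dataclass
class PlanningPhantom:
    image: Volume               # with contrast offsets (as acquired)
    image_nocontrast: Volume    # same anatomy, no contrast agent
    labels: Volume              # delineation codes 0..5
    landmarks: LandmarkSet
    anatomy: _Anatomy


@dataclass
class GroundTruth:
    """Reference correspondence for one week (the 'expert' role)."""

    field: VectorField          # planning -> week, dense on planning grid
    landmarks: LandmarkSet      # positions on the weekly anatomy
    labels: Volume              # weekly delineation map


@dataclass
class WeeklySample:
    image: Volume
    truth: GroundTruth


def _grid_points(spec: PhantomSpec) -> np.ndarray:
    axes = [spec.spacing[a] * np.arange(spec.shape[a]) for a in range(3)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def generate_planning_phantom(spec: PhantomSpec | None = None) -> PlanningPhantom:
    """Render the planning anatomy: HU volume, delineation map, landmarks."""
    spec = spec or PhantomSpec()
    anatomy = _Anatomy(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    pts = _grid_points(spec)
    noise = rng.normal(0.0, spec.noise_sd_hu, spec.shape)
    hu_c = anatomy.hu(pts, contrast=True) + noise
    hu_n = anatomy.hu(pts, contrast=False) + noise
    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    labels = Volume(anatomy.label(pts), unit="label", **geom)
    landmarks = LandmarkSet.from_catalog(_LANDMARK_POSITIONS.copy())
    return PlanningPhantom(
        Volume(hu_c, unit="HU", **geom),
        Volume(hu_n, unit="HU", **geom),
        labels,
        landmarks,
        anatomy,
    )


def _invert_displacement(deform: _Deformation, week: int, targets: np.ndarray) -> np.ndarray:
    """Fixed-point inversion: find p with p + u(p) = q for each target q."""
    p = targets.copy()
    for _ in range(12):  # contraction mapping; |u| <~ 8 mm shrinks well below 1e-3 mm
        p = targets - deform.displacement(p, week)
    return p


def generate_weekly_series(
    spec: PhantomSpec, planning: PlanningPhantom, max_attempts: int = 5
) -> list:
    """Weekly images with exact ground-truth fields, landmarks and labels.

    The course deformation composes parotid shrinkage (reaching the
    course-total volume loss at the final week, linear weekly
    progression), lateral neck thinning and a small random smooth
    residual; non-invertible draws of the residual are rejected and
    redrawn (error after ``max_attempts``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    pts = _grid_points(spec)
    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))

    deform = None
    for attempt in range(max_attempts):
        cand = _Deformation(spec, rng)
        disp_final = cand.displacement(pts, spec.weeks)
        fld = VectorField(disp_final, **geom)
        if fld.jacobian_determinant().min() > 0:
            deform = cand
            break
    if deform is None:
        raise RuntimeError(f"no invertible residual field found in {max_attempts} attempts")

    weeks = []
    for w in range(1, spec.weeks + 1):
        disp = deform.displacement(pts, w)
        fld = VectorField(disp, **geom)
        inv = _invert_displacement(deform, w, pts)
        hu = planning.anatomy.hu(inv, contrast=False)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, spec.shape)
        labels = Volume(planning.anatomy.label(inv), unit="label", **geom)
        lm_pos = planning.landmarks.positions
        # recorded motion is the dense field sampled at the planning
        # positions, so landmarks and field are consistent by construction
        lm_weekly = planning.landmarks.with_positions(lm_pos + fld.sample(lm_pos))
        weeks.append(
            WeeklySample(Volume(hu, unit="HU", **geom), GroundTruth(fld, lm_weekly, labels))
        )
    return weeks


def planned_dose_at(spec: PhantomSpec, points: np.ndarray) -> np.ndarray:
    """Analytic planned dose (Gy) at world points: plateau + logistic fall-off."""
    d = np.linalg.norm(np.asarray(points, dtype=np.float64) - _TARGET_CENTER, axis=-1)
    w = spec.target_dose_gy / (4.0 * spec.dose_gradient_gy_mm)
    raw = 1.0 / (1.0 + np.exp(-(spec.target_radius_mm - d) / w))
    norm = 1.0 / (1.0 + np.exp(-spec.target_radius_mm / w))
    return spec.target_dose_gy * raw / norm


def generate_dose(spec: PhantomSpec, planning: PlanningPhantom):
    """Planned dose plus per-week fraction dose grids.

    The treatment is delivered as planned, so the dose field is rigidly
    attached to the treatment room: every weekly fraction grid equals the
    planned dose divided by the number of fractions, on the same grid.
    """
    pts = _grid_points(spec)
    geom = dict(spacing=spec.spacing, origin=(0.0, 0.0, 0.0))
    planned_arr = planned_dose_at(spec, pts)
    if not np.isclose(
        planned_dose_at(spec, _TARGET_CENTER), spec.target_dose_gy
    ):
        raise RuntimeError("dose model failed to reach the prescription at the target centre")
    planned = DoseGrid(planned_arr, provenance="planned", **geom)
    weekly = [
        DoseGrid(planned_arr / spec.fractions, provenance=f"week{w}", **geom)
        for w in range(1, spec.weeks + 1)
    ]
    return planned, weekly
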