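"""End-to-end study orchestration across the method matrix.

A *method* is one combination of registration family (rigid, demons,
FFD), input preprocessing (original CTs, sigmoid-filtered CTs,
delineation maps) and similarity metric (MSE, MI).  Ten deformable
combinations are valid - MI is never paired with delineation maps, whose
codes are arbitrary, and the rigid baseline only runs as original+MSE -
giving an 11-method matrix including the baseline.

``run_study`` executes, per weekly CT and method: rigid pre-alignment,
preprocessing, deformable registration, contour propagation (Dice),
landmark propagation (registration error), dose warping + accumulation
and cumulated landmark / mean parotid dose errors against the ground
truth; per-pair paired tests summarise the method ordering.  Weekly dose
grids carry per-fraction dose; the pipeline scales them by
``fractions / weeks`` when cumulating so cumulated doses live on the
total-course (70 Gy) scale.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dfield, replace

import numpy as np
import pandas as pd

from .core_image import Volume, VectorField, warp_volume, warp_labels
from .dose_accumulation import DoseGrid, accumulate, mean_dose, warp_dose
from .evaluation import (
    LandmarkSet,
    accuracy_precision,
    compare_methods,
    cumulated_dose_at_landmarks,
    landmark_errors,
    propagate_landmarks,
)
from .preprocessing import SigmoidParams, sigmoid_filter
from .registration_demons import DemonsConfig, demons_register
from .registration_ffd import FFDConfig, ffd_register
from .registration_rigid import RigidConfig, RigidTransform, register_rigid, rigid_to_field
from .similarity import dsc
from .synthetic_phantom import (
    PhantomSpec,
    generate_dose,
    generate_planning_phantom,
    generate_weekly_series,
)

__all__ = [
    "MethodSpec",
    "enumerate_methods",
    "StudyData",
    "StudyConfig",
    "StudyReport",
    "phantom_study",
    "run_study",
]


@dataclass(frozen=True)
class MethodSpec:
    """One cell of the method matrix."""

    name: str
    family: str       # rigid | demons | ffd
    input_mode: str   # original | filtered | dmaps
    metric: str       # mse | mi

    def __post_init__(self):
        if self.family not in ("rigid", "demons", "ffd"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.input_mode not in ("original", "filtered", "dmaps"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.metric not in ("mse", "mi"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.input_mode == "dmaps" and self.metric == "mi":
            raise ValueError("MI is never paired with delineation maps")
        if self.family == "rigid" and (self.input_mode != "original" or self.metric != "mse"):
            raise ValueError("the rigid baseline runs only as original + MSE")


def enumerate_methods(include_rigid: bool = True) -> list:
    """The method matrix in column order: rigid baseline, demons, FFD."""
    methods = []
    if include_rigid:
        methods.append(MethodSpec("rigid_mse", "rigid", "original", "mse"))
    for family in ("demons", "ffd"):
        methods.extend(
            [
                MethodSpec(f"{family}_mse", family, "original", "mse"),
                MethodSpec(f"{family}_mse_filtered", family, "filtered", "mse"),
                MethodSpec(f"{family}_mse_dmaps", family, "dmaps", "mse"),
                MethodSpec(f"{family}_mi", family, "original", "mi"),
                MethodSpec(f"{family}_mi_filtered", family, "filtered", "mi"),
            ]
        )
    return methods


@dataclass
class StudyData:
    """Everything one monitored course needs: planning + weekly inputs.

    ``weekly_landmarks`` plays the reference-expert role (ground truth on
    phantoms); ``weekly_labels`` provide both the delineation-map inputs
    and the contours whose propagation is scored by Dice.
    """

    planning_image: Volume
    planning_labels: Volume
    planning_landmarks: LandmarkSet
    weekly_images: list
    weekly_labels: list
    weekly_landmarks: list
    weekly_doses: list           # per-fraction dose grids, Gy
    planned_dose: DoseGrid | None = None
    truth_fields: list | None = None
    patient: int = 0

    @property
    def weeks(self) -> int:
        return len(self.weekly_images)


def phantom_study(spec: PhantomSpec | None = None) -> StudyData:
    """Generate a complete synthetic course as study input."""
    spec = spec or PhantomSpec()
    planning = generate_planning_phantom(spec)
    weekly = generate_weekly_series(spec, planning)
    planned, fraction_doses = generate_dose(spec, planning)
    return StudyData(
        planning_image=planning.image,
        planning_labels=planning.labels,
        planning_landmarks=planning.landmarks,
        weekly_images=[w.image for w in weekly],
        weekly_labels=[w.truth.labels for w in weekly],
        weekly_landmarks=[w.truth.landmarks for w in weekly],
        weekly_doses=fraction_doses,
        planned_dose=planned,
        truth_fields=[w.truth.field for w in weekly],
    )


@dataclass
class StudyConfig:
    """Numerical defaults of the pipeline stages; all overridable."""

    rigid: RigidConfig = dfield(default_factory=RigidConfig)
    demons: DemonsConfig = dfield(default_factory=DemonsConfig)
    # piecewise-constant delineation maps lose their thin structures in a
    # pyramid; a single native-resolution level with a wider regulariser
    # works markedly better for them
    demons_dmaps: DemonsConfig = dfield(
        default_factory=lambda: DemonsConfig(sigma=1.5, levels=1, iterations=(250,))
    )
    ffd: FFDConfig = dfield(default_factory=FFDConfig)
    sigmoid: SigmoidParams = dfield(default_factory=SigmoidParams)
    fractions: int = 35
    weeks: list | None = None          # 1-based subset, None = all
    dsc_structures: tuple = (2, 3, 4, 5)  # label codes scored by Dice
    seed: int = 0

    def to_manifest(self) -> dict:
        def plain(obj):
            if hasattr(obj, "__dataclass_fields__"):
                return {k: plain(getattr(obj, k)) for k in obj.__dataclass_fields__}
            if isinstance(obj, (list, tuple)):
                return [plain(x) for x in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return obj

        d = plain(self)
        d["config_hash"] = hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
        return d


@dataclass
class StudyReport:
    landmark_table: pd.DataFrame   # method, patient, week, landmark, tissue, error_mm
    dsc_table: pd.DataFrame        # method, patient, week, structure, dsc
    dose_table: pd.DataFrame       # method, patient, landmark, dose_error_gy, ...
    parotid_dose_table: pd.DataFrame
    comparisons: object
    manifest: dict

    def accuracy_precision(self, method: str):
        sub = self.landmark_table[self.landmark_table["method"] == method]
        return accuracy_precision(sub.rename(columns={"error_mm": "error"}))

    def dose_accuracy_precision(self, method: str):
        sub = self.dose_table[self.dose_table["method"] == method]
        return float(sub["dose_error_gy"].mean()), float(sub["dose_error_gy"].std(ddof=1))

    def mean_dsc(self, method: str) -> float:
        sub = self.dsc_table[self.dsc_table["method"] == method]
        return float(sub["dsc"].mean())

    def summary(self) -> str:
        lines = ["Dose-monitoring study report", "=" * 32]
        lines.append(f"{'method':<22}{'acc mm':>8}{'prec mm':>9}{'DSC':>7}{'dose acc Gy':>13}")
        for m in self.landmark_table["method"].unique():
            acc, prec = self.accuracy_precision(m)
            dacc, _ = self.dose_accuracy_precision(m)
            lines.append(
                f"{m:<22}{acc:>8.2f}{prec:>9.2f}{self.mean_dsc(m):>7.3f}{dacc:>13.2f}"
            )
        return "\n".join(lines)

    def to_dir(self, path) -> None:
        import os

        os.makedirs(path, exist_ok=True)
        self.landmark_table.to_csv(os.path.join(path, "landmark_errors.csv"), index=False)
        self.dsc_table.to_csv(os.path.join(path, "dsc.csv"), index=False)
        self.dose_table.to_csv(os.path.join(path, "dose_errors.csv"), index=False)
        self.parotid_dose_table.to_csv(os.path.join(path, "parotid_mean_dose.csv"), index=False)
        if self.comparisons is not None:
            self.comparisons.p_adjusted.to_csv(os.path.join(path, "pairwise_p_adjusted.csv"))
        with open(os.path.join(path, "manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def _labelmap_as_image(labels: Volume) -> Volume:
    """Delineation map reinterpreted as registration intensities."""
    return Volume(labels.voxels, labels.spacing, labels.origin, "unitless")


def _compose_rigid(dir_field: VectorField, transform: RigidTransform) -> VectorField:
    """Total planning->week map p -> T(p + u(p)) as one dense field."""
    pts = dir_field.grid_points()
    moved = transform.apply((pts + dir_field.displacements).reshape(-1, 3)).reshape(pts.shape)
    return VectorField(moved - pts, spacing=dir_field.spacing, origin=dir_field.origin)


def _method_inputs(method, planning_img, weekly_img, planning_labels, weekly_labels, cfg):
    if method.input_mode == "original":
        return planning_img, weekly_img
    if method.input_mode == "filtered":
        return sigmoid_filter(planning_img, cfg.sigmoid), sigmoid_filter(weekly_img, cfg.sigmoid)
    return _labelmap_as_image(planning_labels), _labelmap_as_image(weekly_labels)


def _register(method: MethodSpec, fixed: Volume, moving: Volume, cfg: StudyConfig, seed: int):
    if method.family == "demons":
        base = cfg.demons_dmaps if method.input_mode == "dmaps" else cfg.demons
        dc = replace(base, force="mi" if method.metric == "mi" else "intensity")
        return demons_register(fixed, moving, dc).field
    fc = replace(cfg.ffd, metric=method.metric, seed=seed)
    return ffd_register(fixed, moving, fc).field


def run_study(
    data: StudyData,
    methods: list | None = None,
    config: StudyConfig | None = None,
    compare: bool = True,
) -> StudyReport:
    """Run the full monitoring pipeline over the method matrix.

    Returns per-method landmark-error, Dice, cumulated-dose and parotid
    mean-dose tables plus pairwise comparisons and a provenance manifest.
    """
    cfg = config or StudyConfig()
    methods = methods if methods is not None else enumerate_methods()
    weeks = cfg.weeks or list(range(1, data.weeks + 1))
    missing = [w for w in weeks if not (1 <= w <= data.weeks)]
    if missing:
        raise ValueError(f"weeks {missing} not present in the study data")

    plan_img = data.planning_image
    cat = data.planning_landmarks
    scale = cfg.fractions / len(weeks)  # per-fraction -> course scale

    # rigid pre-alignment once per week, shared by every method
    pre = {}
    for w in weeks:
        wk = data.weekly_images[w - 1]
        rigid_res = register_rigid(plan_img, wk, cfg.rigid)
        t = rigid_res.transform
        rigid_field = rigid_to_field(t, plan_img)
        pre[w] = {
            "transform": t,
            "field": rigid_field,
            "image": warp_volume(wk, rigid_field),
            "labels": warp_labels(data.weekly_labels[w - 1], rigid_field),
        }

    lm_rows, dsc_rows, dose_rows, pg_rows = [], [], [], []
    parotid_codes = {2: "parotid_r", 3: "parotid_l"}

    for method in methods:
        fields = {}
        for w in weeks:
            if method.family == "rigid":
                total = pre[w]["field"]
            else:
                fixed_in, moving_in = _method_inputs(
                    method, plan_img, pre[w]["image"],
                    data.planning_labels, pre[w]["labels"], cfg,
                )
                seed = int(
                    hashlib.sha256(f"{cfg.seed}|{method.name}|{w}".encode()).hexdigest()[:7],
                    16,
                )
                dir_field = _register(method, fixed_in, moving_in, cfg, seed)
                total = _compose_rigid(dir_field, pre[w]["transform"])
            fields[w] = total

            est = propagate_landmarks(cat, total)
            err = landmark_errors(data.weekly_landmarks[w - 1], est)
            for idx, e in err.items():
                pos = int(np.where(cat.indices == idx)[0][0])
                lm_rows.append(
                    {
                        "method": method.name,
                        "patient": data.patient,
                        "week": w,
                        "landmark": int(idx),
                        "tissue": cat.tissues[pos],
                        "error_mm": float(e),
                    }
                )
            warped = warp_labels(data.weekly_labels[w - 1], total)
            for code in cfg.dsc_structures:
                plan_mask = (data.planning_labels.voxels.astype(int) == code).astype(float)
                wk_mask = (warped.voxels.astype(int) == code).astype(float)
                dsc_rows.append(
                    {
                        "method": method.name,
                        "patient": data.patient,
                        "week": w,
                        "structure": int(code),
                        "dsc": dsc(plan_mask, wk_mask),
                    }
                )

        # cumulated landmark dose: reference (expert/ground-truth positions)
        # versus the method's propagated positions
        doses = [data.weekly_doses[w - 1] for w in weeks]
        ref_pos = [data.weekly_landmarks[w - 1] for w in weeks]
        est_pos = [propagate_landmarks(cat, fields[w]) for w in weeks]
        ref_dose = cumulated_dose_at_landmarks(doses, ref_pos) * scale
        est_dose = cumulated_dose_at_landmarks(doses, est_pos) * scale
        for idx in ref_dose.index:
            dose_rows.append(
                {
                    "method": method.name,
                    "patient": data.patient,
                    "landmark": int(idx),
                    "reference_dose_gy": float(ref_dose[idx]),
                    "estimated_dose_gy": float(est_dose[idx]),
                    "dose_error_gy": float(abs(ref_dose[idx] - est_dose[idx])),
                }
            )

        # mean parotid dose: planned vs cumulated through the method fields
        warped_doses = [warp_dose(data.weekly_doses[w - 1], fields[w]) for w in weeks]
        cum = accumulate(warped_doses, weights=[scale] * len(weeks))
        for code, organ in parotid_codes.items():
            mask = (data.planning_labels.voxels.astype(int) == code).astype(float)
            if mask.sum() == 0:
                continue
            row = {
                "method": method.name,
                "patient": data.patient,
                "structure": organ,
                "cumulated_mean_gy": mean_dose(cum, mask),
            }
            if data.planned_dose is not None:
                row["planned_mean_gy"] = mean_dose(data.planned_dose, mask)
            pg_rows.append(row)

    lm_table = pd.DataFrame(lm_rows)
    comparisons = None
    if compare and len(methods) >= 2:
        comparisons = compare_methods(lm_table)

    manifest = {
        "config": cfg.to_manifest(),
        "methods": [m.name for m in methods],
        "weeks": weeks,
        "patient": data.patient,
        "versions": _versions(),
    }
    return StudyReport(
        lm_table,
        pd.DataFrame(dsc_rows),
        pd.DataFrame(dose_rows),
        pd.DataFrame(pg_rows),
        comparisons,
        manifest,
    )


def _versions() -> dict:
    import scipy

    from . import __version__

    return {"doseacc": __version__, "numpy": np.__version__, "scipy": scipy.__version__, "pandas": pd.__version__}
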