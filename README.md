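# doseacc

Deformable image registration and dose accumulation for longitudinal CT
monitoring in head-and-neck radiotherapy.

During a 7-week radiotherapy course the anatomy drifts — parotid glands
shrink by roughly a quarter of their volume, the neck thins by several
millimetres — so the dose actually delivered, fraction after fraction, no
longer matches the plan, and organs at risk near steep dose gradients can
be silently overdosed.  Deciding whether to replan requires *dose
monitoring*: estimate, for each weekly CT, the deformation back to the
planning CT, pull the weekly dose through it, and sum.  `doseacc` is a
reusable implementation of that pipeline for medical-physics and
image-analysis researchers who want to study how the *choice of
registration method* propagates into the cumulated dose.

## What is inside

* **Registration methods** — the classical matrix of
  family × preprocessing × metric:
  * rigid six-parameter MSE pre-alignment (also the baseline method);
  * demons: dense field from Thirion's normalised force
    `u += (f−m)∇f / (‖∇f‖² + (f−m)²)`, Gaussian-regularised (σ = 1
    voxel), three pyramid levels;
  * B-spline free-form deformation on a 30/20/10/5 mm control grid with a
    stochastic optimiser using the adaptive gain law `a/(k+A)^α`
    (a = 10⁴, A = 51, α = 0.602);
  * inputs: original CTs, sigmoid-filtered CTs
    (`I′ = (Max−Min)·σ((I−β)/α) + Min`, α = 100 HU, β = 0 HU), or
    delineation maps (skin 1, parotids 2/3, brain stem 4, cord 5);
  * metrics: MSE or mutual information (realised as joint-histogram
    intensity remapping; see `docs/methods.md`).
  Eleven valid combinations: 10 deformable methods plus the rigid
  baseline.
* **Dose accumulation** — trilinear pull-back of weekly dose grids onto
  the planning anatomy, voxelwise summation, DVH curves and
  DVH-difference export.
* **Evaluation** — Dice overlap of propagated contours, landmark
  registration error (accuracy = mean error, precision = mean
  per-landmark SD), cumulated dose at 14 anatomical landmarks
  (7 bony, 7 soft tissue), mean parotid dose, and exact paired sign tests
  with Holm correction for all method pairs.
* **Synthetic course generator** — a head-and-neck phantom with known
  ground truth: planning CT plus weekly CTs with calibrated parotid
  volume loss (28.3% course total), neck thinning (7.9 mm), residual
  setup offsets, and a planning-only contrast-agent enhancement; analytic
  70 Gy dose with a 5 Gy/mm gradient abutting one parotid.

## Worked example

```python
from doseacc import PhantomSpec, StudyConfig, phantom_study, run_study, enumerate_methods

spec = PhantomSpec(seed=7, weeks=2)          # a short two-week course
data = phantom_study(spec)

methods = [m for m in enumerate_methods() if m.name in ("rigid_mse", "demons_mi_filtered")]
report = run_study(data, methods=methods, config=StudyConfig(), compare=False)
print(report.summary())
```

prints

```
Dose-monitoring study report
================================
method                  acc mm  prec mm    DSC  dose acc Gy
rigid_mse                 1.73     0.84  0.771         1.69
demons_mi_filtered        1.21     0.43  0.820         0.94
```

Reading it: against the known ground truth, rigid alignment alone leaves
a mean landmark error of 1.73 mm and a mean Dice overlap of 0.771, which
translates into a 1.69 Gy mean error in the cumulated dose at the
landmarks; MI-driven demons on filtered CTs halves the dose error.  The
per-parotid table shows why monitoring matters — the gland abutting the
target accumulates more than planned as it shrinks toward the target:

```
            method  patient structure  cumulated_mean_gy  planned_mean_gy
         rigid_mse        0 parotid_l              14.29            11.89
demons_mi_filtered        0 parotid_l              22.10            11.89
```

(the spread between methods is exactly the registration-induced
uncertainty of the cumulated-dose estimate).

The same pipeline runs from the shell:

```
doseacc phantom --out course/ --seed 7
doseacc run --data course/ --methods all --out report/
```

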