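"""Geometric and dosimetric scoring of registration methods.

Terminology follows the adaptive-radiotherapy evaluation convention:

* *landmark registration error* - 3-D Euclidean distance between a
  reference landmark position and the position propagated by a method;
* *accuracy* - the mean error over all observations;
* *precision* - the mean, over landmarks, of the per-landmark sample
  standard deviation of the error (across patients and weeks);
* *cumulated landmark dose* - the sum over weeks of the weekly dose
  sampled at that week's landmark position.

``compare_methods`` runs paired location tests (exact sign test by
default, Wilcoxon optionally) on per-(patient, week, landmark) error
differences for every method pair, with Holm correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .core_image import VectorField, sample_volume

__all__ = [
    "LandmarkSet",
    "load_landmark_catalog",
    "propagate_landmarks",
    "landmark_errors",
    "accuracy_precision",
    "cumulated_dose_at_landmarks",
    "DoseErrorResult",
    "cumulated_dose_error",
    "MethodComparison",
    "compare_methods",
]


def load_landmark_catalog() -> pd.DataFrame:
    """The default 14-entry landmark catalog (7 bone + 7 soft tissue)."""
    text = resources.files("doseacc.data").joinpath("landmark_catalog.json").read_text()
    return pd.DataFrame(json.loads(text))


@dataclass
class LandmarkSet:
    """Named 3-D points (mm) with unique indices and a tissue class."""

    indices: np.ndarray          # (n,) int
    names: list
    tissues: list                # "bone" | "soft"
    positions: np.ndarray        # (n, 3) mm

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        n = len(self.indices)
        if len(set(self.indices.tolist())) != n:
            raise ValueError("landmark indices must be unique")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (n, 3)")
        if not set(self.tissues) <= {"bone", "soft"}:
            raise ValueError("tissue class must be 'bone' or 'soft'")

    def __len__(self):
        return len(self.indices)

    @classmethod
    def from_catalog(cls, positions: np.ndarray, catalog: pd.DataFrame | None = None) -> "LandmarkSet":
        cat = catalog if catalog is not None else load_landmark_catalog()
        return cls(
            cat["index"].to_numpy(),
            cat["name"].tolist(),
            cat["tissue"].tolist(),
            positions,
        )

    def with_positions(self, positions: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(self.indices.copy(), list(self.names), list(self.tissues), positions)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": self.indices,
                "name": self.names,
                "tissue": self.tissues,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LandmarkSet":
        return cls(
            df["index"].to_numpy(),
            df["name"].tolist(),
            df["tissue"].tolist(),
            df[["x_mm", "y_mm", "z_mm"]].to_numpy(),
        )


def propagate_landmarks(lms: LandmarkSet, fld: VectorField) -> LandmarkSet:
    """Move each landmark by the trilinearly interpolated field displacement."""
    return lms.with_positions(lms.positions + fld.sample(lms.positions))


def _aligned(reference: LandmarkSet, estimated: LandmarkSet):
    if not np.array_equal(np.sort(reference.indices), np.sort(estimated.indices)):
        raise ValueError("landmark sets carry different indices")
    order_ref = np.argsort(reference.indices)
    order_est = np.argsort(estimated.indices)
    return (
        reference.indices[order_ref],
        reference.positions[order_ref],
        estimated.positions[order_est],
    )


def landmark_errors(reference: LandmarkSet, estimated: LandmarkSet) -> pd.Series:
    """Per-landmark Euclidean distance (mm), indexed by landmark index."""
    idx, rp, ep = _aligned(reference, estimated)
    return pd.Series(np.linalg.norm(rp - ep, axis=1), index=idx, name="error_mm")


def accuracy_precision(errors, group: str = "landmark", accuracy_over: str = "cells"):
    """Mean error and mean per-group sample SD of an error table.

    Parameters
    ----------
    errors : DataFrame with columns [group, "error"] or mapping group -> array
    group : grouping column for the precision SDs (default per landmark)
    accuracy_over : "cells" averages every observation (default);
        "groups" averages the per-group means first.

    Returns ``(accuracy, precision)``; precision is NaN when every group is
    a singleton (SD undefined).
    """
    if isinstance(errors, dict):
        frames = [pd.DataFrame({group: k, "error": np.asarray(v, float)}) for k, v in errors.items()]
        df = pd.concat(frames, ignore_index=True)
    else:
        df = errors.rename(columns=lambda c: c)
    if "error" not in df.columns:
        raise ValueError("expected an 'error' column")
    grouped = df.groupby(group)["error"]
    if accuracy_over == "cells":
        accuracy = float(df["error"].mean())
    elif accuracy_over == "groups":
        accuracy = float(grouped.mean().mean())
    else:
        raise ValueError("accuracy_over must be 'cells' or 'groups'")
    sds = grouped.std(ddof=1).dropna()
    precision = float(sds.mean()) if len(sds) else float("nan")
    return accuracy, precision


def cumulated_dose_at_landmarks(weekly_doses: list, weekly_positions: list) -> pd.Series:
    """Sum over weeks of the trilinear dose sample at each week's position.

    ``weekly_doses[i]`` is the dose grid of week i and ``weekly_positions[i]``
    the landmark set on that week's anatomy.  Positions outside a dose grid
    contribute the zero-dose fill.
    """
    if len(weekly_doses) != len(weekly_positions):
        raise ValueError("need one landmark set per weekly dose")
    ref = weekly_positions[0]
    total = np.zeros(len(ref))
    for dose, lms in zip(weekly_doses, weekly_positions):
        if not np.array_equal(np.sort(lms.indices), np.sort(ref.indices)):
            raise ValueError("weekly landmark sets carry different indices")
        order = np.argsort(lms.indices)
        total += sample_volume(dose, lms.positions[order], fill=0.0)
    return pd.Series(total, index=np.sort(ref.indices), name="dose_gy")


@dataclass
class DoseErrorResult:
    errors: pd.Series     # absolute per-landmark dose difference, Gy
    accuracy: float       # mean absolute difference
    precision: float      # sample SD of the differences

    def summary(self) -> str:
        return (
            "Cumulated landmark dose error\n"
            f"  accuracy  [Gy]: {self.accuracy:.3f}\n"
            f"  precision [Gy]: {self.precision:.3f}\n"
            f"  worst landmark: {int(self.errors.idxmax())} ({self.errors.max():.3f} Gy)"
        )


def cumulated_dose_error(reference: pd.Series, estimated: pd.Series) -> DoseErrorResult:
    """Absolute per-landmark cumulated-dose differences with accuracy/precision."""
    if not np.array_equal(np.sort(reference.index), np.sort(estimated.index)):
        raise ValueError("landmark indices mismatch")
    est = estimated.reindex(reference.index)
    err = (reference - est).abs()
    err.name = "dose_error_gy"
    precision = float(err.std(ddof=1)) if len(err) > 1 else float("nan")
    return DoseErrorResult(err, float(err.mean()), precision)


@dataclass
class MethodComparison:
    """Pairwise paired-test results over a matched error table."""

    p_one_sided: pd.DataFrame   # P[row worse-or-equal]; tests "row < col"
    p_adjusted: pd.DataFrame    # Holm-adjusted one-sided p-values
    mean_errors: pd.Series
    alpha: float = 0.05
    better_pairs: list = field(default_factory=list)  # (A, B, p_adj): A < B

    def summary(self) -> str:
        lines = ["Pairwise method comparison (paired sign test, Holm-adjusted)"]
        lines.append("  mean errors:")
        for m, v in self.mean_errors.sort_values().items():
            lines.append(f"    {m}: {v:.3f}")
        if self.better_pairs:
            lines.append(f"  significant orderings (alpha={self.alpha}):")
            for a, b, p in self.better_pairs:
                lines.append(f"    {a} < {b}  (p_adj={p:.2e})")
        else:
            lines.append("  no significant orderings")
        return "\n".join(lines)


def _paired_p(diff: np.ndarray, test: str) -> float:
    """One-sided p-value for 'first method has lower error' (diff = a - b)."""
    nz = diff[diff != 0]
    if nz.size == 0:
        return 1.0
    if test == "sign":
        wins = int(np.sum(nz < 0))
        return float(stats.binomtest(wins, nz.size, 0.5, alternative="greater").pvalue)
    if test == "wilcoxon":
        return float(stats.wilcoxon(nz, alternative="less").pvalue)
    raise ValueError(f"unknown test {test!r}")


def compare_methods(
    table: pd.DataFrame,
    test: str = "sign",
    alpha: float = 0.05,
    error_col: str = "error_mm",
) -> MethodComparison:
    """All-pairs paired comparison of methods on a matched error table.

    ``table`` must hold one row per (method, patient, week, landmark) with
    the error in ``error_col``; every method must cover the same cells.
    For each ordered pair (A, B) the one-sided null "A's error is not
    lower than B's" is tested on the per-cell differences; Holm correction
    is applied across the ordered pairs.
    """
    from statsmodels.stats.multitest import multipletests

    methods = list(dict.fromkeys(table["method"]))
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    keys = ["patient", "week", "landmark"]
    wide = table.pivot_table(index=keys, columns="method", values=error_col)
    if wide.isna().any().any():
        raise ValueError("unmatched design: some methods miss cells")

    pairs, raw = [], []
    for a in methods:
        for b in methods:
            if a == b:
                continue
            diff = (wide[a] - wide[b]).to_numpy()
            pairs.append((a, b))
            raw.append(_paired_p(diff, test))
    adj = multipletests(raw, method="holm")[1]

    p1 = pd.DataFrame(np.ones((len(methods), len(methods))), index=methods, columns=methods)
    padj = p1.copy()
    better = []
    for (a, b), pr, pa in zip(pairs, raw, adj):
        p1.loc[a, b] = pr
        padj.loc[a, b] = pa
        if pa < alpha:
            better.append((a, b, float(pa)))
    return MethodComparison(p1, padj, wide.mean(axis=0), alpha, better)
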