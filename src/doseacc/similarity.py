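"""Voxel-similarity metrics and overlap scores.

``mse`` and ``mutual_information`` are the matching criteria driving the
registration modules; ``dsc`` is the Dice overlap used to score propagated
contours.  Mutual information uses a fixed-width joint histogram (64 bins
per image by default over each image's observed range) and natural-log
entropies, so it is reported in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_image import Volume

__all__ = ["JointHistogram", "joint_histogram", "mse", "mutual_information", "dsc"]


def _as_array(v) -> np.ndarray:
    return v.voxels if isinstance(v, Volume) else np.asarray(v, dtype=np.float64)


def _check_same_geometry(a, b):
    if isinstance(a, Volume) and isinstance(b, Volume):
        if not a.same_geometry(b):
            raise ValueError("volumes must share geometry")
    else:
        if _as_array(a).shape != _as_array(b).shape:
            raise ValueError("arrays must share shape")


def _considered(a, b, exclude_fill: bool):
    """Paired samples, optionally dropping voxels at either fill value."""
    av, bv = _as_array(a), _as_array(b)
    if exclude_fill:
        fa = a.fill_value if isinstance(a, Volume) else None
        fb = b.fill_value if isinstance(b, Volume) else None
        keep = np.ones(av.shape, dtype=bool)
        if fa is not None:
            keep &= av != fa
        if fb is not None:
            keep &= bv != fb
        if keep.any():
            return av[keep], bv[keep]
    return av.ravel(), bv.ravel()


@dataclass
class JointHistogram:
    """Joint intensity counts of two images on a fixed-width binning."""

    counts: np.ndarray  # (bins_a, bins_b)
    edges_a: np.ndarray
    edges_b: np.ndarray

    @property
    def n(self) -> float:
        return float(self.counts.sum())

    def probabilities(self) -> np.ndarray:
        return self.counts / self.n


def joint_histogram(a, b, bins: int = 64, exclude_fill: bool = False) -> JointHistogram:
    if bins < 2:
        raise ValueError("bins must be >= 2")
    _check_same_geometry(a, b)
    av, bv = _considered(a, b, exclude_fill)
    counts, ea, eb = np.histogram2d(av, bv, bins=bins)
    return JointHistogram(counts, ea, eb)


def mse(a, b, exclude_fill: bool = True) -> float:
    """Mean squared intensity difference over the considered voxels."""
    _check_same_geometry(a, b)
    av, bv = _considered(a, b, exclude_fill)
    return float(np.mean((av - bv) ** 2))


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def mutual_information(a, b, bins: int = 64, exclude_fill: bool = False) -> float:
    """Image-level mutual information in nats, ``H(A) + H(B) - H(A, B)``.

    Computed from the empirical joint histogram over the voxel population.
    A constant image collapses to a single occupied bin and yields 0.
    """
    h = joint_histogram(a, b, bins=bins, exclude_fill=exclude_fill)
    p = h.probabilities()
    mi = _entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0)) - _entropy(p.ravel())
    return max(mi, 0.0)


def dsc(a, b) -> float:
    """Dice similarity coefficient ``2|A n B| / (|A| + |B|)`` of two masks.

    Accepts boolean arrays, {0,1} arrays, or label volumes already reduced
    to a single structure.  Two empty masks count as perfect overlap (1).
    """
    _check_same_geometry(a, b)
    av, bv = _as_array(a), _as_array(b)
    for v in (av, bv):
        vals = np.unique(v)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValueError("dsc expects binary masks (values 0/1)")
    na, nb = av.sum(), bv.sum()
    if na == 0 and nb == 0:
        return 1.0
    shared = np.logical_and(av > 0, bv > 0).sum()
    return float(2.0 * shared / (na + nb))
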