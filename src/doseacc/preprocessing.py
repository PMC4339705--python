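"""Image conditioning before registration.

Two conditioners are provided:

* a logistic (sigmoid) intensity filter that stretches the soft-tissue HU
  band into the full output window, de-emphasising the very high contrast
  of bone and air so that similarity metrics respond to soft tissue;
* delineation maps, label images with one fixed code per segmented
  structure, used to drive registration directly from contours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_image import Volume

__all__ = [
    "SigmoidParams",
    "sigmoid_filter",
    "DELINEATION_CODES",
    "make_delineation_map",
]

#: Structure -> code used in delineation maps.  Background is 0.
DELINEATION_CODES = {
    "skin": 1,
    "parotid_r": 2,
    "parotid_l": 3,
    "brainstem": 4,
    "cord": 5,
}


@dataclass
class SigmoidParams:
    """Logistic intensity mapping parameters.

    ``alpha`` is the HU width of the transition band, ``beta`` its centre;
    output intensities are confined to the open interval
    (``out_min``, ``out_max``).  With ``ascending=True`` (the default) the
    mapping is monotonically increasing, the conventional soft-tissue
    enhancement; ``ascending=False`` selects the intensity-reversing
    orientation with ``exp(+(I - beta)/alpha)`` in the denominator.
    """

    alpha: float = 100.0
    beta: float = 0.0
    out_min: float = -1024.0
    out_max: float = 2976.0
    ascending: bool = True

    def __post_init__(self):
        if self.alpha == 0:
            raise ValueError("alpha must be nonzero")
        if not self.out_max > self.out_min:
            raise ValueError("out_max must exceed out_min")


def sigmoid_filter(vol: Volume, params: SigmoidParams | None = None) -> Volume:
    """Voxelwise logistic remapping of a HU volume.

    ``I' = (Max - Min) / (1 + exp(-+ (I - beta)/alpha)) + Min`` with the sign
    of the exponent set by ``params.ascending``.
    """
    p = params or SigmoidParams()
    t = (vol.voxels - p.beta) / p.alpha
    if p.ascending:
        t = -t
    out = (p.out_max - p.out_min) / (1.0 + np.exp(t)) + p.out_min
    return vol.with_voxels(out)


def make_delineation_map(masks: dict) -> Volume:
    """Combine named binary masks into a single coded label volume.

    Parameters
    ----------
    masks : dict
        Maps structure names from :data:`DELINEATION_CODES` to binary
        :class:`Volume` objects sharing one geometry.

    Voxels covered by several masks take the highest applicable code, so
    organ codes (2-5) override the skin code (1).
    """
    unknown = set(masks) - set(DELINEATION_CODES)
    if unknown:
        raise ValueError(f"unknown structure names: {sorted(unknown)}")
    if not masks:
        raise ValueError("at least one mask is required")
    vols = list(masks.values())
    ref = vols[0]
    for v in vols[1:]:
        if not ref.same_geometry(v):
            raise ValueError("delineation masks must share one geometry")
    out = np.zeros(ref.shape)
    for name, code in sorted(DELINEATION_CODES.items(), key=lambda kv: kv[1]):
        if name in masks:
            out[masks[name].voxels > 0.5] = code
    return Volume(out, spacing=ref.spacing, origin=ref.origin, unit="label")
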