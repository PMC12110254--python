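"""A single 3D local-binary-pattern summary of the quantized ROI.

For every in-ROI voxel with at least one in-ROI neighbor in the cubic
26-neighborhood at the given radius, the fraction of neighbors whose
quantized level strictly exceeds the center level is computed; the feature
is the mean of these fractions over the ROI.  A homogeneous region scores 0,
a region dominated by fine local contrast approaches 0.5.
"""

from __future__ import annotations

import numpy as np

from .quantize import QuantizedROI
from .texture import DIRECTIONS_3D, _shift


def lbp_feature(q: QuantizedROI, radius: int = 1) -> dict[str, float]:
    lv = q.levels
    mask = q.mask
    above = np.zeros(lv.shape, dtype=np.int64)
    count = np.zeros(lv.shape, dtype=np.int64)
    offsets = [tuple(radius * c for c in d) for d in DIRECTIONS_3D]
    offsets += [tuple(-o for o in off) for off in offsets]
    for off in offsets:
        nb_lv = _shift(lv, off)
        nb_ok = _shift(mask.astype(np.int8), off).astype(bool)
        valid = mask & nb_ok
        above[valid] += (nb_lv[valid] > lv[valid]).astype(np.int64)
        count[valid] += 1
    has_nb = mask & (count > 0)
    if not has_nb.any():
        return {"AboveCenterFraction": float("nan")}
    frac = above[has_nb] / count[has_nb]
    return {"AboveCenterFraction": float(frac.mean())}
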