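"""Per-study feature extraction: 144 features per (sequence, region) pair.

``extract_pair`` computes the nine families for one sequence/region
combination; ``extract_study`` assembles the full 4752-entry vector over the
11 sequences and 3 subregions, and ``extract_cohort`` stacks studies into a
cohort table with subject ids and labels.

In strict mode a missing sequence or an empty region aborts extraction; in
permissive mode the affected features become NaN sentinels and the problem
is logged.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ..study import MultiParametricStudy
from . import texture
from .firstorder import histogram_features, intensity_features
from .lbp import lbp_feature
from .manifest import (
    FAMILIES,
    FAMILY_FEATURES,
    REGIONS,
    SEQUENCES,
    feature_name,
    full_feature_names,
)
from .quantize import EmptyRegionError, quantize_roi
from .shape import morphology_features, volumetric_features

logger = logging.getLogger(__name__)


def extract_pair(
    volume: np.ndarray,
    mask: np.ndarray,
    region_code: int,
    spacing=(1.0, 1.0, 1.0),
    bins: int = 16,
    radius: int = 1,
) -> dict[str, float]:
    """All 144 family features (bare names) for one volume/region pair."""
    q = quantize_roi(volume, mask, region_code, bins=bins, spacing=spacing)
    voxel_vol = float(np.prod([float(s) for s in spacing]))

    values: dict[str, dict[str, float]] = {
        "INTENSITY": intensity_features(q.roi_values, voxel_vol),
        "HISTOGRAM": histogram_features(q),
        "VOLUMETRIC": volumetric_features(mask, region_code, spacing),
        "MORPHOLOGY": morphology_features(mask, region_code, spacing),
        "GLCM": texture.glcm_features(texture.glcm_matrix(q, radius=radius)),
        "GLRLM": texture.glrlm_features(q),
        "GLSZM": texture.glszm_features(q),
        "NGTDM": texture.ngtdm_features(q, radius=radius),
        "LBP": lbp_feature(q, radius=radius),
    }

    out: dict[str, float] = {}
    for family in FAMILIES:
        fam_vals = values[family]
        for feat in FAMILY_FEATURES[family]:
            out[f"{family}::{feat}"] = fam_vals[feat]
    return out


def extract_study(
    study: MultiParametricStudy,
    bins: int = 16,
    radius: int = 1,
    strict: bool = True,
) -> pd.Series:
    """The ordered 4752-entry feature vector of one subject.

    Ordered by (sequence, region, family, feature) with manifest-dialect
    names, e.g. ``DSC_PSR_ET_GLCM_Bins.16_Radius.1_Contrast``.
    """
    problems = study.validate(strict=strict)
    for p in problems:
        logger.warning("study %s: %s", study.subject_id, p)

    out: dict[str, float] = {}
    for seq in SEQUENCES:
        vol = study.volumes.get(seq)
        for region in REGIONS:
            code = study.region_codes[region]
            try:
                if vol is None:
                    raise EmptyRegionError(f"sequence {seq} missing")
                pair = extract_pair(
                    vol, study.mask, code, study.spacing, bins=bins, radius=radius
                )
            except (EmptyRegionError, ValueError) as exc:
                if strict:
                    raise
                logger.warning(
                    "study %s, %s/%s: %s — emitting NaN sentinels",
                    study.subject_id,
                    seq,
                    region,
                    exc,
                )
                pair = {
                    f"{fam}::{feat}": float("nan")
                    for fam in FAMILIES
                    for feat in FAMILY_FEATURES[fam]
                }
            for key, val in pair.items():
                family, feat = key.split("::", 1)
                out[feature_name(seq, region, family, feat, bins, radius)] = val

    expected = full_feature_names(bins, radius)
    vec = pd.Series(out, name=study.subject_id).reindex(expected)
    assert len(vec) == 144 * len(SEQUENCES) * len(REGIONS)
    return vec


def extract_cohort(
    studies: list[MultiParametricStudy],
    bins: int = 16,
    radius: int = 1,
    strict: bool = True,
) -> pd.DataFrame:
    """Cohort feature table: one row per subject, first column ``label``."""
    rows = [extract_study(s, bins=bins, radius=radius, strict=strict) for s in studies]
    df = pd.DataFrame(rows)
    df.index.name = "subject_id"
    labels = pd.Series(
        {s.subject_id: s.label for s in studies}, name="label", dtype="Int64"
    )
    df.insert(0, "label", labels)
    return df
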