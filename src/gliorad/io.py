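"""File formats: NIfTI studies, CSV feature tables, JSON configs.

One subject's study is stored as one NIfTI volume per sequence
(``<subject>_<SEQ>.nii``) plus one integer mask (``<subject>_mask.nii``);
the cohort label table is a two-column CSV (subject_id, label).  Feature
tables are CSV with subject_id as index, a leading ``label`` column and the
manifest-ordered feature columns, written with 12 significant digits so a
round trip is lossless at that precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .features.manifest import DEFAULT_REGION_CODES, SEQUENCES
from .study import MultiParametricStudy

CSV_FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# NIfTI studies
# ---------------------------------------------------------------------------

def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def write_study(study: MultiParametricStudy, out_dir: str | Path) -> list[Path]:
    """Write one NIfTI per sequence plus the mask; returns written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    aff = _affine(study.spacing)
    written = []
    for seq, vol in study.volumes.items():
        path = out_dir / f"{study.subject_id}_{seq}.nii"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), aff), path)
        written.append(path)
    mask_path = out_dir / f"{study.subject_id}_mask.nii"
    nib.save(nib.Nifti1Image(study.mask.astype(np.int16), aff), mask_path)
    written.append(mask_path)
    return written


def read_study(
    subject_id: str,
    in_dir: str | Path,
    label: int | None = None,
    region_codes: dict[str, int] | None = None,
    strict: bool = True,
) -> MultiParametricStudy:
    """Load a study written by :func:`write_study`, validating grid alignment,
    sequence coverage and mask label codes."""
    in_dir = Path(in_dir)
    mask_path = in_dir / f"{subject_id}_mask.nii"
    if not mask_path.exists():
        raise FileNotFoundError(f"mask file not found: {mask_path}")
    mask_img = nib.load(mask_path)
    mask = np.asarray(mask_img.dataobj).astype(np.int16)
    spacing = tuple(float(z) for z in mask_img.header.get_zooms()[:3])

    volumes = {}
    for seq in SEQUENCES:
        path = in_dir / f"{subject_id}_{seq}.nii"
        if not path.exists():
            if strict:
                raise FileNotFoundError(
                    f"missing sequence {seq} for {subject_id}: {path}"
                )
            continue
        img = nib.load(path)
        vol = np.asarray(img.dataobj, dtype=np.float64)
        if vol.shape != mask.shape:
            raise ValueError(
                f"{path.name}: shape {vol.shape} does not match mask {mask.shape}"
            )
        vol_spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        if not np.allclose(vol_spacing, spacing):
            raise ValueError(
                f"{path.name}: spacing {vol_spacing} does not match mask {spacing}"
            )
        volumes[seq] = vol

    study = MultiParametricStudy(
        subject_id=subject_id,
        volumes=volumes,
        mask=mask,
        spacing=spacing,
        label=label,
        region_codes=dict(region_codes or DEFAULT_REGION_CODES),
    )
    study.validate(strict=strict)
    return study


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_labels(table: pd.DataFrame, path: str | Path) -> None:
    table[["subject_id", "label"]].to_csv(path, index=False)


def read_labels(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"subject_id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns subject_id, label")
    return df


def write_feature_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, float_format=CSV_FLOAT_FORMAT)


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="subject_id")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate feature columns")
    return df


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of a pipeline run."""

    bins: int = 16
    radius: int = 1
    region_codes: dict = field(default_factory=lambda: dict(DEFAULT_REGION_CODES))
    lasso_alpha: float = 0.05
    lasso_weight: float = 2.0
    mrmr_weight: float = 1.0
    weight_threshold: float = 3.0
    n_folds: int = 5
    mrmr_k: int = 100
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    seed: int = 0
    strict: bool = True
    threshold_mode: str = "search"
    selection_on_full_data: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]
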