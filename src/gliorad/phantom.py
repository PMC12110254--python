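"""Synthetic multiparametric imaging studies and tabular feature matrices.

The imaging phantom stands in for a glioma cohort: each subject carries 11
co-registered sequence volumes on a common grid and a three-label subregion
mask (necrotic core NCR inside an enhancing-tumor shell ET, surrounded by an
edema shell ED), built from nested ellipsoids with seeded per-subject jitter.
Class effects are injected per (sequence, region): a mean intensity shift,
and a texture effect obtained by mixing a smooth base field with a seeded
high-frequency noise component whose amplitude differs by class — the latter
raises local gray-level contrast (GLCM contrast, NGTDM contrast) without
preferring any direction.

The tabular generator plants a known informative set: the first
``n_informative`` columns separate the classes by a standardized mean
difference ``effect_size`` on unit-variance noise; all remaining columns are
pure noise.  Both generators are bit-reproducible under a fixed seed, with
per-subject substreams spawned from the master seed so results do not depend
on iteration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .features.manifest import DEFAULT_REGION_CODES, SEQUENCES
from .study import MultiParametricStudy

# Cohort composition mirrored by the default prevalence: 97 methylated of
# 146 subjects.
DEFAULT_PREVALENCE = 97.0 / 146.0

MIN_REGION_VOXELS = 8


@dataclass(frozen=True)
class EffectSpec:
    """Class-dependent effect on one (sequence, region) pair.

    mean_shift   — intensity offset (in noise-SD units) added for class 1.
    texture_shift — extra high-frequency noise amplitude (in noise-SD units)
                    for class 1; raises local contrast without direction.
    """

    sequence: str
    region: str
    mean_shift: float = 0.0
    texture_shift: float = 0.0


def default_effect_profile() -> tuple[EffectSpec, ...]:
    """Default study conditions: perfusion-weighted texture and enhancement
    differences concentrated in the enhancing tumor, plus a FLAIR edema shift."""
    return (
        EffectSpec("DSC_PSR", "ET", mean_shift=0.8, texture_shift=0.8),
        EffectSpec("DSC_rCBV", "ET", mean_shift=0.5, texture_shift=0.6),
        EffectSpec("T1Gd", "ET", mean_shift=0.5, texture_shift=0.0),
        EffectSpec("FLAIR", "ED", mean_shift=0.4, texture_shift=0.0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions of a synthetic imaging cohort."""

    grid_size: int = 48
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_subjects: int = 40
    class_prevalence: float = DEFAULT_PREVALENCE
    effect_profile: tuple[EffectSpec, ...] = field(
        default_factory=default_effect_profile
    )
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if not 0.0 < self.class_prevalence < 1.0:
            raise ValueError("class_prevalence must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_profile"] = [asdict(e) for e in self.effect_profile]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        d["effect_profile"] = tuple(
            EffectSpec(**e) for e in d.get("effect_profile", [])
        )
        d["voxel_spacing"] = tuple(d.get("voxel_spacing", (1.0, 1.0, 1.0)))
        return cls(**d)


@dataclass(frozen=True)
class TabularSpec:
    """Conditions of a synthetic tabular feature matrix."""

    n_subjects: int = 200
    n_features: int = 100
    n_informative: int = 5
    effect_size: float = 3.0
    correlation_within_informative: float = 0.0
    class_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.correlation_within_informative < 1.0:
            raise ValueError("correlation_within_informative must be in [0, 1)")
        if not 0.0 < self.class_prevalence < 1.0:
            raise ValueError("class_prevalence must be in (0, 1)")


@dataclass
class TabularDataset:
    """Planted feature matrix plus ground truth."""

    X: pd.DataFrame
    y: pd.Series
    informative: list[str]


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def cohort_labels(spec: PhantomSpec) -> np.ndarray:
    """Deterministic fixed-composition label vector.

    ``round(prevalence * n)`` positives, shuffled by the seeded stream —
    drawing without replacement from a fixed composition, so observed counts
    match the rounded prevalence exactly.
    """
    n = spec.n_subjects
    n_pos = int(round(spec.class_prevalence * n))
    labels = np.array([1] * n_pos + [0] * (n - n_pos), dtype=np.int64)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(2**20,)))
    return rng.permutation(labels)


def _subject_rng(spec: PhantomSpec, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(subject_index,))
    )


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return acc <= 1.0


def _build_mask(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Nested ellipsoids: NCR core, ET shell, ED surround (BraTS codes)."""
    g = spec.grid_size
    center = np.array([g / 2.0] * 3) + rng.uniform(-0.06 * g, 0.06 * g, size=3)
    jitter = rng.uniform(0.9, 1.1, size=3)
    r_ncr = 0.12 * g * jitter
    r_et = 0.20 * g * jitter
    r_ed = 0.30 * g * jitter

    core = _ellipsoid((g, g, g), center, r_ncr)
    et_ball = _ellipsoid((g, g, g), center, r_et)
    ed_ball = _ellipsoid((g, g, g), center, r_ed)

    mask = np.zeros((g, g, g), dtype=np.int16)
    mask[ed_ball] = DEFAULT_REGION_CODES["ED"]
    mask[et_ball] = DEFAULT_REGION_CODES["ET"]
    mask[core] = DEFAULT_REGION_CODES["NCR"]

    for region, code in DEFAULT_REGION_CODES.items():
        n = int((mask == code).sum())
        if n < MIN_REGION_VOXELS:
            raise ValueError(
                f"degenerate phantom: region {region} has {n} voxels "
                f"(< {MIN_REGION_VOXELS}); increase grid_size"
            )
    return mask


# baseline tissue contrast per sequence and region (arbitrary units);
# gives every sequence a distinct mean level and region ordering
_BASE_LEVEL = {seq: 10.0 + 2.0 * k for k, seq in enumerate(SEQUENCES)}
_REGION_OFFSET = {"NCR": -2.0, "ET": 3.0, "ED": 1.0}


def simulate_study(spec: PhantomSpec, subject_index: int) -> MultiParametricStudy:
    """One subject's 11 volumes + 3-label mask, bit-reproducible per seed."""
    if not 0 <= subject_index < spec.n_subjects:
        raise IndexError(
            f"subject_index {subject_index} out of range for n_subjects={spec.n_subjects}"
        )
    label = int(cohort_labels(spec)[subject_index])
    rng = _subject_rng(spec, subject_index)
    mask = _build_mask(spec, rng)
    g = spec.grid_size

    effects = {(e.sequence, e.region): e for e in spec.effect_profile}
    region_masks = {
        region: mask == code for region, code in DEFAULT_REGION_CODES.items()
    }

    volumes: dict[str, np.ndarray] = {}
    for seq in SEQUENCES:
        # Smooth anatomical background; normalized to SD = 2 noise_sd so it
        # dominates the ROI intensity range.  Texture effects then raise the
        # ratio of high-frequency to smooth variation, which is what the
        # quantized texture features (e.g. GLCM contrast) respond to.
        smooth = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (g, g, g)), sigma=3.0)
        sd = smooth.std()
        if sd > 0:
            smooth *= 2.0 * spec.noise_sd / sd
        vol = _BASE_LEVEL[seq] + smooth
        vol += rng.normal(0.0, 0.1 * spec.noise_sd, (g, g, g))  # scanner noise
        for region, rmask in region_masks.items():
            vol[rmask] += _REGION_OFFSET[region]
            eff = effects.get((seq, region))
            hf = rng.normal(0.0, 1.0, (g, g, g))  # high-frequency texture field
            base_amp = 0.15 * spec.noise_sd
            amp = base_amp
            if eff is not None and label == 1:
                amp = base_amp + eff.texture_shift * spec.noise_sd
            vol[rmask] += amp * hf[rmask]
            if eff is not None and label == 1:
                vol[rmask] += eff.mean_shift * spec.noise_sd
        volumes[seq] = vol.astype(np.float64)

    return MultiParametricStudy(
        subject_id=f"sub-{subject_index:04d}",
        volumes=volumes,
        mask=mask,
        spacing=spec.voxel_spacing,
        label=label,
    )


def simulate_cohort(spec: PhantomSpec) -> tuple[list[MultiParametricStudy], pd.DataFrame]:
    """All subjects plus the (subject_id, label) table."""
    studies = [simulate_study(spec, i) for i in range(spec.n_subjects)]
    table = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in studies],
            "label": [s.label for s in studies],
        }
    )
    return studies, table


# ---------------------------------------------------------------------------
# tabular generator
# ---------------------------------------------------------------------------

def simulate_feature_matrix(spec: TabularSpec) -> TabularDataset:
    """Planted-signal feature matrix with named columns and ground truth."""
    n, p, k = spec.n_subjects, spec.n_features, spec.n_informative
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    n_pos = int(round(spec.class_prevalence * n))
    y = rng.permutation(np.array([1] * n_pos + [0] * (n - n_pos), dtype=np.int64))

    X = rng.normal(0.0, 1.0, (n, p))
    if k > 0:
        rho = spec.correlation_within_informative
        if rho > 0.0:
            # equicorrelated informative block via a shared latent factor
            shared = rng.normal(0.0, 1.0, (n, 1))
            X[:, :k] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * X[:, :k]
        X[:, :k] += spec.effect_size * y[:, None]

    names = [f"F{j + 1:04d}" for j in range(p)]
    df = pd.DataFrame(X, columns=names)
    df.index = [f"sub-{i:04d}" for i in range(n)]
    df.index.name = "subject_id"
    return TabularDataset(
        X=df,
        y=pd.Series(y, index=df.index, name="label"),
        informative=names[:k],
    )
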