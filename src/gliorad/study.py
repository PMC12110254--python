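"""In-memory containers for one subject's multiparametric imaging study."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features.manifest import DEFAULT_REGION_CODES, SEQUENCES


@dataclass
class MultiParametricStudy:
    """One subject: co-registered volumes per sequence + subregion mask.

    All volumes and the mask share one voxel grid and spacing; nonzero mask
    labels identify the tumor subregions (default BraTS-style codes
    NCR=1, ED=2, ET=4).
    """

    subject_id: str
    volumes: dict[str, np.ndarray]
    mask: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    label: int | None = None  # 1 = methylated, 0 = unmethylated
    region_codes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_CODES)
    )

    def validate(self, strict: bool = True) -> list[str]:
        """Check grid alignment, sequence coverage and mask label codes.

        Returns the list of problems; raises in strict mode.
        """
        problems: list[str] = []
        shape = self.mask.shape
        for seq in SEQUENCES:
            if seq not in self.volumes:
                problems.append(f"missing sequence {seq}")
        for seq, vol in self.volumes.items():
            if seq not in SEQUENCES:
                problems.append(
                    f"unknown sequence name {seq!r}; valid names: {', '.join(SEQUENCES)}"
                )
            elif vol.shape != shape:
                problems.append(
                    f"sequence {seq} shape {vol.shape} does not match mask {shape}"
                )
            elif not np.isfinite(vol).all():
                problems.append(f"sequence {seq} contains non-finite values")
        allowed = set(self.region_codes.values()) | {0}
        observed = set(np.unique(self.mask).tolist())
        extra = observed - allowed
        if extra:
            problems.append(f"mask contains unexpected labels {sorted(extra)}")
        for region, code in self.region_codes.items():
            if not (self.mask == code).any():
                problems.append(f"region {region} (code {code}) is empty")
        if strict and problems:
            raise ValueError("; ".join(problems))
        return problems
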