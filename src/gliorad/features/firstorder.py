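"""First-order features: intensity statistics and histogram descriptors.

Intensity features are moments, order statistics and dispersion measures of
the raw ROI intensities; they are invariant to anything outside the mask.
The histogram family combines a fixed 32-bin normalized frequency profile of
the raw intensities with distribution statistics of the quantized gray
levels (1..B), so its values carry the ``Bins.<B>`` tag in the feature name.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .manifest import N_HISTOGRAM_BINS
from .quantize import QuantizedROI


def _safe_ratio(num: float, den: float, default: float = 0.0) -> float:
    return float(num / den) if den != 0 else default


def intensity_features(values: np.ndarray, voxel_volume: float = 1.0) -> dict[str, float]:
    """Twenty first-order statistics of the raw in-ROI intensities."""
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("intensity features require a non-empty region")
    mean = float(x.mean())
    median = float(np.median(x))
    var = float(x.var())
    sd = float(np.sqrt(var))
    p10, q25, q75, p90 = np.percentile(x, [10, 25, 75, 90])
    skew = float(stats.skew(x)) if var > 0 else 0.0
    kurt = float(stats.kurtosis(x)) if var > 0 else 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
    energy = float((x**2).sum())
    return {
        "Mean": mean,
        "Median": median,
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": energy,
        "TotalEnergy": float(voxel_volume * energy),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "MedianAbsoluteDeviation": float(np.median(np.abs(x - median))),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(q75 - q25),
        "CoefficientOfVariation": _safe_ratio(sd, abs(mean)),
        "QuartileCoefficientOfDispersion": _safe_ratio(q75 - q25, q75 + q25),
    }


def histogram_features(q: QuantizedROI) -> dict[str, float]:
    """Sixty-one histogram descriptors of the ROI.

    32 normalized bin frequencies over the raw intensity range, then 29
    statistics of the quantized gray-level distribution.
    """
    x = q.roi_values
    g = q.roi_levels.astype(float)
    if x.size == 0:
        raise ValueError("histogram features require a non-empty region")

    vmin, vmax = float(x.min()), float(x.max())
    if vmax > vmin:
        counts, _ = np.histogram(x, bins=N_HISTOGRAM_BINS, range=(vmin, vmax))
    else:  # constant ROI: all mass in the first bin
        counts = np.zeros(N_HISTOGRAM_BINS, dtype=int)
        counts[0] = x.size
    freqs = counts / counts.sum()

    out = {
        f"Bin.{i + 1:02d}Frequency": float(freqs[i]) for i in range(N_HISTOGRAM_BINS)
    }

    # discrete distribution of gray levels
    lvl_counts = np.bincount(q.roi_levels, minlength=q.bins + 1)[1:]
    p = lvl_counts / lvl_counts.sum()
    nz = p[p > 0]
    mean_g = float(g.mean())
    var_g = float(g.var())
    median_g = float(np.median(g))
    mode_level = int(np.argmax(lvl_counts)) + 1  # ties -> lowest level
    deciles = np.percentile(g, [10, 20, 30, 40, 50, 60, 70, 80, 90])
    q25, q75 = np.percentile(g, [25, 75])
    p10, p90 = deciles[0], deciles[8]
    robust = g[(g >= p10) & (g <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    out.update(
        {
            "Entropy": float(-(nz * np.log2(nz)).sum()),
            "Uniformity": float((p**2).sum()),
            "GrayLevelEnergy": float((g**2).sum()),
            "GrayLevelMean": mean_g,
            "GrayLevelVariance": var_g,
            "GrayLevelSkewness": float(stats.skew(g)) if var_g > 0 else 0.0,
            "GrayLevelKurtosis": float(stats.kurtosis(g)) if var_g > 0 else 0.0,
            "GrayLevelMedian": median_g,
            "GrayLevelMode": float(mode_level),
            "ModeProbability": float(p[mode_level - 1]),
            "GrayLevelMinimum": float(g.min()),
            "GrayLevelMaximum": float(g.max()),
            "GrayLevelRange": float(g.max() - g.min()),
            **{f"Decile.{10 * (i + 1)}": float(deciles[i]) for i in range(9)},
            "Quartile.25": float(q25),
            "Quartile.75": float(q75),
            "GrayLevelInterquartileRange": float(q75 - q25),
            "GrayLevelMeanAbsoluteDeviation": float(np.abs(g - mean_g).mean()),
            "GrayLevelMedianAbsoluteDeviation": float(
                np.median(np.abs(g - median_g))
            ),
            "GrayLevelRobustMeanAbsoluteDeviation": rmad,
            "GrayLevelCoefficientOfVariation": _safe_ratio(
                float(np.sqrt(var_g)), abs(mean_g)
            ),
        }
    )
    return out
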