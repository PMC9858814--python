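"""First-order (histogram) intensity features and gray-level discretization.

All statistics are computed over within-mask voxel intensities.  Entropy and
Uniformity operate on the discretized histogram (base-2 log, 0*log0 := 0);
the remaining statistics use the raw intensities.  Skewness and Kurtosis are
population moment ratios (Kurtosis is uncorrected: a Gaussian gives 3).
"""

from __future__ import annotations

import numpy as np

from radigen._utils import as_mask, as_volume, check_same_shape


def discretize(volume: np.ndarray, mask: np.ndarray, n_bins: int = 32) -> np.ndarray:
    """Equal-width binning of within-mask intensities to levels 1..n_bins.

    Bins span [within-mask min, within-mask max]; the maximum maps to level
    n_bins.  A constant region maps to level 1 everywhere.  Voxels outside
    the mask are assigned level 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    volume = as_volume(volume)
    mask = as_mask(mask)
    check_same_shape(volume, mask)
    vals = volume[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(volume.shape, dtype=np.int64)
    if hi == lo:
        levels[mask] = 1
        return levels
    width = (hi - lo) / n_bins
    binned = np.floor((vals - lo) / width).astype(np.int64) + 1
    levels[mask] = np.clip(binned, 1, n_bins)
    return levels


def _histogram_probs(levels: np.ndarray, mask: np.ndarray, n_bins: int) -> np.ndarray:
    counts = np.bincount(levels[mask], minlength=n_bins + 1)[1:]
    return counts / counts.sum()


def extract_first_order(
    volume: np.ndarray,
    mask: np.ndarray,
    n_bins: int = 32,
    spacing_mm=(1.0, 1.0, 1.0),
) -> dict[str, float]:
    """The 18 first-order features on within-mask intensities."""
    volume = as_volume(volume)
    mask = as_mask(mask)
    check_same_shape(volume, mask)
    x = volume[mask].astype(float)
    n = x.size
    voxel_volume = float(np.prod(np.asarray(spacing_mm, dtype=float)))

    mean = float(x.mean())
    diff = x - mean
    m2 = float(np.mean(diff**2))
    m3 = float(np.mean(diff**3))
    m4 = float(np.mean(diff**4))
    # numerically constant input: moment ratios are 0 by convention
    degenerate = m2 <= 1e-13 * max(float(np.mean(x**2)), 1e-300)
    skewness = 0.0 if degenerate else m3 / m2**1.5
    kurtosis = 0.0 if degenerate else m4 / m2**2

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0

    levels = discretize(volume, mask, n_bins)
    p = _histogram_probs(levels, mask, n_bins)
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(diff))),
        "RobustMeanAbsoluteDeviation": robust_mad,
        "RootMeanSquared": float(np.sqrt(energy / n)),
        "Skewness": float(skewness),
        "Kurtosis": float(kurtosis),
        "Variance": m2,
        "Uniformity": uniformity,
    }
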