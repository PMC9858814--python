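"""Voxel-wise DCE-MRI kinetic maps and image normalization/resampling.

Four co-registered timepoints are used: a pre-contrast volume and early
(~1 min), middle (~3 min) and late (~5 min) post-contrast volumes.  From
these the percentage-enhancement map

    PE_early = 100 * (I_early - I_pre) / I_pre

and the signal-enhancement-ratio maps

    SER_t = (I_early - I_pre) / (I_t - I_pre),   t in {middle, late}

are computed voxel by voxel.  PE measures early uptake; SER > 1 indicates
wash-out (the early enhancement exceeds the later one), SER < 1 persistent
enhancement.  Voxels where a denominator is numerically zero are flagged in
an explicit invalid-voxel mask and set to 0 rather than propagating NaN.

The module also provides the two preprocessing steps applied before feature
extraction: histogram remapping of within-mask intensities to the mean ± 3
standard deviations window, and resampling to 1 mm isotropic resolution with
cubic B-spline interpolation (nearest-neighbor for masks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from radigen._utils import as_mask, as_volume, check_same_shape

TIMEPOINTS = ("pre", "early", "middle", "late")

#: relative threshold for "denominator is numerically zero"
EPS_REL = 1e-6


@dataclass
class DceSeries:
    """Four co-registered 3-D volumes (pre/early/middle/late) plus spacing."""

    volumes: dict[str, np.ndarray]
    spacing_mm: tuple[float, float, float]
    patient_id: str = ""

    def __post_init__(self) -> None:
        missing = [t for t in TIMEPOINTS if t not in self.volumes]
        if missing:
            raise ValueError(f"DceSeries missing timepoints {missing}")
        vols = {t: as_volume(self.volumes[t], t) for t in TIMEPOINTS}
        check_same_shape(*vols.values())
        self.volumes = vols
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        self.spacing_mm = spacing

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes["pre"].shape


@dataclass
class ParametricMapSet:
    """Pre-contrast volume plus the derived PE / SER maps.

    ``invalid_voxel_mask`` marks voxels where a division guard fired in any
    of the maps; intensity statistics downstream exclude those voxels.
    """

    pre: np.ndarray
    pe_early: np.ndarray
    ser_middle: np.ndarray
    ser_late: np.ndarray
    invalid_voxel_mask: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def images(self) -> dict[str, np.ndarray]:
        """Maps keyed by the catalog image labels."""
        return {
            "pre": self.pre,
            "PE_early": self.pe_early,
            "SER_middle": self.ser_middle,
            "SER_late": self.ser_late,
        }


def _guard_eps(reference: np.ndarray, mask: np.ndarray | None) -> float:
    """Absolute guard threshold: EPS_REL x mean |reference| within the mask."""
    vals = np.abs(reference[mask]) if mask is not None else np.abs(reference)
    scale = float(vals.mean()) if vals.size else 0.0
    return EPS_REL * scale if scale > 0 else EPS_REL


def compute_pe_early(
    pre: np.ndarray,
    early: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentage-enhancement map 100*(I_early - I_pre)/I_pre.

    Parameters
    ----------
    pre, early
        Co-registered 3-D volumes (pre-contrast and ~1 min post-contrast).
    mask
        Optional region used to scale the zero-denominator guard; defaults
        to the whole volume.

    Returns
    -------
    pe : ndarray
        Percent enhancement; 0 at invalid voxels.
    invalid : ndarray of bool
        Voxels where I_pre was below the guard threshold.
    """
    pre = as_volume(pre, "pre")
    early = as_volume(early, "early")
    check_same_shape(pre, early)
    if np.any(pre < 0):
        raise ValueError("pre-contrast intensities must be non-negative")
    eps = _guard_eps(pre, mask)
    invalid = pre < eps
    denom = np.where(invalid, 1.0, pre)
    pe = 100.0 * (early - pre) / denom
    pe[invalid] = 0.0
    return pe, invalid


def compute_ser(
    pre: np.ndarray,
    early: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Signal-enhancement-ratio map (I_early - I_pre)/(I_target - I_pre).

    ``target`` is the middle (~3 min) or late (~5 min) volume.  Voxels where
    |I_target - I_pre| is below the guard threshold are flagged invalid and
    set to 0.
    """
    pre = as_volume(pre, "pre")
    early = as_volume(early, "early")
    target = as_volume(target, "target")
    check_same_shape(pre, early, target)
    diff = target - pre
    eps = _guard_eps(pre, mask)
    invalid = np.abs(diff) < eps
    denom = np.where(invalid, 1.0, diff)
    ser = (early - pre) / denom
    ser[invalid] = 0.0
    return ser, invalid


def compute_maps(series: DceSeries, mask: np.ndarray | None = None) -> ParametricMapSet:
    """All three kinetic maps for one patient's DCE series."""
    v = series.volumes
    pe, inv_pe = compute_pe_early(v["pre"], v["early"], mask)
    ser_mid, inv_mid = compute_ser(v["pre"], v["early"], v["middle"], mask)
    ser_late, inv_late = compute_ser(v["pre"], v["early"], v["late"], mask)
    invalid = inv_pe | inv_mid | inv_late
    meta = {
        "patient_id": series.patient_id,
        "n_invalid": int(invalid.sum()),
        "n_invalid_pe": int(inv_pe.sum()),
        "n_invalid_ser_middle": int(inv_mid.sum()),
        "n_invalid_ser_late": int(inv_late.sum()),
    }
    return ParametricMapSet(
        pre=v["pre"].copy(),
        pe_early=pe,
        ser_middle=ser_mid,
        ser_late=ser_late,
        invalid_voxel_mask=invalid,
        meta=meta,
    )


def normalize_volume(
    volume: np.ndarray,
    mask: np.ndarray,
    out_range: tuple[float, float] = (0.0, 100.0),
) -> tuple[np.ndarray, dict]:
    """Remap intensities so the within-mask mean ± 3 SD window spans ``out_range``.

    Values are clipped to [mu - 3*sigma, mu + 3*sigma] (mu, sigma computed
    within the mask) and affinely mapped to ``out_range``; the remap is
    order-preserving on the clipped range.  A constant region (sigma = 0)
    returns the midpoint everywhere with ``params['degenerate'] = True``.

    Returns the remapped volume and a parameter record (mu, sigma, range).
    """
    volume = as_volume(volume)
    mask = as_mask(mask)
    check_same_shape(volume, mask)
    vals = volume[mask]
    mu = float(vals.mean())
    sigma = float(vals.std(ddof=0))
    lo, hi = out_range
    params = {"mu": mu, "sigma": sigma, "out_range": [lo, hi], "degenerate": False}
    if sigma == 0.0:
        warnings.warn("constant volume within mask; returning midpoint remap")
        params["degenerate"] = True
        return np.full_like(volume, (lo + hi) / 2.0), params
    clipped = np.clip(volume, mu - 3.0 * sigma, mu + 3.0 * sigma)
    remapped = lo + (clipped - (mu - 3.0 * sigma)) * (hi - lo) / (6.0 * sigma)
    return remapped, params


def resample_isotropic(
    volume: np.ndarray,
    spacing_mm,
    is_mask: bool = False,
    target_mm: float = 1.0,
) -> np.ndarray:
    """Resample to isotropic ``target_mm`` spacing over the same physical extent.

    Intensities are interpolated with a cubic B-spline; masks use
    nearest-neighbor and are re-binarized.  Output voxel ``i`` along an axis
    sits at physical position ``i * target_mm``, coincident with input voxel
    centers at position ``i * spacing``.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("volume must be 3-D")
    spacing = np.asarray(spacing_mm, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing_mm}")
    if np.allclose(spacing, target_mm):
        out = volume.astype(bool) if is_mask else volume.astype(float)
        return out.copy()
    extent = (np.array(volume.shape) - 1) * spacing  # physical span of voxel centers
    new_shape = np.floor(extent / target_mm).astype(int) + 1
    coords = np.meshgrid(
        *(np.arange(n) * target_mm / s for n, s in zip(new_shape, spacing)),
        indexing="ij",
    )
    order = 0 if is_mask else 3
    out = ndimage.map_coordinates(
        volume.astype(float), np.array(coords), order=order, mode="nearest"
    )
    if is_mask:
        return out > 0.5
    return out
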