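"""Gray-level co-occurrence matrix and its 22 texture features.

The GLCM is accumulated over the 13 unique 3-D direction offsets at a given
voxel distance (both voxels of a pair must lie inside the mask), symmetrized
by counting each pair in both orders, summed over directions and normalized
to unit mass.  Feature formulas use levels i, j in 1..L, base-2 logs and the
0*log0 := 0 convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from radigen._utils import as_mask, check_same_shape

# 13 unique 3-D offsets: first nonzero component positive (z, y, x order)
UNIQUE_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in ((-1, 0, 1) if dz == 1 else (0, 1))
    for dx in ((-1, 0, 1) if (dz, dy) != (0, 0) else (1,))
)
assert len(UNIQUE_OFFSETS) == 13


@dataclass
class Glcm:
    """Normalized symmetric co-occurrence matrix."""

    matrix: np.ndarray
    levels: int
    distance: int
    directions: tuple[tuple[int, int, int], ...]


def _pair_slices(offset, shape):
    """Slices selecting source voxels and their offset partners."""
    src, dst = [], []
    for d, n in zip(offset, shape):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return tuple(src), tuple(dst)


def compute_glcm(
    levels_volume: np.ndarray,
    mask: np.ndarray,
    distance: int = 1,
    directions: tuple[tuple[int, int, int], ...] | None = None,
) -> Glcm:
    """Aggregate GLCM over direction offsets at the given distance.

    ``levels_volume`` holds integer levels 1..L inside the mask (level 0 is
    allowed outside).  Raises if no co-occurring in-mask pair exists.
    """
    levels_volume = np.asarray(levels_volume)
    mask = as_mask(mask)
    check_same_shape(levels_volume, mask)
    in_mask = levels_volume[mask]
    if in_mask.min() < 1:
        raise ValueError("levels inside mask must be >= 1")
    L = int(in_mask.max())
    if directions is None:
        directions = UNIQUE_OFFSETS
    counts = np.zeros((L, L), dtype=np.int64)
    for direction in directions:
        offset = tuple(int(d) * distance for d in direction)
        src, dst = _pair_slices(offset, mask.shape)
        both = mask[src] & mask[dst]
        a = levels_volume[src][both] - 1
        b = levels_volume[dst][both] - 1
        if a.size:
            counts += np.bincount(a * L + b, minlength=L * L).reshape(L, L)
    counts = counts + counts.T  # each pair in both orders
    total = counts.sum()
    if total == 0:
        raise ValueError("mask contains no co-occurring voxel pairs")
    return Glcm(
        matrix=counts / total,
        levels=L,
        distance=distance,
        directions=tuple(tuple(d) for d in directions),
    )


def extract_glcm_features(glcm: Glcm) -> dict[str, float]:
    """The 22 GLCM texture features of the catalog."""
    P = np.asarray(glcm.matrix, dtype=float)
    L = P.shape[0]
    if P.shape != (L, L):
        raise ValueError("GLCM must be square")
    if not np.allclose(P, P.T, atol=1e-12):
        raise ValueError("GLCM must be symmetric")
    if not np.isclose(P.sum(), 1.0, atol=1e-9):
        raise ValueError("GLCM must be normalized to sum 1")

    i = np.arange(1, L + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    ux = float((i * px).sum())
    uy = float((i * py).sum())
    sx = float(np.sqrt(((i - ux) ** 2 * px).sum()))
    sy = float(np.sqrt(((i - uy) ** 2 * py).sum()))

    def xlog2(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        nz = v > 0
        out[nz] = v[nz] * np.log2(v[nz])
        return out

    # difference distribution p_{x-y}(k), k = 0..L-1
    k_diff = np.abs(ii - jj)
    p_diff = np.bincount(k_diff.ravel(), weights=P.ravel(), minlength=L)[:L]
    kd = np.arange(L)
    diff_avg = float((kd * p_diff).sum())
    # sum distribution p_{x+y}(k), k = 2..2L
    k_sum = ii + jj
    p_sum = np.bincount(k_sum.ravel(), weights=P.ravel(), minlength=2 * L + 1)[2:]

    joint_entropy = float(-xlog2(P).sum())
    hx = float(-xlog2(px).sum())
    hy = float(-xlog2(py).sum())
    pxpy = np.outer(px, py)
    hxy1 = float(-(P * np.where(pxpy > 0, np.log2(np.where(pxpy > 0, pxpy, 1.0)), 0.0)).sum())
    hxy2 = float(-xlog2(pxpy).sum())

    if max(hx, hy) > 0:
        imc1 = (joint_entropy - hxy1) / max(hx, hy)
    else:
        imc1 = 0.0
    imc2_arg = 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy))
    imc2 = float(np.sqrt(max(imc2_arg, 0.0)))

    if sx > 0 and sy > 0:
        correlation = float(((ii * jj * P).sum() - ux * uy) / (sx * sy))
    else:
        correlation = 1.0  # flat region convention

    nz_k = kd[1:]
    return {
        "Autocorrelation": float((ii * jj * P).sum()),
        "JointAverage": ux,
        "ClusterProminence": float((((ii + jj) - ux - uy) ** 4 * P).sum()),
        "ClusterShade": float((((ii + jj) - ux - uy) ** 3 * P).sum()),
        "ClusterTendency": float((((ii + jj) - ux - uy) ** 2 * P).sum()),
        "Contrast": float(((ii - jj) ** 2 * P).sum()),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-xlog2(p_diff).sum()),
        "DifferenceVariance": float(((kd - diff_avg) ** 2 * p_diff).sum()),
        "Id": float((P / (1.0 + k_diff)).sum()),
        "Idm": float((P / (1.0 + k_diff**2)).sum()),
        "Idmn": float((P / (1.0 + k_diff**2 / L**2)).sum()),
        "Idn": float((P / (1.0 + k_diff / L)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / nz_k**2).sum()),
        "JointEnergy": float((P**2).sum()),
        "JointEntropy": joint_entropy,
        "MaximumProbability": float(P.max()),
        "SumEntropy": float(-xlog2(p_sum).sum()),
        "SumSquares": float(((ii - ux) ** 2 * P).sum()),
    }
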