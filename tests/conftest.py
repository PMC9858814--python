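import numpy as np
import pandas as pd
import pytest

from radigen.dce_maps import ParametricMapSet
from radigen.synthetic import KineticParams, PhantomConfig, make_tumor_mask, simulate_dce


def digital_ball(radius_vox: float, n: int) -> np.ndarray:
    """Voxelized ball of given radius centered in an n^3 grid."""
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


def digital_ellipsoid(semi_axes, n: int) -> np.ndarray:
    c = (n - 1) / 2.0
    zz, yy, xx = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    a, b, d = semi_axes
    return ((zz - c) / a) ** 2 + ((yy - c) / b) ** 2 + ((xx - c) / d) ** 2 <= 1.0


def flag_matrix(n_pairs, n_pathways_hit, n_features_hit, shape=(174, 50)):
    """Deterministic boolean feature x pathway matrix with exact counts."""
    flags = np.zeros(shape, dtype=bool)
    for i in range(n_features_hit):
        flags[i, i % max(n_pathways_hit, 1)] = True
    placed = n_features_hit
    for i in range(n_features_hit):
        for j in range(n_pathways_hit):
            if placed >= n_pairs:
                break
            if not flags[i, j]:
                flags[i, j] = True
                placed += 1
        if placed >= n_pairs:
            break
    assert flags.sum() == n_pairs
    assert flags.any(axis=0).sum() == n_pathways_hit
    assert flags.any(axis=1).sum() == n_features_hit
    return pd.DataFrame(
        flags,
        index=[f"f{i:03d}" for i in range(shape[0])],
        columns=[f"path{j:02d}" for j in range(shape[1])],
    )


@pytest.fixture(scope="session")
def ball10():
    return digital_ball(10.0, 32)


@pytest.fixture(scope="session")
def phantom_case():
    """One deterministic phantom with maps, reused across feature tests."""
    from radigen.dce_maps import compute_maps

    cfg = PhantomConfig(
        n_patients=1, grid_shape=(40, 40, 40), lobulation=1.0,
        noise_sd=0.02, seed=42,
    )
    mask, _ = make_tumor_mask(cfg, 0, semi_axes_mm=(9.0, 7.0, 6.0))
    kin = KineticParams(washin=2.0, washout=0.1, heterogeneity=0.4)
    series = simulate_dce(mask, kin, cfg, 0)
    maps = compute_maps(series, mask)
    return mask, series, maps


def make_map_set(images: dict, invalid=None) -> ParametricMapSet:
    shape = images["pre"].shape
    return ParametricMapSet(
        pre=images["pre"],
        pe_early=images["PE_early"],
        ser_middle=images["SER_middle"],
        ser_late=images["SER_late"],
        invalid_voxel_mask=(
            invalid if invalid is not None else np.zeros(shape, dtype=bool)
        ),
    )
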