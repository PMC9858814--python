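"""IBSI-style radiomic feature catalog: shape, first-order, GLCM.

The catalog holds 174 features: 14 tumor-shape features computed once from
the binary mask, plus 18 first-order and 22 gray-level co-occurrence matrix
(GLCM) features computed on each of four images — the pre-contrast volume
and the PE-early / SER-middle / SER-late parametric maps.  Full feature
names follow ``imageLabel_family_featureName`` (shape features carry no
image label), so 14 + 4*(18 + 22) = 174.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from radigen._utils import as_mask
from radigen.dce_maps import ParametricMapSet
from radigen.features.firstorder import discretize, extract_first_order
from radigen.features.glcm import Glcm, compute_glcm, extract_glcm_features
from radigen.features.shape import extract_shape

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)

GLCM_NAMES = (
    "Autocorrelation",
    "JointAverage",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointEnergy",
    "JointEntropy",
    "MaximumProbability",
    "SumEntropy",
    "SumSquares",
)

IMAGE_LABELS = ("pre", "PE_early", "SER_middle", "SER_late")


@dataclass(frozen=True)
class FeatureCatalog:
    """Names and category annotations of the 174-feature catalog."""

    shape_names: tuple[str, ...] = SHAPE_NAMES
    firstorder_names: tuple[str, ...] = FIRSTORDER_NAMES
    glcm_names: tuple[str, ...] = GLCM_NAMES
    image_labels: tuple[str, ...] = IMAGE_LABELS

    @property
    def full_names(self) -> list[str]:
        names = [f"shape_{n}" for n in self.shape_names]
        for label in self.image_labels:
            names += [f"{label}_firstorder_{n}" for n in self.firstorder_names]
            names += [f"{label}_glcm_{n}" for n in self.glcm_names]
        return names

    def categories(self) -> pd.DataFrame:
        """Per-feature category annotations.

        category_I: algorithm family (shape / firstorder / glcm);
        category_II: source image (or 'none' for shape);
        category_III: the family x image cross label.
        """
        rows = []
        for n in self.shape_names:
            rows.append((f"shape_{n}", "shape", "none", "shape"))
        for label in self.image_labels:
            for n in self.firstorder_names:
                rows.append(
                    (f"{label}_firstorder_{n}", "firstorder", label, f"firstorder_{label}")
                )
            for n in self.glcm_names:
                rows.append((f"{label}_glcm_{n}", "glcm", label, f"glcm_{label}"))
        return pd.DataFrame(
            rows, columns=["feature", "category_I", "category_II", "category_III"]
        ).set_index("feature")

    def __len__(self) -> int:
        return len(self.shape_names) + len(self.image_labels) * (
            len(self.firstorder_names) + len(self.glcm_names)
        )


def extract_all(
    maps: ParametricMapSet,
    mask: np.ndarray,
    spacing_mm=(1.0, 1.0, 1.0),
    n_bins: int = 32,
    catalog: FeatureCatalog | None = None,
) -> pd.Series:
    """The full 174-value feature vector for one patient.

    Shape features come from the mask alone; first-order and GLCM features
    are computed per image on within-mask voxels, excluding voxels flagged
    invalid by the map computation.
    """
    catalog = catalog or FeatureCatalog()
    mask = as_mask(mask)
    valid_mask = mask & ~maps.invalid_voxel_mask.astype(bool)
    if not valid_mask.any():
        raise ValueError("no valid voxels left inside the mask")

    values: dict[str, float] = {}
    shape_vals = extract_shape(mask, spacing_mm)
    for n in catalog.shape_names:
        values[f"shape_{n}"] = shape_vals[n]

    for label, image in maps.images.items():
        try:
            fo = extract_first_order(image, valid_mask, n_bins=n_bins, spacing_mm=spacing_mm)
            levels = discretize(image, valid_mask, n_bins=n_bins)
            glcm = compute_glcm(levels, valid_mask)
            tex = extract_glcm_features(glcm)
        except Exception as exc:  # re-raise with the image label for context
            raise RuntimeError(f"feature extraction failed on image '{label}': {exc}") from exc
        for n in catalog.firstorder_names:
            values[f"{label}_firstorder_{n}"] = fo[n]
        for n in catalog.glcm_names:
            values[f"{label}_glcm_{n}"] = tex[n]

    out = pd.Series(values, dtype=float).reindex(catalog.full_names)
    if out.isna().any():
        missing = out.index[out.isna()].tolist()
        raise RuntimeError(f"features missing from extraction: {missing}")
    return out


__all__ = [
    "FeatureCatalog",
    "SHAPE_NAMES",
    "FIRSTORDER_NAMES",
    "GLCM_NAMES",
    "IMAGE_LABELS",
    "extract_all",
    "extract_shape",
    "extract_first_order",
    "discretize",
    "Glcm",
    "compute_glcm",
    "extract_glcm_features",
]
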