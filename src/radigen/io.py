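"""Reading and writing the pipeline's file formats.

Volumes and masks: NIfTI (.nii / .nii.gz) via nibabel, spacing taken from the
header zooms (note nibabel stores data in (x, y, z) order on disk; arrays in
this package are (z, y, x), so volumes are transposed on read/write).
Counts: TSV, genes x samples with a header row of sample IDs.
Gene sets: GMT (name, description, tab-separated gene IDs per line).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from radigen.dce_maps import TIMEPOINTS, DceSeries


def write_volume(path, volume: np.ndarray, spacing_mm=(1.0, 1.0, 1.0)) -> None:
    """Write a (z, y, x) array as NIfTI with the given voxel spacing."""
    spacing = np.asarray(spacing_mm, dtype=float)
    affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
    data = np.asarray(volume)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), affine)
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns ((z, y, x) array, spacing in mm)."""
    img = nib.load(str(path))
    data = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0))
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return np.asarray(data, dtype=float), spacing


def read_dce_series(paths: dict[str, str], patient_id: str = "") -> DceSeries:
    """Load the four timepoint volumes named in ``paths`` (pre/early/middle/late)."""
    missing = [t for t in TIMEPOINTS if t not in paths]
    if missing:
        raise FileNotFoundError(f"missing timepoint file(s) for {missing}")
    volumes, spacings = {}, set()
    for label in TIMEPOINTS:
        p = Path(paths[label])
        if not p.exists():
            raise FileNotFoundError(f"timepoint '{label}': no such file {p}")
        vol, spacing = read_volume(p)
        volumes[label] = vol
        spacings.add(spacing)
    if len(spacings) > 1:
        raise ValueError(f"timepoints disagree on voxel spacing: {sorted(spacings)}")
    return DceSeries(volumes=volumes, spacing_mm=spacings.pop(), patient_id=patient_id)


def read_mask(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a binary tumor mask and validate single-component connectivity."""
    data, spacing = read_volume(path)
    mask = data > 0.5
    if not mask.any():
        raise ValueError(f"mask {path} is empty")
    _, n_comp = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    if n_comp != 1:
        raise ValueError(f"mask {path} has {n_comp} connected components, expected 1")
    return mask, spacing


def write_counts(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    """Genes x samples non-negative integer TSV with a sample-ID header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs in {path}: {dupes[:5]}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number) or (values < 0).any():
        raise ValueError(f"counts in {path} must be non-negative numbers")
    return df


def write_gmt(path, sets: dict[str, list[str]], description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_gmt(path) -> dict[str, list[str]]:
    """GMT parser: one set per line, name TAB description TAB genes..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description, genes")
            name, _desc, *genes = parts
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set '{name}'")
            if len(set(genes)) != len(genes):
                raise ValueError(f"{path}:{lineno}: duplicate gene IDs in set '{name}'")
            sets[name] = genes
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return sets


def write_tsv(path, df: pd.DataFrame, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
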