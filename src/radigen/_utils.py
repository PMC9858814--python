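"""Shared helpers: seed derivation, rounding, validation."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, fanned out from one global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matches hand-rounded tables, not banker's)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def check_same_shape(*arrays: np.ndarray) -> None:
    shapes = {a.shape for a in arrays}
    if len(shapes) > 1:
        raise ValueError(f"volumes must share a shape, got {sorted(map(str, shapes))}")


def as_volume(a, name: str = "volume") -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 3:
        raise ValueError(f"{name} must be 3-D, got ndim={a.ndim}")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def as_mask(m, name: str = "mask") -> np.ndarray:
    m = np.asarray(m)
    if m.ndim != 3:
        raise ValueError(f"{name} must be 3-D, got ndim={m.ndim}")
    m = m.astype(bool)
    if not m.any():
        raise ValueError(f"{name} is empty")
    return m
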