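"""Mask construction operators and per-ROI summaries of MWF maps.

Masks are plain binary 3-D arrays aligned to the map grid.  Undefined map
voxels (NaN) are excluded from all summaries and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Mask",
    "RoiSummary",
    "threshold_binarize",
    "erode",
    "roi_mean",
    "mask_percentile",
]


@dataclass(frozen=True)
class Mask:
    data: np.ndarray  # binary, uint8
    name: str = ""

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if not np.isin(d, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "data", d.astype(np.uint8))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def astype_bool(self) -> np.ndarray:
        return self.data.astype(bool)


@dataclass(frozen=True)
class RoiSummary:
    """Mean/SD of defined in-mask voxels of one map."""

    roi: str
    mean: float
    sd: float
    n_voxels: int
    n_undefined: int = 0
    participant: str | int | None = None
    site: str | None = None


def threshold_binarize(prob_map: np.ndarray, threshold: float, name: str = "") -> Mask:
    """Binary mask of voxels with probability >= threshold.

    Idempotent on binary input for any threshold <= 1.
    """
    if not (0 < threshold <= 1):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    prob_map = np.asarray(prob_map, dtype=float)
    return Mask((prob_map >= threshold).astype(np.uint8), name=name)


def erode(mask: Mask, iterations: int = 1) -> Mask:
    """Morphological erosion with a 6-connected (face-adjacent) element.

    ``iterations=0`` is the identity; the result is always a subset of the
    input.
    """
    if iterations < 0:
        raise ValueError(f"iterations must be >= 0, got {iterations}")
    if iterations == 0:
        return mask
    structure = ndimage.generate_binary_structure(mask.data.ndim, 1)
    out = ndimage.binary_erosion(
        mask.astype_bool(), structure=structure, iterations=iterations
    )
    return Mask(out.astype(np.uint8), name=mask.name)


def _masked_values(map_data: np.ndarray, mask: Mask) -> tuple[np.ndarray, int]:
    map_data = np.asarray(map_data, dtype=float)
    if map_data.shape != mask.data.shape:
        raise ValueError(
            f"map shape {map_data.shape} does not match mask shape {mask.data.shape}"
        )
    vals = map_data[mask.astype_bool()]
    defined = vals[np.isfinite(vals)]
    return defined, int(vals.size - defined.size)


def roi_mean(
    map_data: np.ndarray,
    mask: Mask,
    participant: str | int | None = None,
    site: str | None = None,
) -> RoiSummary:
    """Arithmetic mean and SD (n-1 denominator) over defined in-mask voxels."""
    defined, n_undef = _masked_values(map_data, mask)
    if defined.size == 0:
        raise ValueError(f"mask '{mask.name}' has no defined voxels")
    sd = float(np.std(defined, ddof=1)) if defined.size > 1 else 0.0
    return RoiSummary(
        roi=mask.name,
        mean=float(defined.mean()),
        sd=sd,
        n_voxels=int(defined.size),
        n_undefined=n_undef,
        participant=participant,
        site=site,
    )


def mask_percentile(map_data: np.ndarray, mask: Mask, q: float) -> float:
    """Linear-interpolation percentile of defined in-mask map values."""
    if not (0 <= q <= 100):
        raise ValueError(f"q must be in [0, 100], got {q}")
    defined, _ = _masked_values(map_data, mask)
    if defined.size == 0:
        raise ValueError(f"mask '{mask.name}' has no defined voxels")
    return float(np.percentile(defined, q))
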