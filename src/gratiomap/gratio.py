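"""Axon volume fraction and aggregate MR fiber g-ratio maps.

The aggregate g-ratio of a voxel is the ratio of inner (axon) to outer
(axon + myelin) fiber diameter implied by its myelin and axon volume
fractions:

    AVF = (1 - MVF) (1 - Viso) Vic
    g   = sqrt(AVF / (MVF + AVF))

NaN propagates from any parent map; voxels with MVF + AVF = 0 are
undefined and flagged in the QC mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "MicrostructureMaps",
    "compute_avf",
    "compute_gratio",
    "compute_microstructure",
    "erode_mask",
]


@dataclass
class MicrostructureMaps:
    mvf: np.ndarray
    avf: np.ndarray
    gratio: np.ndarray
    qc_mask: np.ndarray  # True where all maps are valid


def compute_avf(mvf, viso, vic) -> np.ndarray:
    """Axon volume fraction, (1 - MVF)(1 - Viso) Vic, elementwise."""
    mvf = np.asarray(mvf, dtype=float)
    viso = np.asarray(viso, dtype=float)
    vic = np.asarray(vic, dtype=float)
    if not (mvf.shape == viso.shape == vic.shape):
        raise ValueError("input maps must share one grid")
    for name, arr in (("mvf", mvf), ("viso", viso), ("vic", vic)):
        finite = arr[np.isfinite(arr)]
        if np.any((finite < -1e-9) | (finite > 1 + 1e-9)):
            raise ValueError(f"{name} must lie in [0, 1]")
    return (1.0 - mvf) * (1.0 - viso) * vic


def compute_gratio(avf, mvf) -> np.ndarray:
    """Aggregate fiber g-ratio, sqrt(AVF / (MVF + AVF)).

    MVF + AVF = 0 yields NaN (no fiber volume to form a ratio).
    """
    avf = np.asarray(avf, dtype=float)
    mvf = np.asarray(mvf, dtype=float)
    if avf.shape != mvf.shape:
        raise ValueError("input maps must share one grid")
    for name, arr in (("avf", avf), ("mvf", mvf)):
        finite = arr[np.isfinite(arr)]
        if np.any(finite < -1e-9):
            raise ValueError(f"{name} must be non-negative")
    total = mvf + avf
    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.sqrt(np.where(total > 0, avf / np.where(total > 0, total, 1.0), np.nan))
    return g


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """In-plane one-voxel erosion of a cord mask (per axial slice).

    Trims edge voxels whose values are dominated by partial volume or
    registration error before ROI statistics.
    """
    mask = np.asarray(mask, dtype=bool)
    if iterations <= 0:
        return mask
    struct = np.zeros((3, 3, 1), dtype=bool)
    struct[1, :, 0] = True
    struct[:, 1, 0] = True
    return ndimage.binary_erosion(mask, structure=struct, iterations=iterations)


def compute_microstructure(
    mvf: np.ndarray,
    vic: np.ndarray,
    viso: np.ndarray,
    mask: np.ndarray | None = None,
    erode: bool = True,
) -> MicrostructureMaps:
    """AVF and g-ratio maps with QC propagation.

    ``mask`` (e.g. the cord mask) is eroded by one in-plane voxel by
    default; any voxel invalid (NaN) in any parent map is invalid in the
    outputs and excluded from the QC mask.
    """
    avf = compute_avf(mvf, viso, vic)
    g = compute_gratio(avf, np.asarray(mvf, dtype=float))
    valid = np.isfinite(avf) & np.isfinite(g)
    if mask is not None:
        roi = erode_mask(mask) if erode else np.asarray(mask, dtype=bool)
        valid &= roi
    return MicrostructureMaps(
        mvf=np.asarray(mvf, dtype=float), avf=avf, gratio=g, qc_mask=valid
    )
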