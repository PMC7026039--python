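"""Slice-wise NCCT brain extraction by Hounsfield thresholding and morphology.

Six steps per axial slice: Gaussian smoothing (variance 4 px², i.e. σ = 2 px),
keep 0–100 HU, binary erosion (disk radius 1), largest 8-connected component,
binary dilation (disk radius 1); after stacking the per-slice masks, holes in
the 3D mask are filled with an iterative neighborhood-voting filter. Brain
parenchyma and CSF fall inside the 0–100 HU window while skull (~1000 HU) and
air (−1000 HU) are excluded, so the largest in-window component per slice is
the brain cross-section.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .image_core import BinaryMask, Volume

logger = logging.getLogger(__name__)

__all__ = ["extract_slice", "extract_volume", "voting_hole_fill"]

HU_LOW, HU_HIGH = 0.0, 100.0
SMOOTH_SIGMA = 2.0  # px; "variance = 4 pixels" read as sigma^2 = 4
_DISK1 = morphology.disk(1)


def extract_slice(slice_hu: np.ndarray) -> np.ndarray:
    """Brain mask of one axial CT slice (uint8 {0,1}); empty if nothing in-window."""
    arr = np.asarray(slice_hu, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {arr.shape}")
    sm = ndimage.gaussian_filter(arr, sigma=SMOOTH_SIGMA)
    mask = (sm >= HU_LOW) & (sm <= HU_HIGH)
    mask = ndimage.binary_erosion(mask, _DISK1)
    if not mask.any():
        return np.zeros(arr.shape, dtype=np.uint8)
    labels = measure.label(mask, connectivity=2)  # 8-connected
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    mask = ndimage.binary_dilation(mask, _DISK1)
    return mask.astype(np.uint8)


def voting_hole_fill(
    m: BinaryMask | np.ndarray,
    radius: int = 1,
    majority: float = 0.5,
    max_iter: int = 10,
) -> BinaryMask | np.ndarray:
    """Iterative majority-voting hole filling (monotone: foreground never unset).

    A background voxel becomes foreground when strictly more than ``majority``
    of its neighborhood (face-connected ball of the given radius, center
    excluded) is foreground; the strict inequality fills enclosed holes but
    does not creep along flat or gently concave surfaces. Stops at
    convergence or ``max_iter``.
    """
    is_mask = isinstance(m, BinaryMask)
    arr = (m.voxels if is_mask else np.asarray(m)).astype(bool)
    ndim = arr.ndim
    # face-connected (6-connected in 3D) ball footprint, center excluded
    footprint = ndimage.generate_binary_structure(ndim, 1)
    if radius > 1:
        footprint = ndimage.iterate_structure(footprint, radius)
    footprint = footprint.copy()
    footprint[tuple(s // 2 for s in footprint.shape)] = False
    n_neigh = int(footprint.sum())
    need = np.floor(majority * n_neigh) + 1  # strictly more than the majority

    out = arr.copy()
    for _ in range(max_iter):
        votes = ndimage.convolve(
            out.astype(np.uint8), footprint.astype(np.uint8), mode="constant", cval=0
        )
        grow = (~out) & (votes >= need)
        if not grow.any():
            break
        out |= grow
    result = out.astype(np.uint8)
    if is_mask:
        return BinaryMask(result, spacing=m.spacing, affine=m.affine)
    return result


def extract_volume(v: Volume) -> BinaryMask:
    """Slice-by-slice brain extraction of a CT volume + 3D voting hole fill."""
    if v.modality != "CT":
        raise ValueError(f"CT brain extraction requires a CT volume, got {v.modality}")
    out = np.zeros(v.shape, dtype=np.uint8)
    n_empty = 0
    for k in range(v.shape[2]):
        sl = extract_slice(v.voxels[:, :, k])
        if not sl.any():
            n_empty += 1
        out[:, :, k] = sl
    if n_empty:
        logger.info("%d/%d slices produced empty masks", n_empty, v.shape[2])
    out = voting_hole_fill(out)
    return BinaryMask.from_volume(v, out)
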