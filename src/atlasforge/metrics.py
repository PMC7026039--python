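"""Validation metrics: histogram entropy (sharpness), Dice overlap, Jacobians.

The entropy of an intensity histogram is the pipeline's sharpness proxy for
averaged templates: a blurry group average spreads intensity over many bins
(high entropy), a sharp one concentrates it (low entropy). Computed over 256
equal-width bins in nats by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_core import BinaryMask, DisplacementField, Volume

__all__ = ["EntropyConfig", "image_entropy", "dice", "jacobian_determinant"]


@dataclass
class EntropyConfig:
    """Binning for :func:`image_entropy`.

    ``bin_range``: ``"min_max"`` spans the data, or a fixed ``(lo, hi)`` pair.
    ``include_background``: when False, voxels equal to the data minimum
    (background plateau) are dropped before binning.
    """

    n_bins: int = 256
    bin_range: str | tuple[float, float] = "min_max"
    include_background: bool = True

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def image_entropy(v: Volume | np.ndarray, cfg: EntropyConfig | None = None) -> float:
    """H = −Σ pᵢ ln pᵢ over an equal-width intensity histogram (nats).

    Empty bins contribute 0; a constant image has a single occupied bin and
    entropy 0. Always within [0, ln n_bins].
    """
    if cfg is None:
        cfg = EntropyConfig()
    data = v.voxels if isinstance(v, Volume) else np.asarray(v)
    data = data[np.isfinite(data)].ravel().astype(np.float64)
    if data.size == 0:
        raise ValueError("cannot compute entropy of an empty image")
    if not cfg.include_background:
        data = data[data > data.min()]
        if data.size == 0:
            return 0.0
    if cfg.bin_range == "min_max":
        lo, hi = float(data.min()), float(data.max())
        if lo == hi:  # constant image: one bin, H = 0
            return 0.0
    else:
        lo, hi = map(float, cfg.bin_range)
    counts, _ = np.histogram(data, bins=cfg.n_bins, range=(lo, hi))
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def dice(a: BinaryMask | np.ndarray, b: BinaryMask | np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); two empty masks → 1 by convention."""
    av = (a.voxels if isinstance(a, BinaryMask) else np.asarray(a)).astype(bool)
    bv = (b.voxels if isinstance(b, BinaryMask) else np.asarray(b)).astype(bool)
    if av.shape != bv.shape:
        raise ValueError(f"mask grids differ: {av.shape} vs {bv.shape}")
    denom = av.sum() + bv.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(av, bv).sum() / denom)


def jacobian_determinant(f: DisplacementField | np.ndarray) -> np.ndarray:
    """Determinant of the central-difference Jacobian of (identity + f).

    Returns a scalar field on the full grid (one-sided differences at the
    boundary via ``np.gradient``). Strictly positive everywhere for a
    diffeomorphic displacement.
    """
    vec = f.vectors if isinstance(f, DisplacementField) else np.asarray(f)
    ndim = vec.shape[-1]
    grads = [np.gradient(vec[..., c]) for c in range(ndim)]  # grads[c][axis]
    if ndim == 2:
        j00 = 1.0 + grads[0][0]
        j01 = grads[0][1]
        j10 = grads[1][0]
        j11 = 1.0 + grads[1][1]
        return j00 * j11 - j01 * j10
    j = np.empty((*vec.shape[:-1], 3, 3))
    for c in range(3):
        for ax in range(3):
            j[..., c, ax] = grads[c][ax]
        j[..., c, c] += 1.0
    return np.linalg.det(j)
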