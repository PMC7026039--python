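"""Image, mask and displacement-field data model with NIfTI-1 I/O.

The carriers defined here are shared by every stage of the atlas pipeline:

* :class:`Volume` — a 3D scalar grid with per-axis spacing (mm), a
  voxel-index→world affine (RAS, NIfTI-1 convention) and a modality tag
  (``"MR"`` for FLAIR-like float intensities, ``"CT"`` for Hounsfield units).
* :class:`BinaryMask` — a {0,1} grid on the same geometry.
* :class:`DisplacementField` — a dense per-voxel vector field. Components are
  stored in voxel units of the fixed grid; conversion to mm happens only at
  I/O, where fields are written as 4D NIfTI volumes with the vector dimension
  last.

Warping follows the pull-back convention throughout:
``output(x) = input(x + d(x))`` — the field lives on the fixed grid and points
into the moving image. Array-level helpers (:func:`warp_array`,
:func:`compose_disp`, :func:`exp_velocity`, :func:`invert_disp`) work on raw
``numpy`` arrays in 2D or 3D and are the numerical workhorses used by the
registration engine; the typed wrappers validate geometry.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "Volume",
    "BinaryMask",
    "DisplacementField",
    "warp",
    "warp_array",
    "compose",
    "compose_disp",
    "exp_velocity",
    "invert_disp",
    "flip_x",
    "read_volume",
    "write_volume",
    "read_field",
    "write_field",
    "default_fill",
]

#: dtypes that round-trip bit-exactly through NIfTI-1
SUPPORTED_DTYPES = (np.float32, np.float64, np.int16, np.int32, np.uint8)


def default_fill(modality: str) -> float:
    """Modality-plausible out-of-domain fill: 0 for MR, -1000 HU (air) for CT."""
    return -1000.0 if modality == "CT" else 0.0


@dataclass
class Volume:
    """A 3D image: voxel grid + geometry + modality tag.

    ``voxels`` holds intensities (arbitrary units for MR, HU for CT),
    ``spacing`` is mm per axis, ``affine`` maps 0-based voxel indices to
    world mm (RAS).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    modality: str = "MR"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"Volume requires a 3D array, got shape {self.voxels.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if self.modality not in ("MR", "CT"):
            raise ValueError(f"modality must be 'MR' or 'CT', got {self.modality!r}")
        if np.issubdtype(self.voxels.dtype, np.floating) and not np.all(
            np.isfinite(self.voxels)
        ):
            raise ValueError("voxel values must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def with_voxels(self, voxels: np.ndarray) -> "Volume":
        """Same geometry and modality, new voxel data."""
        return dataclasses.replace(self, voxels=voxels)

    def astype(self, dtype) -> "Volume":
        return self.with_voxels(self.voxels.astype(dtype))


@dataclass
class BinaryMask:
    """A {0,1} grid sharing a Volume's geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"mask values must be exactly {{0,1}}, found {uniq[:10]}")
        self.voxels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.affine = np.asarray(self.affine, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    @classmethod
    def from_volume(cls, vol: Volume, data: np.ndarray) -> "BinaryMask":
        if data.shape != vol.shape:
            raise ValueError(
                f"mask shape {data.shape} does not match volume shape {vol.shape}"
            )
        return cls(data, spacing=vol.spacing, affine=vol.affine)


@dataclass
class DisplacementField:
    """Dense displacement field on a fixed grid, components in voxel units.

    ``vectors`` has shape ``(*grid, ndim)`` with the vector dimension last.
    """

    vectors: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        ndim = self.vectors.ndim - 1
        if ndim not in (2, 3) or self.vectors.shape[-1] != ndim:
            raise ValueError(
                "vectors must have shape (*grid, ndim) with ndim in {2,3}; "
                f"got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement components must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)[: ndim] or (1.0,) * ndim

    @property
    def ndim(self) -> int:
        return self.vectors.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.vectors.shape[:-1]

    @classmethod
    def zero(cls, grid_shape, spacing=None) -> "DisplacementField":
        ndim = len(grid_shape)
        spacing = spacing if spacing is not None else (1.0,) * ndim
        return cls(np.zeros((*grid_shape, ndim)), spacing=spacing)

    def max_magnitude(self) -> float:
        return float(np.sqrt((self.vectors**2).sum(axis=-1)).max())


# ---------------------------------------------------------------------------
# array-level field numerics (2D/3D)
# ---------------------------------------------------------------------------


def _coords(disp: np.ndarray) -> np.ndarray:
    """Sampling coordinates x + d(x), shape (ndim, *grid)."""
    grid = np.indices(disp.shape[:-1], dtype=np.float64)
    return grid + np.moveaxis(disp, -1, 0)


def warp_array(
    arr: np.ndarray, disp: np.ndarray, fill: float = 0.0, order: int = 1
) -> np.ndarray:
    """Pull-back resampling: out(x) = arr(x + disp(x)), linear by default."""
    if disp.shape[:-1] != arr.shape:
        raise ValueError(
            f"field grid {disp.shape[:-1]} does not match image grid {arr.shape}"
        )
    if np.allclose(disp, 0):
        return np.array(arr, dtype=np.float64, copy=True)
    out = map_coordinates(
        np.asarray(arr, dtype=np.float64),
        _coords(disp),
        order=order,
        mode="constant",
        cval=fill,
    )
    return out


def compose_disp(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    """Displacement of the map composition T1∘T2.

    (f1∘f2)(x) = f2(x) + f1(x + f2(x)); f1 sampled linearly with edge
    extension (fields vary smoothly, so nearest-edge is the stable choice).
    """
    if f1.shape != f2.shape:
        raise ValueError(f"field grids differ: {f1.shape} vs {f2.shape}")
    coords = _coords(f2)
    out = np.empty_like(f2)
    for c in range(f2.shape[-1]):
        out[..., c] = f2[..., c] + map_coordinates(
            f1[..., c], coords, order=1, mode="nearest"
        )
    return out


def exp_velocity(vel: np.ndarray, max_step: float = 0.5) -> np.ndarray:
    """Exponentiate a stationary velocity field by scaling and squaring.

    Scales the field so the initial step is below ``max_step`` voxels, then
    squares (self-composes) back up; guarantees a diffeomorphic displacement
    for smooth velocities.
    """
    mag = float(np.sqrt((vel**2).sum(axis=-1)).max())
    if mag == 0.0:
        return np.zeros_like(vel)
    n = max(0, int(np.ceil(np.log2(mag / max_step))))
    disp = vel / (2.0**n)
    for _ in range(n):
        disp = compose_disp(disp, disp)
    return disp


def invert_disp(
    disp: np.ndarray, iters: int = 30, tol: float = 1e-3
) -> np.ndarray:
    """Fixed-point inversion: g ← −f(x + g(x)). Converges for diffeomorphic f."""
    inv = -disp
    coords_base = np.indices(disp.shape[:-1], dtype=np.float64)
    for _ in range(iters):
        coords = coords_base + np.moveaxis(inv, -1, 0)
        new = np.empty_like(inv)
        for c in range(disp.shape[-1]):
            new[..., c] = -map_coordinates(
                disp[..., c], coords, order=1, mode="nearest"
            )
        delta = float(np.abs(new - inv).max())
        inv = new
        if delta < tol:
            break
    return inv


# ---------------------------------------------------------------------------
# typed wrappers
# ---------------------------------------------------------------------------


def warp(image: Volume, fld: DisplacementField, fill: float | None = None) -> Volume:
    """Warp a Volume under a displacement field on the same grid."""
    if fld.grid_shape != image.shape:
        raise ValueError(
            f"field grid {fld.grid_shape} does not match image grid {image.shape}"
        )
    if fill is None:
        fill = default_fill(image.modality)
    out = warp_array(image.voxels, fld.vectors, fill=fill)
    return image.with_voxels(out)


def compose(f1: DisplacementField, f2: DisplacementField) -> DisplacementField:
    if f1.grid_shape != f2.grid_shape:
        raise ValueError(f"field grids differ: {f1.grid_shape} vs {f2.grid_shape}")
    return DisplacementField(compose_disp(f1.vectors, f2.vectors), spacing=f1.spacing)


def flip_x(image: Volume) -> Volume:
    """Mirror the image about the grid mid-plane along the first voxel axis.

    The affine is kept, so the mirrored content occupies the same world
    extent: voxel (i,j,k) of the output equals voxel (W−1−i,j,k) of the input.
    Exact involution.
    """
    return image.with_voxels(image.voxels[::-1].copy())


# ---------------------------------------------------------------------------
# NIfTI-1 I/O
# ---------------------------------------------------------------------------


def _check_dtype(dtype) -> None:
    if not any(np.issubdtype(dtype, d) for d in SUPPORTED_DTYPES):
        raise ValueError(
            f"unsupported voxel dtype {dtype}; supported: "
            + ", ".join(np.dtype(d).name for d in SUPPORTED_DTYPES)
        )


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a Volume as NIfTI-1 (.nii or .nii.gz); lossless for supported dtypes."""
    _check_dtype(volume.voxels.dtype)
    img = nib.Nifti1Image(volume.voxels, volume.affine)
    img.header.set_zooms(volume.spacing)
    img.header["descrip"] = f"modality={volume.modality}".encode()
    nib.save(img, str(path))


def read_volume(path: str | Path, modality: str | None = None) -> Volume:
    """Read a NIfTI-1 volume. Modality comes from the header tag unless given."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several header/parse error types
        raise ValueError(f"failed to parse NIfTI file {path}: {exc}") from exc
    if not isinstance(img, (nib.Nifti1Image, nib.Nifti1Pair)):
        raise ValueError(f"{path} is not a NIfTI-1 image (got {type(img).__name__})")
    _check_dtype(img.get_data_dtype())
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    if modality is None:
        descrip = bytes(img.header["descrip"]).rstrip(b"\x00").decode(errors="replace")
        modality = "CT" if "modality=CT" in descrip else "MR"
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing=spacing, affine=img.affine, modality=modality)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), mask.affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    vol = read_volume(path)
    return BinaryMask(vol.voxels, spacing=vol.spacing, affine=vol.affine)


def write_field(fld: DisplacementField, path: str | Path) -> None:
    """Fields go to disk as 4D NIfTI, vector dimension last, components in mm."""
    mm = fld.vectors * np.asarray(fld.spacing)
    img = nib.Nifti1Image(mm.astype(np.float32), np.eye(4))
    img.header.set_zooms((*fld.spacing, 1.0))
    nib.save(img, str(path))


def read_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    mm = np.asanyarray(img.dataobj).astype(np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[: mm.shape[-1]])
    return DisplacementField(mm / np.asarray(spacing), spacing=spacing)
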