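"""Deterministic synthetic cohorts emulating clinical FLAIR-MR and NCCT scans.

The generator produces brain-shaped test objects at desk scale: a smoothed
ellipsoid "brain" with a low-frequency sulcal ripple on its boundary, interior
ellipsoidal "ventricles" whose size scales with a single atrophy proxy
(``ventricle_scale``), an optional high-HU skull shell for CT, a smooth
multiplicative bias field and additive Gaussian noise. Cohorts jitter the
anatomy (radii, ventricle scale) and the rigid pose per subject, with all
randomness split from one seed so generation is bit-reproducible.

Tissue values:

========== ================= =================
label      MR (a.u.)         CT (HU)
========== ================= =================
background 0                 −1000
brain      ~100 (90–110)     26–38
ventricle  25 (CSF dark)     20
skull      —                 1000
========== ================= =================

Labels: 0 background, 1 brain parenchyma, 2 ventricle, 3 skull.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .image_core import BinaryMask, Volume

__all__ = [
    "PhantomSpec",
    "CohortVariability",
    "PhantomSubject",
    "make_phantom",
    "make_cohort",
    "make_anisotropic",
]

LABEL_BACKGROUND, LABEL_BRAIN, LABEL_VENTRICLE, LABEL_SKULL = 0, 1, 2, 3

# fraction of the brain semi-axes occupied by the ventricles at scale 1
_VENT_BASE_FRAC = 0.30
# scaled ventricle semi-axis must stay below this fraction of the brain's
_VENT_MAX_FRAC = 0.85


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "MR"
    brain_radii: tuple[float, float, float] = (22.0, 26.0, 20.0)  # mm semi-axes
    ventricle_scale: float = 1.0
    skull_thickness: float = 2.0  # mm, CT only
    noise_sd: float = 0.0
    bias_amplitude: float = 0.0
    seed: int = 0
    # rigid pose baked into the geometry (used by make_cohort)
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    ripple_amplitude: float = 0.04
    ripple_frequency: int = 6
    # MR only: partial-volume edge smoothing (px). CT stays crisp so its
    # three tissue classes keep exact HU plateaus.
    edge_smoothing_px: float = 0.7

    def __post_init__(self) -> None:
        if self.modality not in ("MR", "CT"):
            raise ValueError(f"modality must be MR or CT, got {self.modality!r}")
        if self.ventricle_scale < 0:
            raise ValueError("ventricle_scale must be non-negative")
        if self.ventricle_scale * _VENT_BASE_FRAC >= _VENT_MAX_FRAC:
            raise ValueError(
                "ventricle exceeds brain extent: scaled ventricle semi-axis "
                f"would be {self.ventricle_scale * _VENT_BASE_FRAC:.2f} of the "
                f"brain's (limit {_VENT_MAX_FRAC})"
            )


@dataclass
class CohortVariability:
    """Per-subject jitter: anatomy + rigid pose, all in physical units."""

    radius_frac: float = 0.08  # uniform ±fraction on each brain semi-axis
    ventricle_range: tuple[float, float] = (0.7, 1.3)  # uniform multiplier
    rotation_deg: float = 5.0  # uniform ± per axis
    translation_mm: float = 2.0  # uniform ± per axis

    @classmethod
    def none(cls) -> "CohortVariability":
        return cls(radius_frac=0.0, ventricle_range=(1.0, 1.0),
                   rotation_deg=0.0, translation_mm=0.0)

    @classmethod
    def pose_only(cls, rotation_deg: float = 5.0, translation_mm: float = 2.0):
        return cls(radius_frac=0.0, ventricle_range=(1.0, 1.0),
                   rotation_deg=rotation_deg, translation_mm=translation_mm)


@dataclass
class PhantomSubject:
    volume: Volume
    mask: BinaryMask
    labels: np.ndarray
    spec: PhantomSpec


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _body_coords(spec: PhantomSpec) -> np.ndarray:
    """Physical coordinates in the object's body frame, shape (3, *grid)."""
    idx = np.indices(spec.grid_shape, dtype=np.float64)
    center = (np.asarray(spec.grid_shape, dtype=np.float64) - 1.0) / 2.0
    phys = idx * np.asarray(spec.spacing).reshape(3, 1, 1, 1)
    phys_center = center * np.asarray(spec.spacing)
    x = phys - phys_center.reshape(3, 1, 1, 1)
    x = x - np.asarray(spec.translation_mm, dtype=np.float64).reshape(3, 1, 1, 1)
    rot = _rotation_matrix(spec.rotation_deg)
    return np.einsum("ij,j...->i...", rot.T, x)


def _labels(spec: PhantomSpec) -> np.ndarray:
    x = _body_coords(spec)
    radii = np.asarray(spec.brain_radii, dtype=np.float64)
    rho = np.sqrt(((x / radii.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))

    # low-frequency angular ripple of the cortical boundary
    azimuth = np.arctan2(x[1], x[0])
    with np.errstate(invalid="ignore"):
        polar = np.arccos(np.clip(x[2] / np.maximum(np.sqrt((x**2).sum(axis=0)), 1e-9), -1, 1))
    boundary = 1.0 + spec.ripple_amplitude * np.sin(
        spec.ripple_frequency * azimuth
    ) * np.sin(2.0 * polar)

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    brain = rho <= boundary
    labels[brain] = LABEL_BRAIN

    if spec.ventricle_scale > 0:
        vent_radii = radii * _VENT_BASE_FRAC * spec.ventricle_scale
        # two lateral-ventricle lobes, offset along the second axis
        offset = np.zeros((3, 1, 1, 1))
        for sign in (-1.0, 1.0):
            offset[1] = sign * 0.35 * radii[1]
            rho_v = np.sqrt((((x - offset) / vent_radii.reshape(3, 1, 1, 1)) ** 2).sum(axis=0))
            labels[(rho_v <= 1.0) & brain] = LABEL_VENTRICLE

    if spec.modality == "CT" and spec.skull_thickness > 0:
        outer = 1.0 + spec.skull_thickness / radii.min()
        shell = (rho > boundary) & (rho <= boundary * outer)
        labels[shell] = LABEL_SKULL
    return labels


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order multiplicative field, 1 + amplitude·b with b in [−1,1]."""
    coords = [np.linspace(0, np.pi, n) for n in spec.grid_shape]
    gx, gy, gz = np.meshgrid(*coords, indexing="ij")
    coeff = rng.uniform(-1.0, 1.0, size=6)
    b = (
        coeff[0] * np.cos(gx)
        + coeff[1] * np.cos(gy)
        + coeff[2] * np.cos(gz)
        + coeff[3] * np.cos(gx) * np.cos(gy)
        + coeff[4] * np.cos(gy) * np.cos(gz)
        + coeff[5] * np.cos(gx) * np.cos(gz)
    )
    peak = np.abs(b).max()
    if peak > 0:
        b = b / peak
    return 1.0 + spec.bias_amplitude * b


def make_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask, np.ndarray]:
    """Build one phantom. Identical spec (incl. seed) ⇒ bit-identical output."""
    labels = _labels(spec)
    rng = np.random.default_rng(spec.seed)

    x = _body_coords(spec)
    radii = np.asarray(spec.brain_radii).reshape(3, 1, 1, 1)
    rho = np.sqrt(((x / radii) ** 2).sum(axis=0))

    img = np.zeros(spec.grid_shape, dtype=np.float64)
    if spec.modality == "CT":
        img[:] = -1000.0
        # mild radial variation keeps parenchyma inside the 20–40 HU window
        img[labels == LABEL_BRAIN] = 32.0 + 6.0 * np.cos(
            np.pi * np.clip(rho, 0, 1)
        )[labels == LABEL_BRAIN]
        img[labels == LABEL_VENTRICLE] = 20.0
        img[labels == LABEL_SKULL] = 1000.0
    else:
        img[labels == LABEL_BRAIN] = 100.0 + 10.0 * np.cos(
            np.pi * np.clip(rho, 0, 1)
        )[labels == LABEL_BRAIN]
        img[labels == LABEL_VENTRICLE] = 25.0
        if spec.edge_smoothing_px > 0:
            from scipy.ndimage import gaussian_filter

            img = gaussian_filter(img, spec.edge_smoothing_px)

    bias = _bias_field(spec, rng)  # drawn even at amplitude 0 to keep the
    if spec.bias_amplitude > 0:    # RNG stream layout stable across settings
        img = img * bias
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)

    vol = Volume(img, spacing=spec.spacing, modality=spec.modality)
    brain_mask = BinaryMask.from_volume(
        vol, ((labels == LABEL_BRAIN) | (labels == LABEL_VENTRICLE)).astype(np.uint8)
    )
    return vol, brain_mask, labels


def make_cohort(
    n: int,
    base: PhantomSpec,
    variability: CohortVariability | None = None,
    seed: int = 0,
) -> list[PhantomSubject]:
    """Draw ``n`` subjects around ``base``; one seed stream split per subject."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    if variability is None:
        variability = CohortVariability()
    subjects = []
    for i in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([seed, i]))
        radii = tuple(
            r * (1.0 + rng.uniform(-variability.radius_frac, variability.radius_frac))
            for r in base.brain_radii
        )
        vscale = base.ventricle_scale * rng.uniform(*variability.ventricle_range)
        rot = tuple(rng.uniform(-variability.rotation_deg, variability.rotation_deg)
                    for _ in range(3))
        trans = tuple(rng.uniform(-variability.translation_mm, variability.translation_mm)
                      for _ in range(3))
        spec = replace(
            base,
            brain_radii=radii,
            ventricle_scale=vscale,
            rotation_deg=rot,
            translation_mm=trans,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        vol, mask, labels = make_phantom(spec)
        subjects.append(PhantomSubject(vol, mask, labels, spec))
    return subjects


def make_anisotropic(volume: Volume, slice_thickness_mm: float) -> Volume:
    """Box-average downsampling along the through-plane (third) axis.

    Emulates thick-slice clinical acquisition: blocks of thin slices are
    averaged into one thick slice; spacing metadata updated accordingly.
    """
    dz = volume.spacing[2]
    if slice_thickness_mm < dz - 1e-9:
        raise ValueError(
            f"target thickness {slice_thickness_mm} mm is below the current "
            f"through-plane spacing {dz} mm"
        )
    factor_f = slice_thickness_mm / dz
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-6:
        raise ValueError(
            f"slice thickness must be an integer multiple of the input spacing "
            f"(requested factor {factor_f:.4f})"
        )
    if factor == 1:
        return volume.with_voxels(volume.voxels.copy())
    n_out = volume.shape[2] // factor
    data = volume.voxels[:, :, : n_out * factor].astype(np.float64)
    data = data.reshape(volume.shape[0], volume.shape[1], n_out, factor).mean(axis=3)
    new_spacing = (volume.spacing[0], volume.spacing[1], slice_thickness_mm)
    scale = np.diag([1.0, 1.0, float(factor), 1.0])
    return Volume(
        data,
        spacing=new_spacing,
        affine=volume.affine @ scale,
        modality=volume.modality,
    )
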