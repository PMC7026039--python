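"""Rigid, affine and diffeomorphic registration on regular grids.

Parametric (rigid/affine) alignment is a multi-resolution Powell search over
an explicit parameter vector (translations, Euler angles, log-scales, shears)
with a pluggable similarity metric (SSD for intramodal work, negated local
normalized cross-correlation, or joint-histogram mutual information for
intermodal work). All optimization is deterministic.

Non-linear alignment is a diffeomorphic demons scheme on a stationary
velocity field: per iteration a demons force is computed from the intensity
mismatch, smoothed (fluid regularization), added to the velocity, and the
velocity is smoothed again (diffusion regularization). The displacement is the
group exponential of the velocity, computed by scaling and squaring, which
with the per-step Jacobian check keeps every accepted result diffeomorphic
(strictly positive Jacobian determinant). Steps that would fold the grid or
increase the similarity cost are rejected with step halving, so the recorded
metric trace is non-increasing within each resolution level.

Transforms follow the pull-back convention of :mod:`atlasforge.image_core`:
``x_moving = linear @ x_fixed + translation`` in 0-based voxel coordinates of
the fixed grid, and ``warp(moving, forward) ≈ fixed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .image_core import (
    DisplacementField,
    Volume,
    compose_disp,
    exp_velocity,
    invert_disp,
    warp_array,
)
from .metrics import jacobian_determinant

logger = logging.getLogger(__name__)

__all__ = [
    "AffineTransform",
    "RegistrationParams",
    "RegistrationResult",
    "register_rigid",
    "register_affine",
    "register_diffeomorphic",
    "register_demons_array",
    "remove_rigid",
    "invert_field",
    "mutual_information",
]


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


@dataclass
class AffineTransform:
    """x_moving = linear @ x_fixed + translation (voxel units, pull-back)."""

    linear: np.ndarray
    translation: np.ndarray
    converged: bool = True

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        d = self.linear.shape[0]
        if self.linear.shape != (d, d) or d not in (2, 3):
            raise ValueError(f"linear part must be 2x2 or 3x3, got {self.linear.shape}")
        if abs(np.linalg.det(self.linear)) < 1e-12:
            raise ValueError("linear part is not invertible")

    @classmethod
    def identity(cls, ndim: int = 3, converged: bool = True) -> "AffineTransform":
        return cls(np.eye(ndim), np.zeros(ndim), converged=converged)

    @property
    def ndim(self) -> int:
        return self.linear.shape[0]

    def apply_to_array(
        self, moving: np.ndarray, output_shape=None, fill: float = 0.0, order: int = 1
    ) -> np.ndarray:
        """Resample ``moving`` onto the fixed grid under this transform."""
        return ndimage.affine_transform(
            np.asarray(moving, dtype=np.float64),
            self.linear,
            offset=self.translation,
            output_shape=output_shape or moving.shape,
            order=order,
            mode="constant",
            cval=fill,
        )

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(inv, -inv @ self.translation, converged=self.converged)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Pull-back composition: applying result ≡ apply self then other."""
        return AffineTransform(
            other.linear @ self.linear,
            other.linear @ self.translation + other.translation,
            converged=self.converged and other.converged,
        )

    def to_displacement(self, grid_shape) -> np.ndarray:
        idx = np.indices(grid_shape, dtype=np.float64)
        x = idx.reshape(len(grid_shape), -1)
        d = (self.linear @ x + self.translation[:, None]) - x
        return np.moveaxis(d.reshape(len(grid_shape), *grid_shape), 0, -1)

    def as_matrix(self) -> np.ndarray:
        d = self.ndim
        m = np.eye(d + 1)
        m[:d, :d] = self.linear
        m[:d, d] = self.translation
        return m


def remove_rigid(t: AffineTransform) -> AffineTransform:
    """Strip rotation and translation, keeping the symmetric stretch.

    Polar-decomposes ``linear = R·S`` (rotation × SPD stretch) via SVD and
    returns the pure-stretch transform with zero translation. Used for the
    template's drift-free affine shape update.
    """
    u, s, vt = np.linalg.svd(t.linear)
    if np.linalg.det(u @ vt) < 0:  # keep R a proper rotation
        u = u.copy()
        u[:, -1] *= -1
        s = s.copy()
        s[-1] *= -1
    stretch = vt.T @ np.diag(s) @ vt
    return AffineTransform(stretch, np.zeros(t.ndim), converged=t.converged)


# ---------------------------------------------------------------------------
# similarity metrics (all minimized)
# ---------------------------------------------------------------------------


def _ssd(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _neg_ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float(-(a * b).sum() / denom)


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """Joint-histogram mutual information in nats (higher = more similar)."""
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    nz = p > 0
    outer = np.outer(px, py)
    return float((p[nz] * np.log(p[nz] / outer[nz])).sum())


def _neg_mi(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    return -mutual_information(a, b, bins=bins)


_METRICS = {"SSD": _ssd, "NCC": _neg_ncc, "MI": _neg_mi}


@dataclass
class RegistrationParams:
    """Multi-resolution schedule and regularization knobs.

    The default schedule runs three levels coarse-to-fine with a maximum of
    (30, 50, 20) cycles at downsampling factors (4, 2, 1). Sigmas are in
    voxels of the current level; ``step_length`` is the demons step in voxels,
    halved whenever a step would fold the grid.
    """

    levels: tuple[tuple[int, int], ...] = ((4, 30), (2, 50), (1, 20))
    metric: str = "SSD"
    smoothing_sigma_update: float = 1.5
    smoothing_sigma_field: float = 1.0
    step_length: float = 1.0
    mi_bins: int = 32

    def __post_init__(self) -> None:
        if any(it <= 0 for _, it in self.levels):
            raise ValueError("iterations per level must be positive")
        if self.metric not in _METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    @classmethod
    def fast_2d(cls, metric: str = "SSD") -> "RegistrationParams":
        # scaled-down schedule for slice-to-slice (2D) work
        return cls(levels=((4, 15), (2, 25), (1, 10)), metric=metric)


@dataclass
class RegistrationResult:
    """Forward/inverse displacement + affine component + similarity trace.

    ``forward`` satisfies ``warp(moving, forward) ≈ fixed``; ``inverse`` is
    its group inverse (exp of the negated velocity). ``velocity`` is the
    stationary velocity field, exposed so fractional transforms exp(t·v) can
    be formed (used by the slice interpolator).
    """

    forward: DisplacementField
    inverse: DisplacementField
    affine: AffineTransform
    metric_trace: list[float] = field(default_factory=list)
    converged: bool = True
    velocity: np.ndarray | None = None


# ---------------------------------------------------------------------------
# parametric registration
# ---------------------------------------------------------------------------


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return np.asarray(arr, dtype=np.float64)
    sm = ndimage.gaussian_filter(np.asarray(arr, dtype=np.float64), sigma=factor / 2.0)
    return ndimage.zoom(sm, 1.0 / factor, order=1)


def _rot2(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def _rot3(angles) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _params_to_transform(x: np.ndarray, ndim: int, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Parameter vector → (linear, translation-about-center)."""
    if ndim == 2:
        t = x[:2]
        rot = _rot2(x[2])
        if mode == "rigid":
            return rot, t
        scale = np.diag(np.exp(x[3:5]))
        shear = np.array([[1.0, x[5]], [0.0, 1.0]])
        return rot @ shear @ scale, t
    t = x[:3]
    rot = _rot3(x[3:6])
    if mode == "rigid":
        return rot, t
    scale = np.diag(np.exp(x[6:9]))
    shear = np.eye(3)
    shear[0, 1], shear[0, 2], shear[1, 2] = x[9], x[10], x[11]
    return rot @ shear @ scale, t


def _n_params(ndim: int, mode: str) -> int:
    if ndim == 2:
        return 3 if mode == "rigid" else 6
    return 6 if mode == "rigid" else 12


def _centered(linear: np.ndarray, t: np.ndarray, shape) -> AffineTransform:
    c = (np.asarray(shape, dtype=np.float64) - 1.0) / 2.0
    return AffineTransform(linear, t + c - linear @ c)


def _com_offset(fixed: np.ndarray, moving: np.ndarray) -> np.ndarray:
    """Center-of-mass translation initialization (pull-back convention)."""
    def com(arr):
        w = arr - arr.min()
        total = w.sum()
        if total <= 0:
            return (np.asarray(arr.shape, dtype=np.float64) - 1.0) / 2.0
        return np.array(ndimage.center_of_mass(w))

    return com(moving) - com(fixed)


def _register_parametric(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RegistrationParams,
    mode: str,
    fill: float,
) -> AffineTransform:
    ndim = fixed.ndim
    metric_fn = _METRICS[params.metric]
    x = np.zeros(_n_params(ndim, mode))
    x[:ndim] = _com_offset(fixed, moving)  # translation head start
    converged = True
    for factor, iters in params.levels:
        f_l = _downsample(fixed, factor)
        m_l = _downsample(moving, factor)

        big = max(f_l.shape)
        n_ang = 1 if ndim == 2 else 3
        t_bound = big / 6.0

        def cost(p, f_l=f_l, m_l=m_l, big=big, t_bound=t_bound):
            # capture-range bounds: inputs are roughly pre-aligned, so large
            # rotations (e.g. the point-reflection optimum on symmetric
            # objects), evictions and extreme scales/shears are excluded
            t_part = p[:ndim]
            angles = p[ndim : ndim + n_ang]
            rest = p[ndim + n_ang :]
            if (
                np.abs(t_part).max(initial=0.0) > t_bound
                or np.abs(angles).max(initial=0.0) > np.pi / 4.0
                or np.abs(rest).max(initial=0.0) > 0.5
            ):
                return 1e12
            linear, t = _params_to_transform(p, ndim, mode)
            tr = _centered(linear, t, f_l.shape)
            warped = tr.apply_to_array(m_l, output_shape=f_l.shape, fill=fill)
            # mild preference for the smallest transform: tie-breaks the flat
            # valleys of (near-)symmetric objects without biasing sharp optima
            pen = (
                (t_part**2).sum() / t_bound**2
                + (angles**2).sum() / (np.pi / 4.0) ** 2
                + (rest**2).sum() / 0.25
            )
            return metric_fn(f_l, warped) * (1.0 + 0.05 * pen)

        # translations live in voxels of the current level
        x0_level = x.copy()
        x0_level[:ndim] = x[:ndim] / factor
        res = optimize.minimize(
            cost,
            x0_level,
            method="Powell",
            options={"maxiter": min(iters, 12), "xtol": 1e-3, "ftol": 1e-7},
        )
        best = res.x if res.fun <= cost(x0_level) else x0_level
        x = np.asarray(best, dtype=np.float64).copy()
        x[:ndim] = x[:ndim] * factor
    linear, t = _params_to_transform(x, ndim, mode)
    out = _centered(linear, t, fixed.shape)
    # keep whichever of (identity, search result) scores better at full res
    final = metric_fn(fixed, out.apply_to_array(moving, output_shape=fixed.shape, fill=fill))
    initial = metric_fn(fixed, moving)
    if final > initial + 1e-9:
        logger.info("parametric search did not beat identity; keeping identity")
        out = AffineTransform.identity(ndim)
    # non-convergence = no shared foreground support at all (nothing to align)
    f_fg = fixed > fixed.min() + 0.05 * (np.ptp(fixed) + 1e-12)
    m_fg = moving > moving.min() + 0.05 * (np.ptp(moving) + 1e-12)
    if not np.logical_and(f_fg, m_fg).any():
        logger.warning("no overlapping content after coarse search; non-converged")
        return AffineTransform.identity(ndim, converged=False)
    out.converged = converged
    return out


def _as_array(v) -> np.ndarray:
    return v.voxels if isinstance(v, Volume) else np.asarray(v)


def _fill_for(v, fill: float | None) -> float:
    if fill is not None:
        return fill
    if isinstance(v, Volume) and v.modality == "CT":
        return -1000.0
    return 0.0


def register_rigid(
    fixed, moving, params: RegistrationParams | None = None, fill: float | None = None
) -> AffineTransform:
    """Rotation + translation aligning ``moving`` to ``fixed``."""
    fa, ma = _as_array(fixed), _as_array(moving)
    if fa.ndim != ma.ndim:
        raise ValueError("fixed and moving dimensionality differ")
    params = params or RegistrationParams()
    return _register_parametric(fa, ma, params, "rigid", _fill_for(moving, fill))


def register_affine(
    fixed, moving, params: RegistrationParams | None = None, fill: float | None = None
) -> AffineTransform:
    """Full affine (rotation, scale, shear, translation) alignment."""
    fa, ma = _as_array(fixed), _as_array(moving)
    if fa.ndim != ma.ndim:
        raise ValueError("fixed and moving dimensionality differ")
    params = params or RegistrationParams()
    return _register_parametric(fa, ma, params, "affine", _fill_for(moving, fill))


# ---------------------------------------------------------------------------
# diffeomorphic demons
# ---------------------------------------------------------------------------


def _normalize_pair(fixed: np.ndarray, moving: np.ndarray):
    lo = min(fixed.min(), moving.min())
    hi = max(fixed.max(), moving.max())
    if hi - lo < 1e-12:
        return fixed * 0.0, moving * 0.0, 0.0
    return (fixed - lo) / (hi - lo), (moving - lo) / (hi - lo), (lo, hi)


def _upscale_velocity(vel: np.ndarray, new_shape) -> np.ndarray:
    old_shape = vel.shape[:-1]
    zoom = [n / o for n, o in zip(new_shape, old_shape)]
    comps = []
    for c in range(vel.shape[-1]):
        comps.append(ndimage.zoom(vel[..., c], zoom, order=1) * zoom[c])
    out = np.stack(comps, axis=-1)
    # zoom can be off by one voxel; crop/pad to exact shape
    slices = tuple(slice(0, n) for n in new_shape)
    if out.shape[:-1] != tuple(new_shape):
        fixed_out = np.zeros((*new_shape, vel.shape[-1]))
        src = tuple(slice(0, min(a, b)) for a, b in zip(out.shape[:-1], new_shape))
        fixed_out[src] = out[src]
        out = fixed_out
    return out[slices]


def _smooth_field(vec: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return vec
    out = np.empty_like(vec)
    for c in range(vec.shape[-1]):
        out[..., c] = ndimage.gaussian_filter(vec[..., c], sigma=sigma)
    return out


def _conditional_lut(moving: np.ndarray, fixed: np.ndarray, bins: int = 64):
    """Intensity LUT mapping moving-intensity bins to the conditional mean of
    the fixed intensity — the intermodal reduction used by the MI demons."""
    lo, hi = moving.min(), moving.max()
    if hi - lo < 1e-12:
        return lambda m: np.full_like(m, fixed.mean())
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.digitize(moving.ravel(), edges) - 1, 0, bins - 1)
    sums = np.bincount(idx, weights=fixed.ravel(), minlength=bins)
    counts = np.bincount(idx, minlength=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    filled = counts > 0
    lut = np.interp(centers, centers[filled], sums[filled] / counts[filled])
    lut = ndimage.gaussian_filter1d(lut, 1.0)
    return lambda m: np.interp(m, centers, lut)


def register_demons_array(
    fixed: np.ndarray,
    moving: np.ndarray,
    params: RegistrationParams | None = None,
    intermodal: bool = False,
    lut_refresh: int = 10,
):
    """Stationary-velocity diffeomorphic demons on raw arrays (2D or 3D).

    Returns ``(velocity, metric_trace, converged)`` at the full resolution of
    ``fixed``. ``intermodal=True`` re-estimates a conditional-mean intensity
    mapping of the moving image every ``lut_refresh`` iterations and matches
    the remapped image by SSD (the trace is then SSD on remapped intensities).
    """
    params = params or RegistrationParams()
    f_norm, m_norm, rng_ = _normalize_pair(
        np.asarray(fixed, dtype=np.float64), np.asarray(moving, dtype=np.float64)
    )
    if rng_ == 0.0:
        zero = np.zeros((*fixed.shape, fixed.ndim))
        return zero, [0.0], True

    vel = None
    trace: list[float] = []
    converged = True
    for factor, iters in params.levels:
        f_l = _downsample(f_norm, factor)
        m_l = _downsample(m_norm, factor)
        if vel is None:
            vel = np.zeros((*f_l.shape, f_l.ndim))
        else:
            vel = _upscale_velocity(vel, f_l.shape)

        m_eff = m_l
        lut = None
        if intermodal:
            lut = _conditional_lut(m_l, f_l)
            m_eff = lut(m_l)

        step = params.step_length
        disp = exp_velocity(vel)
        warped = warp_array(m_eff, disp, fill=0.0)
        cost = _ssd(f_l, warped)
        stall = 0
        for it in range(iters):
            if intermodal and it > 0 and it % lut_refresh == 0:
                lut = _conditional_lut(m_l, f_l)  # refresh on current overlap
                m_eff = lut(m_l)
                warped = warp_array(m_eff, disp, fill=0.0)
                cost = _ssd(f_l, warped)
            diff = warped - f_l
            grad = np.stack(np.gradient(warped), axis=-1)
            gnorm2 = (grad**2).sum(axis=-1)
            denom = gnorm2 + diff**2
            with np.errstate(divide="ignore", invalid="ignore"):
                force = -(diff[..., None] * grad) / denom[..., None]
            force[~np.isfinite(force)] = 0.0
            update = _smooth_field(force, params.smoothing_sigma_update)
            mag = np.sqrt((update**2).sum(axis=-1)).max()
            if mag < 1e-6:
                break
            update = update / max(mag, 1.0)  # cap at 1 voxel before stepping

            accepted = False
            local_step = step
            for _attempt in range(4):
                vel_try = _smooth_field(vel + local_step * update, params.smoothing_sigma_field)
                disp_try = exp_velocity(vel_try)
                if jacobian_determinant(disp_try).min() <= 0:
                    local_step *= 0.5
                    continue
                warped_try = warp_array(m_eff, disp_try, fill=0.0)
                cost_try = _ssd(f_l, warped_try)
                if cost_try <= cost * (1.0 + 1e-9):
                    vel, disp, warped, cost = vel_try, disp_try, warped_try, cost_try
                    accepted = True
                    break
                local_step *= 0.5
            trace.append(cost)
            if not accepted:
                stall += 1
                if stall >= 3:
                    break
            else:
                stall = 0
    if vel is None:
        vel = np.zeros((*fixed.shape, fixed.ndim))
    if vel.shape[:-1] != fixed.shape:
        vel = _upscale_velocity(vel, fixed.shape)
    return vel, trace, converged


def register_diffeomorphic(
    fixed, moving, params: RegistrationParams | None = None
) -> RegistrationResult:
    """Diffeomorphic alignment of ``moving`` to ``fixed`` (same grid).

    The forward field satisfies ``warp(moving, forward) ≈ fixed``; the inverse
    is the exponential of the negated velocity, so forward∘inverse stays
    within interpolation tolerance of the identity.
    """
    fa, ma = _as_array(fixed), _as_array(moving)
    if fa.shape != ma.shape:
        raise ValueError(f"grids differ after pre-alignment: {fa.shape} vs {ma.shape}")
    params = params or RegistrationParams()
    intermodal = params.metric == "MI"
    vel, trace, conv = register_demons_array(fa, ma, params, intermodal=intermodal)
    spacing = fixed.spacing if isinstance(fixed, Volume) else (1.0,) * fa.ndim
    forward = DisplacementField(exp_velocity(vel), spacing=spacing)
    inverse = DisplacementField(exp_velocity(-vel), spacing=spacing)
    return RegistrationResult(
        forward=forward,
        inverse=inverse,
        affine=AffineTransform.identity(fa.ndim),
        metric_trace=trace,
        converged=conv,
        velocity=vel,
    )


def invert_field(f: DisplacementField, max_residual: float = 0.5) -> DisplacementField:
    """Fixed-point inversion of a diffeomorphic displacement field."""
    inv = invert_disp(f.vectors)
    residual = compose_disp(f.vectors, inv)
    res_mag = float(np.sqrt((residual**2).sum(axis=-1)).max())
    if res_mag > max_residual:
        raise ValueError(
            f"field inversion did not converge: composition residual "
            f"{res_mag:.3f} voxels exceeds {max_residual}"
        )
    return DisplacementField(inv, spacing=f.spacing)
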