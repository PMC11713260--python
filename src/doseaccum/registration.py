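"""Rigid and free-form deformable image registration.

The deformable engine is a multi-resolution, compositive demons-style
free-form registration: at each pyramid level a dense force field is
derived from the intensity mismatch, smoothed (fluid regularization),
composed into the running displacement field, and the total field is
smoothed again (diffusion regularization).  Two similarity options deal
with CT-vs-CBCT intensity mismatch: local intensity normalization
(a local-normalized-cross-correlation surrogate that is exactly
invariant to locally linear intensity maps) and global histogram
matching followed by mean-squares forces.

Displacement fields use the pull-back convention throughout: for each
voxel x of the *fixed* grid, u(x) is where (in mm, world coordinates)
the moving image is sampled, out(x) = moving(x + u(x)).  Rigid
transforms use the same convention (they are resampling maps, so the
transform recovered for a moving image whose anatomy was shifted by +s
is t = +s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation
from skimage.exposure import match_histograms

from .grid import DoseGrid, Grid, ImageVolume

__all__ = [
    "RigidTransform",
    "DisplacementField",
    "RegistrationParams",
    "JacobianReport",
    "rigid_register",
    "deformable_register",
    "apply_rigid",
    "apply_dvf",
    "compose",
    "invert_dvf",
    "jacobian_determinant",
]

_IMAGE_PAD_HU = -1000.0
_DOSE_PAD_GY = 0.0


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Rigid resampling map x -> R (x - c) + c + t (pull-back convention).

    ``rotation_deg`` are intrinsic x-y-z Euler angles in degrees about the
    rotation centre ``center_mm`` (defaults to the origin; registration
    uses the grid centre).
    """

    translation_mm: tuple[float, float, float]
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation_deg, degrees=True).as_matrix()

    def map_points(self, points_mm: np.ndarray) -> np.ndarray:
        """Apply the map to world points (N, 3)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        c = np.asarray(self.center_mm)
        return (p - c) @ self.matrix.T + c + np.asarray(self.translation_mm)

    def inverse(self) -> "RigidTransform":
        r = Rotation.from_euler("xyz", self.rotation_deg, degrees=True).inv()
        t = -r.apply(np.asarray(self.translation_mm))
        return RigidTransform(
            tuple(t), tuple(r.as_euler("xyz", degrees=True)), self.center_mm
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Map equivalent to applying ``self`` then ``other`` (x -> other(self(x)))."""
        if not np.allclose(self.center_mm, other.center_mm):
            raise ValueError("compose requires a common rotation centre")
        r1 = Rotation.from_euler("xyz", self.rotation_deg, degrees=True)
        r2 = Rotation.from_euler("xyz", other.rotation_deg, degrees=True)
        r = r2 * r1
        t = r2.apply(np.asarray(self.translation_mm)) + np.asarray(other.translation_mm)
        return RigidTransform(
            tuple(t), tuple(r.as_euler("xyz", degrees=True)), self.center_mm
        )

    @property
    def is_identity(self) -> bool:
        return (
            np.allclose(self.translation_mm, 0.0, atol=1e-12)
            and np.allclose(self.rotation_deg, 0.0, atol=1e-12)
        )


# ---------------------------------------------------------------------------
# displacement fields
# ---------------------------------------------------------------------------


@dataclass
class DisplacementField:
    """Dense per-voxel displacement (mm, pull-back) on a fixed-image grid."""

    grid: Grid
    vectors: np.ndarray  # shape grid.shape + (3,)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.shape != self.grid.shape + (3,):
            raise ValueError(
                f"vector field shape {self.vectors.shape} != {self.grid.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, grid: Grid) -> "DisplacementField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    @classmethod
    def from_constant(cls, grid: Grid, t_mm) -> "DisplacementField":
        v = np.zeros(grid.shape + (3,))
        v[...] = np.asarray(t_mm, dtype=float)
        return cls(grid, v)

    @classmethod
    def from_rigid(cls, grid: Grid, rigid: RigidTransform) -> "DisplacementField":
        xs, ys, zs = grid.coordinate_arrays()
        pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1)
        mapped = rigid.map_points(pts.reshape(-1, 3)).reshape(pts.shape)
        return cls(grid, mapped - pts)

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.vectors**2, axis=-1))

    def sample_at(self, points_mm: np.ndarray) -> np.ndarray:
        """Trilinear displacement (mm) at world points (N, 3); edge-clamped."""
        idx = self.grid.world_to_index(points_mm).T
        out = np.empty((idx.shape[1], 3))
        for c in range(3):
            out[:, c] = ndimage.map_coordinates(
                self.vectors[..., c], idx, order=1, mode="nearest"
            )
        return out


@dataclass
class RegistrationParams:
    """Knobs of the demons-style engine.

    ``iterations`` has one entry per pyramid level, coarsest first.
    Sigmas are in mm.  ``metric`` is ``"lncc"`` (local intensity
    normalization, window ``lncc_window_mm``) or ``"msq_histmatch"``
    (histogram matching then mean squares).
    """

    levels: int = 4
    iterations: tuple[int, ...] = (50, 50, 30, 20)
    update_sigma_mm: float = 4.0
    field_sigma_mm: float = 3.0
    metric: str = "lncc"
    lncc_window_mm: float = 12.0
    lncc_sd_floor: float = 0.15
    intensity_window: tuple[float, float] | None = (-300.0, 300.0)
    convergence_tol: float = 1e-4
    convergence_window: int = 5
    restrict_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("pyramid must have >= 1 level")
        if len(self.iterations) != self.levels:
            raise ValueError("need one iteration count per level")
        if self.update_sigma_mm < 0 or self.field_sigma_mm < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.metric not in ("lncc", "msq_histmatch"):
            raise ValueError(f"unknown metric {self.metric!r}")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def _resample_values(
    values: np.ndarray,
    grid: Grid,
    sample_points_idx: np.ndarray,
    order: int,
    cval: float,
) -> np.ndarray:
    return ndimage.map_coordinates(
        values, sample_points_idx, order=order, mode="constant", cval=cval
    )


def _index_mesh(grid: Grid) -> np.ndarray:
    return np.stack(
        np.meshgrid(*[np.arange(n, dtype=float) for n in grid.shape], indexing="ij"),
        axis=0,
    )


def _sample_index_coords(grid: Grid, dvf: DisplacementField) -> np.ndarray:
    """Fractional index coords of x + u(x) for every voxel x."""
    coords = _index_mesh(grid)
    for c in range(3):
        coords[c] = coords[c] + dvf.vectors[..., c] / grid.spacing[c]
    return coords


def apply_rigid(volume, rigid: RigidTransform, cval: float | None = None):
    """Resample a volume / dose / mask through a rigid map (pull-back)."""
    dvf = DisplacementField.from_rigid(_grid_of(volume), rigid)
    return apply_dvf(volume, dvf, cval=cval)


def _grid_of(obj) -> Grid:
    if isinstance(obj, (ImageVolume, DoseGrid)):
        return obj.grid
    raise TypeError("bare arrays need an explicit grid; wrap them or use warp_mask")


def apply_dvf(
    volume,
    dvf: DisplacementField,
    interpolation: str = "trilinear",
    cval: float | None = None,
):
    """Warp an ImageVolume or DoseGrid: out(x) = in(x + u(x)).

    Out-of-bounds samples take the declared padding (-1000 HU for
    images, 0 Gy for dose).  For binary masks use :func:`warp_mask`.
    """
    if isinstance(volume, np.ndarray):
        return warp_mask(volume, dvf, interpolation=interpolation)
    grid = _grid_of(volume)
    grid.require_same_geometry(dvf.grid, "volume vs displacement field")
    coords = _sample_index_coords(grid, dvf)
    order = 0 if interpolation == "nearest" else 1
    if isinstance(volume, ImageVolume):
        pad = _IMAGE_PAD_HU if cval is None else cval
        out = _resample_values(
            volume.values.astype(np.float64), grid, coords, order, pad
        )
        return ImageVolume(grid, out, role=volume.role, metadata=dict(volume.metadata))
    pad = _DOSE_PAD_GY if cval is None else cval
    out = _resample_values(volume.values, grid, coords, order, pad)
    return DoseGrid(grid, np.clip(out, 0.0, None), role=volume.role)


def warp_mask(
    mask: np.ndarray,
    dvf: DisplacementField,
    interpolation: str = "linear_threshold",
    threshold: float = 0.5,
) -> np.ndarray:
    """Warp a binary mask; linear interpolation thresholded at 0.5 by default."""
    if mask.shape != dvf.grid.shape:
        raise ValueError("mask shape does not match displacement-field grid")
    coords = _sample_index_coords(dvf.grid, dvf)
    if interpolation == "nearest":
        out = _resample_values(mask.astype(np.float64), dvf.grid, coords, 0, 0.0) > 0.5
    elif interpolation in ("linear_threshold", "trilinear"):
        out = (
            _resample_values(mask.astype(np.float64), dvf.grid, coords, 1, 0.0)
            >= threshold
        )
    else:
        raise ValueError(f"unknown mask interpolation {interpolation!r}")
    if mask.any() and not out.any():
        warnings.warn("mask warped entirely out of the grid; result is empty")
    return out


def compose(dvf_ab: DisplacementField, dvf_bc: DisplacementField) -> DisplacementField:
    """Field w with warp(v, w) == warp(warp(v, bc), ab): w(x) = ab(x) + bc(x + ab(x))."""
    dvf_ab.grid.require_same_geometry(dvf_bc.grid, "displacement fields")
    coords = _sample_index_coords(dvf_ab.grid, dvf_ab)
    out = np.empty_like(dvf_ab.vectors)
    for c in range(3):
        out[..., c] = dvf_ab.vectors[..., c] + ndimage.map_coordinates(
            dvf_bc.vectors[..., c], coords, order=1, mode="nearest"
        )
    return DisplacementField(dvf_ab.grid, out)


def invert_dvf(
    dvf: DisplacementField, tol_mm: float = 0.05, max_iter: int = 50
) -> DisplacementField:
    """Fixed-point inverse: find g with u(x + g(x)) + g(x) = 0.

    Emits a warning (with residual statistics) if the residual tolerance
    is not met on at least 99% of voxels.
    """
    grid = dvf.grid
    g = -dvf.vectors.copy()
    for _ in range(max_iter):
        coords = _sample_index_coords(grid, DisplacementField(grid, g))
        u_at = np.empty_like(g)
        for c in range(3):
            u_at[..., c] = ndimage.map_coordinates(
                dvf.vectors[..., c], coords, order=1, mode="nearest"
            )
        g_new = -u_at
        step = np.max(np.abs(g_new - g))
        g = g_new
        if step < 0.1 * tol_mm:
            break
    coords = _sample_index_coords(grid, DisplacementField(grid, g))
    res = np.empty_like(g)
    for c in range(3):
        res[..., c] = ndimage.map_coordinates(
            dvf.vectors[..., c], coords, order=1, mode="nearest"
        )
    residual = np.sqrt(np.sum((res + g) ** 2, axis=-1))
    frac_ok = float(np.mean(residual <= tol_mm))
    if frac_ok < 0.99:
        warnings.warn(
            "DVF inversion residual > "
            f"{tol_mm} mm on {100 * (1 - frac_ok):.1f}% of voxels "
            f"(max {residual.max():.3f} mm, mean {residual.mean():.3f} mm)"
        )
    return DisplacementField(grid, g)


@dataclass
class JacobianReport:
    """Determinant of I + grad(u) and its QA summary."""

    values: np.ndarray
    min: float
    max: float
    fraction_nonpositive: float


def jacobian_determinant(dvf: DisplacementField) -> JacobianReport:
    """Central-difference Jacobian determinant of the map x -> x + u(x)."""
    g = dvf.grid
    grads = np.empty(g.shape + (3, 3))
    for i in range(3):
        gi = np.gradient(dvf.vectors[..., i], *g.spacing, edge_order=1)
        for j in range(3):
            grads[..., i, j] = gi[j]
    jac = grads + np.eye(3)
    det = np.linalg.det(jac)
    return JacobianReport(
        values=det,
        min=float(det.min()),
        max=float(det.max()),
        fraction_nonpositive=float(np.mean(det <= 0)),
    )


# ---------------------------------------------------------------------------
# rigid registration
# ---------------------------------------------------------------------------


def _check_registerable(fixed: ImageVolume, moving: ImageVolume) -> None:
    for name, vol in (("fixed", fixed), ("moving", moving)):
        if float(np.std(vol.values)) < 1e-6:
            raise ValueError(f"{name} image is constant; registration is degenerate")
    lo_f = np.asarray(fixed.grid.origin)
    hi_f = lo_f + np.asarray(fixed.grid.extent_mm)
    lo_m = np.asarray(moving.grid.origin)
    hi_m = lo_m + np.asarray(moving.grid.extent_mm)
    if np.any(np.minimum(hi_f, hi_m) <= np.maximum(lo_f, lo_m)):
        raise ValueError("fixed and moving physical extents do not overlap")


def _downsample(values: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return values
    sm = ndimage.gaussian_filter(values, sigma=0.5 * factor)
    return sm[::factor, ::factor, ::factor]


def _ncc_cost(a: np.ndarray, b: np.ndarray, mask: np.ndarray | None) -> float:
    if mask is not None:
        a = a[mask]
        b = b[mask]
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 1.0
    return 1.0 - float((a * b).sum() / denom)


def rigid_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    mask: np.ndarray | None = None,
    dof: str = "translation",
    body_threshold_hu: float = -600.0,
) -> RigidTransform:
    """Intensity-based rigid initialization (negative NCC, Powell).

    ``dof`` is ``"translation"`` (default; matches the interfraction
    setup-shift model) or ``"rigid"`` (adds three small Euler angles).
    Unless a mask is given, the metric is restricted to fixed-image
    voxels above ``body_threshold_hu`` so limited-FOV padding does not
    bias the alignment.  Deterministic: the optimizer has no stochastic
    component.
    """
    from scipy.optimize import minimize

    _check_registerable(fixed, moving)
    fixed.grid.require_same_geometry(moving.grid, "fixed vs moving")
    grid = fixed.grid
    center = tuple(grid.center_mm)

    if mask is None:
        candidate = fixed.values > body_threshold_hu
        if candidate.any() and not candidate.all():
            mask = candidate

    n_par = 3 if dof == "translation" else 6

    def cost_at_scale(factor: int):
        f = _downsample(fixed.values.astype(np.float64), factor)
        m_full = moving.values.astype(np.float64)
        msk = None
        if mask is not None:
            msk = mask[::factor, ::factor, ::factor] if factor > 1 else mask
        sub_grid = Grid(
            f.shape,
            tuple(s * factor for s in grid.spacing),
            grid.origin,
        )
        base = _index_mesh(sub_grid)

        def cost(p):
            t = p[:3]
            rot = p[3:6] if n_par == 6 else (0.0, 0.0, 0.0)
            rigid = RigidTransform(tuple(t), tuple(rot), center)
            xs, ys, zs = sub_grid.coordinate_arrays()
            pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1)
            mapped = rigid.map_points(pts.reshape(-1, 3)).reshape(pts.shape)
            coords = np.empty_like(base)
            valid = np.ones(f.shape, bool)
            for c in range(3):
                coords[c] = (mapped[..., c] - grid.origin[c]) / grid.spacing[c]
                valid &= (coords[c] >= 0) & (coords[c] <= grid.shape[c] - 1)
            if valid.mean() < 0.25:  # almost no overlap left
                return 1.0
            res = ndimage.map_coordinates(
                m_full, coords, order=1, mode="constant", cval=_IMAGE_PAD_HU
            )
            # correlate only where the moving image was actually sampled
            m2 = valid if msk is None else (msk & valid)
            return _ncc_cost(f, res, m2)

        return cost

    p = np.zeros(n_par)
    max_side = max(grid.shape)
    factors = [f for f in (4, 2, 1) if max_side // f >= 16]
    for factor in factors or [1]:
        cost = cost_at_scale(factor)
        res = minimize(
            cost,
            p,
            method="Powell",
            options={"xtol": 1e-3, "ftol": 1e-6, "maxiter": 2000},
        )
        p = res.x
    t = tuple(float(v) for v in p[:3])
    rot = tuple(float(v) for v in p[3:6]) if n_par == 6 else (0.0, 0.0, 0.0)
    return RigidTransform(t, rot, center)


# ---------------------------------------------------------------------------
# deformable registration (demons-style)
# ---------------------------------------------------------------------------


def _local_normalize(
    values: np.ndarray, sigma_vox: np.ndarray, sd_floor_frac: float = 0.2
) -> np.ndarray:
    """Subtract the local mean and divide by the local SD.

    The divisor is floored at ``sd_floor_frac`` x the global SD so that
    flat, noise-dominated regions are damped instead of being amplified
    to unit contrast (CBCT noise would otherwise drive spurious forces).
    """
    mu = ndimage.gaussian_filter(values, sigma_vox)
    var = ndimage.gaussian_filter(values**2, sigma_vox) - mu**2
    sd = np.sqrt(np.clip(var, 0.0, None))
    floor = sd_floor_frac * max(1e-12, float(np.std(values)))
    return (values - mu) / np.maximum(sd, floor)


def _pyramid_level(values: np.ndarray, factor: int) -> np.ndarray:
    return _downsample(values, factor)


def deformable_register(
    fixed: ImageVolume,
    moving: ImageVolume,
    params: RegistrationParams | None = None,
    init: RigidTransform | None = None,
) -> DisplacementField:
    """Multi-resolution demons-style free-form registration.

    Returns the total pull-back displacement field on the fixed grid,
    including the rigid initialization.  The best-metric field seen at
    the finest level is returned; if the iteration budget ends without
    convergence a warning is emitted.
    """
    params = params or RegistrationParams()
    _check_registerable(fixed, moving)
    fixed.grid.require_same_geometry(moving.grid, "fixed vs moving")
    grid = fixed.grid
    spacing = np.asarray(grid.spacing)

    moving_init = apply_rigid(moving, init) if init is not None and not init.is_identity else moving

    if params.restrict_mask is None and "fov_mask" in fixed.metadata:
        # limited-FOV acquisitions: only in-FOV voxels may drive the forces
        params = replace(params, restrict_mask=np.asarray(fixed.metadata["fov_mask"], bool))

    f_full = fixed.values.astype(np.float64)
    m_full = moving_init.values.astype(np.float64)
    if params.restrict_mask is not None:
        # outside the mask the fixed image carries no usable data (e.g. FOV
        # padding): substitute the moving content so the mismatch — and any
        # force leaking through pyramid smoothing — vanishes there exactly
        f_full = np.where(params.restrict_mask.astype(bool), f_full, m_full)

    factors = [2 ** (params.levels - 1 - i) for i in range(params.levels)]
    factors = [f for f in factors if min(grid.shape) // f >= 8] or [1]

    u = None  # field at the current level, shape level_shape + (3,)
    prev_level_grid = None
    best_u_fine = None
    best_metric_fine = np.inf
    converged = False

    for level_i, factor in enumerate(factors):
        f_lvl = _pyramid_level(f_full, factor)
        m_lvl = _pyramid_level(m_full, factor)
        lvl_grid = Grid(f_lvl.shape, tuple(spacing * factor), grid.origin)
        lvl_spacing = np.asarray(lvl_grid.spacing)

        mask_lvl = None
        if params.restrict_mask is not None:
            mask_lvl = (
                params.restrict_mask[::factor, ::factor, ::factor]
                if factor > 1
                else params.restrict_mask
            ).astype(bool)

        if params.metric == "lncc":
            if params.intensity_window is not None:
                lo, hi = params.intensity_window
                f_lvl = np.clip(f_lvl, lo, hi)
                m_lvl = np.clip(m_lvl, lo, hi)
            sig = params.lncc_window_mm / (2.0 * lvl_spacing)
            f_p = _local_normalize(f_lvl, sig, params.lncc_sd_floor)
            m_p = _local_normalize(m_lvl, sig, params.lncc_sd_floor)
        else:
            m_p = match_histograms(m_lvl, f_lvl)
            f_p = f_lvl

        # carry the field up from the previous level
        if u is None:
            u = np.zeros(f_lvl.shape + (3,))
        else:
            new_u = np.empty(f_lvl.shape + (3,))
            zoom = [
                f_lvl.shape[d] / u.shape[d] for d in range(3)
            ]
            for c in range(3):
                new_u[..., c] = ndimage.zoom(u[..., c], zoom, order=1)
            u = new_u

        grad_f = np.gradient(f_p, *lvl_spacing)
        k2 = float(np.mean(lvl_spacing)) ** 2
        upd_sigma = params.update_sigma_mm / lvl_spacing
        fld_sigma = params.field_sigma_mm / lvl_spacing

        n_iter = params.iterations[level_i if level_i < len(params.iterations) else -1]
        metric_hist: list[float] = []
        best_metric = np.inf
        best_u = u.copy()
        finest = factor == factors[-1]

        for _ in range(n_iter):
            dvf_lvl = DisplacementField(lvl_grid, u)
            coords = _sample_index_coords(lvl_grid, dvf_lvl)
            m_w = ndimage.map_coordinates(
                m_p, coords, order=1, mode="constant", cval=0.0
            )
            diff = m_w - f_p
            if mask_lvl is not None:
                diff = diff * mask_lvl
            metric = float(np.mean(diff**2))
            if not np.isfinite(metric):
                raise FloatingPointError("NaN/inf in registration metric")
            metric_hist.append(metric)
            if metric < best_metric:
                best_metric = metric
                best_u = u.copy()

            grad_m = np.gradient(m_w, *lvl_spacing)
            step = np.empty(u.shape)
            gmag2 = np.zeros_like(diff)
            grads_j = []
            for c in range(3):
                gj = 0.5 * (grad_f[c] + grad_m[c])
                grads_j.append(gj)
                gmag2 += gj * gj
            denom = gmag2 + diff**2 / k2
            scale = np.where(denom > 1e-12, -diff / np.maximum(denom, 1e-12), 0.0)
            for c in range(3):
                step[..., c] = scale * grads_j[c]
            if params.update_sigma_mm > 0:
                for c in range(3):
                    step[..., c] = ndimage.gaussian_filter(step[..., c], upd_sigma)
            # compositive update: u <- step o u
            step_dvf = DisplacementField(lvl_grid, step)
            u = compose(step_dvf, DisplacementField(lvl_grid, u)).vectors
            if params.field_sigma_mm > 0:
                for c in range(3):
                    u[..., c] = ndimage.gaussian_filter(u[..., c], fld_sigma)

            w = params.convergence_window
            if len(metric_hist) > w:
                past = metric_hist[-w - 1]
                if past > 0 and (past - metric_hist[-1]) / past < params.convergence_tol:
                    if finest:
                        converged = True
                    break

        u = best_u
        if finest:
            best_metric_fine = best_metric
            best_u_fine = best_u

    if not converged and np.isfinite(best_metric_fine):
        warnings.warn(
            "deformable registration hit its iteration budget before the "
            f"convergence tolerance; returning best field (metric {best_metric_fine:.4g})"
        )
    u = best_u_fine if best_u_fine is not None else u

    # upsample to the full grid if the finest level was decimated
    if u.shape[:3] != grid.shape:
        new_u = np.empty(grid.shape + (3,))
        zoom = [grid.shape[d] / u.shape[d] for d in range(3)]
        for c in range(3):
            new_u[..., c] = ndimage.zoom(u[..., c], zoom, order=1)
        u = new_u

    demons = DisplacementField(grid, u)
    if init is not None and not init.is_identity:
        # total map: x -> rigid(x + u(x));  u_total(x) = rigid(x + u(x)) - x
        xs, ys, zs = grid.coordinate_arrays()
        pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1)
        warped_pts = pts + demons.vectors
        mapped = init.map_points(warped_pts.reshape(-1, 3)).reshape(pts.shape)
        return DisplacementField(grid, mapped - pts)
    return demons
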