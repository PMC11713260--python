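"""Synthetic deformable pelvis phantoms with known ground truth.

The generator emulates the imaging side of a fractionated pelvic
radiotherapy course: a planning CT of a pelvis (body, bony ring,
bladder, rectum, uterus/cervix target), five weekly CBCTs in which the
bladder fills or empties, the patient is set up with a small rigid
offset, rectal gas comes and goes, and the image itself is degraded
(contrast loss, noise, shading, limited field of view).

Every weekly anatomy is produced by a closed-form diffeomorphism —
a radial bladder expansion/contraction with Gaussian falloff composed
with a rigid shift — so downstream registration and dose-warping
accuracy can be scored against exact ground truth: displacement fields,
deformed masks, and landmark positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .grid import Grid, ImageVolume
from .registration import DisplacementField
from .structures import StructureSet

__all__ = [
    "WeeklyParams",
    "PhantomConfig",
    "AnalyticDeformation",
    "GroundTruth",
    "generate_planning_ct",
    "generate_weekly_series",
    "generate_plan",
]

_REQUIRED_HU_ORDER = ["air", "gas", "fat", "bladder", "muscle", "trabecular", "cortical"]


@dataclass(frozen=True)
class WeeklyParams:
    """One week's anatomical change and setup error.

    ``bladder_scale`` is the target bladder *volume* ratio relative to
    planning; ``shift_mm`` the rigid setup offset; ``gas_pocket`` an
    optional (offset_mm_from_rectum_fid, radius_mm) rectal gas bubble.
    """

    bladder_scale: float = 1.0
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gas_pocket: tuple[tuple[float, float, float], float] | None = None


def _default_weeks() -> tuple[WeeklyParams, ...]:
    # Interfraction variation without a bladder-filling protocol: volume
    # ratios spanning filling and emptying, few-mm setup shifts, and
    # occasional rectal gas.
    return (
        WeeklyParams(1.8, (2.0, -1.0, 1.0)),
        WeeklyParams(1.4, (-3.0, 2.0, 0.0), (((0.0, 0.0, 30.0)), 9.0)),
        WeeklyParams(0.65, (1.0, 3.0, -2.0)),
        WeeklyParams(1.25, (0.0, -2.0, 2.0), (((0.0, 0.0, -25.0)), 8.0)),
        WeeklyParams(0.8, (-2.0, 1.0, -1.0)),
    )


def _default_hu() -> dict[str, float]:
    # Planning-CT tissue values from the example-patient ROI table;
    # rectum contents / target are design choices (soft-tissue range).
    return {
        "air": -1000.0,
        "gas": -950.0,
        "fat": -97.9,
        "bladder": 11.4,
        "muscle": 46.9,
        "trabecular": 143.1,
        "cortical": 851.0,
        "rectum": 25.0,
        "target": 55.0,
    }


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of the synthetic patient and imaging protocol."""

    grid_shape: tuple[int, int, int] = (96, 96, 64)
    spacing_mm: tuple[float, float, float] = (5.0, 5.0, 4.0)
    # anatomy (offsets are mm from the grid centre; -y is anterior)
    body_semi_axes_mm: tuple[float, float] = (175.0, 120.0)
    bladder_center_mm: tuple[float, float, float] = (0.0, -47.0, 0.0)
    bladder_axis_ratios: tuple[float, float, float] = (0.95, 0.85, 1.2)
    bladder_volume_cc: float = 89.0
    rectum_center_xy_mm: tuple[float, float] = (0.0, 55.0)
    rectum_radius_mm: float = 13.0
    rectum_half_length_mm: float = 70.0
    target_center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    target_semi_axes_mm: tuple[float, float, float] = (24.0, 20.0, 34.0)
    bone_outer_semi_axes_mm: tuple[float, float] = (150.0, 105.0)
    bone_cortical_frac: float = 0.88   # inner edge of cortical shell
    bone_trabecular_frac: float = 0.80  # inner edge of trabecular layer
    bone_half_length_mm: float = 55.0
    ptv_margin_mm: float = 7.0
    hu_map: dict[str, float] = field(default_factory=_default_hu)
    # weekly change + deformation model
    weekly_params: tuple[WeeklyParams, ...] = field(default_factory=_default_weeks)
    deform_sigma_mm: float = 50.0
    # CBCT acquisition model
    cbct_fov_diameter_mm: float = 465.0
    cbct_fov_longitudinal_mm: float = 160.0
    cbct_noise_sd: float = 15.0
    cbct_contrast_scale: float = 0.9
    cbct_shading_amplitude: float = 25.0
    fov_pad_hu: float = -1000.0
    seed: int = 20240925

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if not 10.0 <= self.bladder_volume_cc <= 500.0:
            raise ValueError(
                f"bladder volume {self.bladder_volume_cc} cc outside supported 10-500 cc"
            )
        ext = [n * s for n, s in zip(self.grid_shape, self.spacing_mm)]
        if min(ext[0], ext[1]) < self.cbct_fov_diameter_mm or ext[2] < self.cbct_fov_longitudinal_mm:
            raise ValueError(
                f"grid extent {ext} mm smaller than CBCT FOV "
                f"({self.cbct_fov_diameter_mm} x {self.cbct_fov_longitudinal_mm} mm)"
            )
        hv = [self.hu_map[k] for k in _REQUIRED_HU_ORDER]
        if not all(np.isfinite(hv)):
            raise ValueError("HU map values must be finite")
        if not all(a < b for a, b in zip(hv, hv[1:])):
            raise ValueError(
                "HU ordering air < gas < fat < bladder < muscle < trabecular "
                f"< cortical violated: {dict(zip(_REQUIRED_HU_ORDER, hv))}"
            )

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing_mm)


# ---------------------------------------------------------------------------
# analytic deformation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticDeformation:
    """Radial Gaussian-falloff scaling about a centre, then a rigid shift.

    Forward map: phi(x) = c + rho(r) * (x - c)/r + t  with
    rho(r) = r * (1 + (lam - 1) exp(-r^2 / (2 sigma^2))).
    Diffeomorphic iff rho'(r) > 0 everywhere, which bounds lam < ~3.24
    for expansion.
    """

    center_mm: tuple[float, float, float]
    lam: float
    sigma_mm: float
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def _rho(self, r: np.ndarray) -> np.ndarray:
        return r * (1.0 + (self.lam - 1.0) * np.exp(-(r**2) / (2 * self.sigma_mm**2)))

    def _drho(self, r: np.ndarray) -> np.ndarray:
        t = r**2 / self.sigma_mm**2
        return 1.0 + (self.lam - 1.0) * np.exp(-t / 2.0) * (1.0 - t)

    def check_diffeomorphic(self) -> None:
        r = np.linspace(0.0, 5.0 * self.sigma_mm, 2001)
        if np.min(self._drho(r)) <= 0:
            raise ValueError(
                f"deformation too strong: radial derivative <= 0 (lam={self.lam:.3f})"
            )

    def forward(self, points_mm: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        c = np.asarray(self.center_mm)
        d = p - c
        r = np.linalg.norm(d, axis=-1)
        safe = np.where(r > 1e-12, r, 1.0)
        scale = np.where(r > 1e-12, self._rho(r) / safe, self.lam)
        return c + d * scale[..., None] + np.asarray(self.shift_mm)

    def inverse(self, points_mm: np.ndarray) -> np.ndarray:
        """Newton inversion of the monotone radial profile (exact to ~1e-10 mm)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float)) - np.asarray(self.shift_mm)
        c = np.asarray(self.center_mm)
        d = p - c
        s = np.linalg.norm(d, axis=-1)
        r = s.copy()
        for _ in range(60):
            f = self._rho(r) - s
            r_new = r - f / self._drho(r)
            r_new = np.clip(r_new, 0.0, None)
            if np.max(np.abs(r_new - r)) < 1e-12:
                r = r_new
                break
            r = r_new
        safe = np.where(s > 1e-12, s, 1.0)
        scale = np.where(s > 1e-12, r / safe, 1.0 / self.lam)
        return c + d * scale[..., None]

    def jacobian_det(self, points_mm: np.ndarray) -> np.ndarray:
        """det D(phi) = rho'(r) * (rho(r)/r)^2 (the shift is volume-preserving)."""
        p = np.atleast_2d(np.asarray(points_mm, dtype=float))
        r = np.linalg.norm(p - np.asarray(self.center_mm), axis=-1)
        safe = np.where(r > 1e-12, r, 1.0)
        ratio = np.where(r > 1e-12, self._rho(r) / safe, self.lam)
        return self._drho(r) * ratio**2

    def pullback_field(self, grid: Grid) -> DisplacementField:
        """u(y) = phi^{-1}(y) - y, the field that warps planning data onto this week."""
        xs, ys, zs = grid.coordinate_arrays()
        pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1)
        flat = pts.reshape(-1, 3)
        u = self.inverse(flat) - flat
        return DisplacementField(grid, u.reshape(pts.shape))


@dataclass
class GroundTruth:
    """Exact weekly anatomy: fields, masks, landmarks, and the maps themselves."""

    dvf_true: list[DisplacementField]
    masks_true: list[StructureSet]
    landmarks_true: list[dict[str, np.ndarray]]
    deformations: list[AnalyticDeformation]


# ---------------------------------------------------------------------------
# planning CT
# ---------------------------------------------------------------------------


def _ellipsoid_mask(grid: Grid, center, semi_axes) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 + ((zs - cz) / az) ** 2 <= 1.0


def _elliptic_cylinder(grid: Grid, center_xy, semi_axes_xy, half_len=None) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    cx, cy = center_xy
    ax, ay = semi_axes_xy
    m = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0
    if half_len is not None:
        zc = grid.center_mm[2]
        m = m & (np.abs(zs - zc) <= half_len)
    return np.broadcast_to(m, grid.shape).copy() if m.shape != grid.shape else m


def _bladder_semi_axes(config: PhantomConfig, volume_cc: float) -> np.ndarray:
    ratios = np.asarray(config.bladder_axis_ratios, dtype=float)
    r3 = volume_cc * 1000.0 / (4.0 / 3.0 * np.pi * np.prod(ratios))
    return ratios * r3 ** (1.0 / 3.0)


def generate_planning_ct(config: PhantomConfig) -> tuple[ImageVolume, StructureSet]:
    """Paint the planning CT and its ground-truth structure set.

    Deterministic (no noise on the planning CT): ROI means over painted
    regions equal the configured HU exactly.
    """
    grid = config.grid
    c0 = grid.center_mm
    hu = config.hu_map

    body = _elliptic_cylinder(grid, (c0[0], c0[1]), config.body_semi_axes_mm)

    bl_center = c0 + np.asarray(config.bladder_center_mm)
    bl_axes = _bladder_semi_axes(config, config.bladder_volume_cc)
    bladder = _ellipsoid_mask(grid, bl_center, bl_axes)

    rect_xy = (c0[0] + config.rectum_center_xy_mm[0], c0[1] + config.rectum_center_xy_mm[1])
    rectum = _elliptic_cylinder(
        grid, rect_xy, (config.rectum_radius_mm, config.rectum_radius_mm),
        half_len=config.rectum_half_length_mm,
    )

    tgt_center = c0 + np.asarray(config.target_center_mm)
    target = _ellipsoid_mask(grid, tgt_center, config.target_semi_axes_mm)

    out_ax = np.asarray(config.bone_outer_semi_axes_mm)
    bone_outer = _elliptic_cylinder(grid, (c0[0], c0[1]), out_ax, config.bone_half_length_mm)
    cort_inner = _elliptic_cylinder(
        grid, (c0[0], c0[1]), out_ax * config.bone_cortical_frac, config.bone_half_length_mm
    )
    trab_inner = _elliptic_cylinder(
        grid, (c0[0], c0[1]), out_ax * config.bone_trabecular_frac, config.bone_half_length_mm
    )
    cortical = bone_outer & ~cort_inner
    trabecular = cort_inner & ~trab_inner
    bones = cortical | trabecular

    organs = {"bladder": bladder, "rectum": rectum, "target": target, "bones": bones}
    names = list(organs)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.any(organs[a] & organs[b]):
                raise ValueError(f"structure placement collision: {a} overlaps {b}")

    muscle_core = _elliptic_cylinder(
        grid, (c0[0], c0[1]), out_ax * config.bone_trabecular_frac * 0.98
    )

    values = np.full(grid.shape, hu["air"], dtype=np.float32)
    values[body] = hu["fat"]
    values[body & muscle_core] = hu["muscle"]
    values[trabecular] = hu["trabecular"]
    values[cortical] = hu["cortical"]
    values[bladder] = hu["bladder"]
    values[rectum] = hu["rectum"]
    values[target] = hu["target"]

    mask_vol = float(np.count_nonzero(bladder)) * grid.voxel_volume_cc
    if abs(mask_vol - config.bladder_volume_cc) / config.bladder_volume_cc > 0.05:
        raise ValueError(
            f"voxelized bladder volume {mask_vol:.1f} cc deviates > 5% from "
            f"target {config.bladder_volume_cc} cc; refine the grid"
        )

    # PTV = target + isotropic margin (distance dilation)
    dist = ndimage.distance_transform_edt(~target, sampling=grid.spacing)
    ptv45 = dist <= config.ptv_margin_mm

    landmarks = {
        "bladder_centroid": bl_center.copy(),
        "bladder_anterior": bl_center + np.array([0.0, -bl_axes[1], 0.0]),
        "bladder_superior": bl_center + np.array([0.0, 0.0, bl_axes[2]]),
        "rectum_fiducial": np.array([rect_xy[0], rect_xy[1], c0[2]]),
        "target_centroid": tgt_center.copy(),
    }

    structs = StructureSet(
        grid,
        masks={
            "body": body, "bones": bones, "bladder": bladder,
            "rectum": rectum, "target": target, "ptv45": ptv45,
        },
        landmarks=landmarks,
        provenance="ground_truth",
    )
    pct = ImageVolume(grid, values, role="pCT")
    return pct, structs


# ---------------------------------------------------------------------------
# weekly series
# ---------------------------------------------------------------------------


def _solve_lambda(config: PhantomConfig, bladder_mask: np.ndarray, grid: Grid,
                  volume_scale: float) -> float:
    """Linear centre-scale lam achieving the requested bladder volume ratio.

    Solves  integral_bladder |det D phi_lam| dx = scale * V_bladder  by
    quadrature over the mask voxels (deterministic).
    """
    if volume_scale <= 0:
        raise ValueError("bladder volume scale must be positive")
    if abs(volume_scale - 1.0) < 1e-12:
        return 1.0
    c0 = grid.center_mm
    center = tuple(c0 + np.asarray(config.bladder_center_mm))
    idx = np.argwhere(bladder_mask)
    pts = grid.index_to_world(idx)

    def warped_ratio(lam: float) -> float:
        d = AnalyticDeformation(center, lam, config.deform_sigma_mm)
        return float(np.mean(d.jacobian_det(pts)))

    f = lambda lam: warped_ratio(lam) - volume_scale
    lo, hi = (1e-3, 1.0) if volume_scale < 1.0 else (1.0, 3.2)
    if f(lo) * f(hi) > 0:
        raise ValueError(
            f"bladder volume scale {volume_scale} not reachable by a "
            "diffeomorphic radial deformation with the configured falloff"
        )
    return float(brentq(f, lo, hi, xtol=1e-8))


def _fov_mask(grid: Grid, config: PhantomConfig) -> np.ndarray:
    xs, ys, zs = grid.coordinate_arrays()
    c = grid.center_mm
    rad2 = (xs - c[0]) ** 2 + (ys - c[1]) ** 2
    trans = rad2 <= (config.cbct_fov_diameter_mm / 2.0) ** 2
    longi = np.abs(zs - c[2]) <= config.cbct_fov_longitudinal_mm / 2.0
    return np.broadcast_to(trans & longi, grid.shape).copy()


def degrade_to_cbct(
    volume: ImageVolume, config: PhantomConfig, rng: np.random.Generator
) -> ImageVolume:
    """Apply the CBCT acquisition model: contrast scale, shading, noise, FOV crop."""
    grid = volume.grid
    fov = _fov_mask(grid, config)
    xs, ys, zs = grid.coordinate_arrays()
    c = grid.center_mm
    r2 = ((xs - c[0]) ** 2 + (ys - c[1]) ** 2) / (config.cbct_fov_diameter_mm / 2.0) ** 2
    shading = config.cbct_shading_amplitude * (np.broadcast_to(r2, grid.shape) - 0.5)
    vals = config.cbct_contrast_scale * volume.values.astype(np.float64) + shading
    if config.cbct_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.cbct_noise_sd, size=grid.shape)
    vals = np.where(fov, vals, config.fov_pad_hu)
    out = ImageVolume(grid, vals, role="CBCT", metadata=dict(volume.metadata))
    out.metadata["fov_mask"] = fov
    out.metadata["pad_value"] = config.fov_pad_hu
    return out


def generate_weekly_series(
    pct: ImageVolume, structs: StructureSet, config: PhantomConfig
) -> tuple[list[ImageVolume], GroundTruth]:
    """Deform the planning anatomy week by week and acquire degraded CBCTs.

    Returns the degraded weekly CBCT volumes plus the exact ground truth
    (pull-back displacement fields, deformed masks, landmark positions,
    and the analytic deformations themselves).
    """
    if len(config.weekly_params) == 0:
        raise ValueError("weekly_params is empty")
    grid = pct.grid
    c0 = grid.center_mm
    bl_center = tuple(c0 + np.asarray(config.bladder_center_mm))
    rng = np.random.default_rng(config.seed)

    from .registration import apply_dvf  # local import to keep module load light

    weekly_images: list[ImageVolume] = []
    dvfs: list[DisplacementField] = []
    masks_true: list[StructureSet] = []
    landmarks_true: list[dict[str, np.ndarray]] = []
    deformations: list[AnalyticDeformation] = []

    for wk in config.weekly_params:
        lam = _solve_lambda(config, structs.masks["bladder"], grid, wk.bladder_scale)
        deform = AnalyticDeformation(bl_center, lam, config.deform_sigma_mm, wk.shift_mm)
        deform.check_diffeomorphic()
        dvf = deform.pullback_field(grid)

        anat = apply_dvf(pct, dvf)
        anat.role = "weekly_ct"

        wk_masks = {n: apply_dvf(m, dvf) for n, m in structs.masks.items()}
        names = list(structs.landmarks)
        pts = np.stack([structs.landmarks[n] for n in names])
        moved = deform.forward(pts)
        wk_landmarks = {n: moved[i] for i, n in enumerate(names)}

        if wk.gas_pocket is not None:
            offset, radius = wk.gas_pocket
            center = wk_landmarks["rectum_fiducial"] + np.asarray(offset)
            pocket = _ellipsoid_mask(grid, center, (radius, radius, radius))
            anat.values[pocket] = config.hu_map["gas"]

        cbct = degrade_to_cbct(anat, config, rng)
        cbct.role = "CBCT"

        weekly_images.append(cbct)
        dvfs.append(dvf)
        masks_true.append(
            StructureSet(grid, wk_masks, wk_landmarks, provenance="ground_truth")
        )
        landmarks_true.append(wk_landmarks)
        deformations.append(deform)

    return weekly_images, GroundTruth(dvfs, masks_true, landmarks_true, deformations)


def generate_plan(structs: StructureSet, prescription_gy: float = 45.0,
                  n_fractions: int = 25, margin_mm: float = 7.0):
    """Four-field box plan on the phantom PTV (see :mod:`doseaccum.dose`)."""
    from .dose import generate_plan as _generate_plan

    return _generate_plan(structs, prescription_gy, n_fractions, margin_mm)
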