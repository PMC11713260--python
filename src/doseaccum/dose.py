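"""Simplified anatomy-responsive dose engine and dose accumulation.

Two cumulative-dose pathways are supported:

* the *recalculated* pathway (ecD): the frozen plan is re-computed on
  each week's merged CBCT with this module's four-field box engine, so
  the dose responds to the anatomy of the day;
* the *deformed* pathway (mdD): the planning dose is resampled through
  the registration displacement field (:func:`deform_dose`).

Weekly doses are then warped to the week-1 reference geometry and
summed (:func:`accumulate`).

The engine is deliberately simple but physically shaped: per beam it
ray-traces water-equivalent depth (WED) through the relative-density
volume, applies an exponential depth kernel with a linear build-up
ramp, and a sigmoid lateral penumbra from the signed distance to the
aperture edge.  It is not a clinical dose calculation; constants are
megavoltage-like orders of magnitude only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grid import DoseGrid, Grid, ImageVolume
from .registration import DisplacementField, apply_dvf
from .structures import StructureSet

__all__ = [
    "Beam",
    "PlanSpec",
    "DoseEngineParams",
    "hu_to_relative_density",
    "generate_plan",
    "normalize_plan",
    "compute_dose",
    "deform_dose",
    "accumulate",
]

_DEFAULT_HU_KNOTS = ((-1000.0, 0.0), (0.0, 1.0), (1000.0, 1.6))


def hu_to_relative_density(hu, knots=_DEFAULT_HU_KNOTS) -> np.ndarray:
    """Piecewise-linear HU -> relative electron density, clamped at the ends."""
    k = np.asarray(knots, dtype=float)
    return np.interp(np.asarray(hu, dtype=float), k[:, 0], k[:, 1])


@dataclass(frozen=True)
class DoseEngineParams:
    """Kernel constants (documented as non-clinical)."""

    mu_eff_per_mm: float = 0.005
    d_max_mm: float = 15.0
    penumbra_mm: float = 6.0  # 80-20 lateral falloff width


@dataclass(frozen=True)
class Beam:
    """One axis-aligned beam of a four-field box.

    The aperture is the PTV projected onto the plane perpendicular to
    the beam axis; ``margin_mm`` expands it continuously (the aperture
    boundary is the margin-offset of the projected mask).
    """

    gantry_deg: float
    axis: int           # grid axis the beam travels along
    direction: int      # +1 or -1 along that axis
    aperture_mask: np.ndarray  # 2D projection of the PTV (plane axes in order)
    plane_axes: tuple[int, int]
    plane_spacing: tuple[float, float]
    margin_mm: float
    weight: float = 1.0

    def aperture_extent_mm(self) -> tuple[float, float]:
        """Aperture edge lengths: voxel extent of the projection + 2 x margin."""
        ext = []
        for d in range(2):
            occ = np.any(self.aperture_mask, axis=1 - d)
            idx = np.flatnonzero(occ)
            ext.append((idx[-1] - idx[0] + 1) * self.plane_spacing[d] + 2 * self.margin_mm)
        return tuple(ext)


@dataclass(frozen=True)
class PlanSpec:
    """A frozen four-field box plan.

    ``normalization`` (Gy per unit raw engine output) is fixed at
    planning by :func:`normalize_plan` and reused unchanged for every
    recalculation.
    """

    isocenter_mm: tuple[float, float, float]
    beams: tuple[Beam, ...]
    prescription_gy: float
    n_fractions: int
    normalization: float | None = None

    @property
    def fraction_gy(self) -> float:
        return self.prescription_gy / self.n_fractions


_GANTRY_TO_AXIS = {0.0: (1, +1), 90.0: (0, -1), 180.0: (1, -1), 270.0: (0, +1)}


def generate_plan(
    structs: StructureSet,
    prescription_gy: float = 45.0,
    n_fractions: int = 25,
    margin_mm: float = 7.0,
    ptv_name: str = "ptv45",
) -> PlanSpec:
    """Four-field box (gantry 0/90/180/270) covering the PTV + margin.

    The isocenter is the PTV centroid; beam weights are equal.  The plan
    still needs :func:`normalize_plan` against the planning anatomy
    before dose can be reported in Gy.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be positive")
    if n_fractions <= 0:
        raise ValueError("fraction count must be positive")
    grid = structs.grid
    ptv = structs.masks.get(ptv_name)
    if ptv is None or not ptv.any():
        raise ValueError(f"PTV structure {ptv_name!r} missing or empty")

    centroid_idx = np.mean(np.argwhere(ptv), axis=0)
    iso = tuple(grid.index_to_world(centroid_idx)[0])

    beams = []
    for gantry, (axis, direction) in _GANTRY_TO_AXIS.items():
        plane_axes = tuple(d for d in range(3) if d != axis)
        proj = np.any(ptv, axis=axis)
        beams.append(
            Beam(
                gantry_deg=gantry,
                axis=axis,
                direction=direction,
                aperture_mask=proj,
                plane_axes=plane_axes,
                plane_spacing=tuple(grid.spacing[d] for d in plane_axes),
                margin_mm=margin_mm,
                weight=1.0,
            )
        )
    return PlanSpec(iso, tuple(beams), float(prescription_gy), int(n_fractions))


# ---------------------------------------------------------------------------
# engine
# ---------------------------------------------------------------------------


def _beam_raw_dose(
    density: np.ndarray, grid: Grid, beam: Beam, params: DoseEngineParams
) -> np.ndarray:
    axis = beam.axis
    step = grid.spacing[axis]
    rho = density if beam.direction > 0 else np.flip(density, axis=axis)
    wed = (np.cumsum(rho, axis=axis) - 0.5 * rho) * step
    if beam.direction < 0:
        wed = np.flip(wed, axis=axis)
    ramp = np.clip(wed / params.d_max_mm, 0.0, 1.0)
    depth_dose = ramp * np.exp(-params.mu_eff_per_mm * wed)

    inside = ndimage.distance_transform_edt(
        beam.aperture_mask, sampling=beam.plane_spacing
    )
    outside = ndimage.distance_transform_edt(
        ~beam.aperture_mask, sampling=beam.plane_spacing
    )
    signed = outside - inside - beam.margin_mm
    sigma = params.penumbra_mm / 2.772  # logistic scale giving an 80-20 width
    lateral = 1.0 / (1.0 + np.exp(np.clip(signed / sigma, -60, 60)))

    shape = [1, 1, 1]
    shape[beam.plane_axes[0]] = lateral.shape[0]
    shape[beam.plane_axes[1]] = lateral.shape[1]
    return beam.weight * depth_dose * lateral.reshape(shape)


def _raw_dose(anatomy: ImageVolume, plan: PlanSpec, params: DoseEngineParams) -> np.ndarray:
    density = hu_to_relative_density(anatomy.values)
    total = np.zeros(anatomy.grid.shape)
    for beam in plan.beams:
        total += _beam_raw_dose(density, anatomy.grid, beam, params)
    return total


def _sample_trilinear(values: np.ndarray, grid: Grid, point_mm) -> float:
    idx = grid.world_to_index(point_mm).T
    return float(ndimage.map_coordinates(values, idx, order=1, mode="nearest")[0])


def normalize_plan(
    plan: PlanSpec, planning_anatomy: ImageVolume, params: DoseEngineParams | None = None
) -> PlanSpec:
    """Freeze the normalization so one fraction delivers the per-fraction
    prescription at the isocenter on the *planning* anatomy."""
    params = params or DoseEngineParams()
    raw = _raw_dose(planning_anatomy, plan, params)
    raw_iso = _sample_trilinear(raw, planning_anatomy.grid, plan.isocenter_mm)
    if raw_iso <= 0:
        raise ValueError("zero engine output at isocenter; check plan geometry")
    return replace(plan, normalization=plan.fraction_gy / raw_iso)


def compute_dose(
    anatomy: ImageVolume,
    plan: PlanSpec,
    fractions: float = 1.0,
    params: DoseEngineParams | None = None,
    role: str = "dose",
) -> DoseGrid:
    """Recalculate the frozen plan on an anatomy (``fractions`` x one fraction).

    Deterministic.  Raises if the plan was never normalized or the
    isocenter lies outside the body (air-equivalent density).
    """
    params = params or DoseEngineParams()
    if plan.normalization is None:
        raise ValueError("plan is not normalized; call normalize_plan on the planning CT")
    iso_hu = _sample_trilinear(anatomy.values.astype(float), anatomy.grid, plan.isocenter_mm)
    if iso_hu < -400.0:
        raise ValueError(f"isocenter outside body (HU {iso_hu:.0f})")
    raw = _raw_dose(anatomy, plan, params)
    return DoseGrid(anatomy.grid, raw * plan.normalization * fractions, role=role)


# ---------------------------------------------------------------------------
# deformation + accumulation
# ---------------------------------------------------------------------------


def deform_dose(dose: DoseGrid, dvf: DisplacementField) -> DoseGrid:
    """Trilinear pull-back resample of a dose grid (out-of-bounds -> 0 Gy)."""
    return apply_dvf(dose, dvf)


def accumulate(
    weekly_doses: list[DoseGrid],
    dvfs_to_reference: list[DisplacementField],
    weights: list[float] | None = None,
    role: str | None = None,
) -> DoseGrid:
    """Sum weekly doses on the reference geometry: sum_i w_i warp(D_i, dvf_i).

    Each weekly image stands for 5 fractions by default (weekly imaging
    as a surrogate for a week of treatment), so ``weights`` defaults to
    5 for every week.
    """
    if len(weekly_doses) != len(dvfs_to_reference):
        raise ValueError(
            f"{len(weekly_doses)} doses vs {len(dvfs_to_reference)} fields"
        )
    if weights is None:
        weights = [5.0] * len(weekly_doses)
    if len(weights) != len(weekly_doses):
        raise ValueError("weights length mismatch")
    ref_grid = dvfs_to_reference[0].grid
    total = np.zeros(ref_grid.shape)
    for dose, dvf, w in zip(weekly_doses, dvfs_to_reference, weights):
        total += w * deform_dose(dose, dvf).values
    if role is None:
        roles = {d.role.split("_")[0] for d in weekly_doses}
        role = "sum_" + roles.pop() if len(roles) == 1 else "sum"
    return DoseGrid(ref_grid, total, role=role)
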