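"""Extended-FOV merged CBCT construction and HU measurement/calibration.

The weekly CBCT sees only a limited cylinder of anatomy.  To recover a
full-extent volume suitable for dose recalculation, the planning CT is
deformed to the CBCT's anatomy *inside* a limiting contour (the CBCT
body), the CBCT supplies the voxels there, and the (deformed) planning
CT supplies everything beyond the field of view.  A linear alpha blend
over a narrow band inside the limiting contour suppresses stitching
seams.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import ImageVolume
from .registration import (
    DisplacementField,
    RegistrationParams,
    RigidTransform,
    apply_dvf,
    deformable_register,
    rigid_register,
)

__all__ = [
    "MergedCBCT",
    "HUCalibration",
    "make_limiting_contour",
    "merge",
    "measure_roi_hu",
    "check_hu_tolerance",
    "fit_hu_calibration",
    "apply_hu_calibration",
]

PROV_PCT, PROV_BLEND, PROV_CBCT = 0, 1, 2


@dataclass
class MergedCBCT:
    """Merged volume on the planning-CT grid plus per-voxel provenance.

    ``provenance``: 2 = CBCT voxel, 0 = deformed planning CT, 1 = blend.
    """

    volume: ImageVolume
    provenance: np.ndarray
    source_week: int
    dvf_pct_to_cbct: DisplacementField
    rigid: RigidTransform


@dataclass(frozen=True)
class HUCalibration:
    """Linear CBCT-to-CT HU map: ct_hu = slope * cbct_hu + intercept."""

    slope: float
    intercept: float
    source: str = "paired ROI"
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"calibration slope must be positive, got {self.slope}")


def make_limiting_contour(
    cbct: ImageVolume,
    body_threshold_hu: float = -300.0,
    fov_mask: np.ndarray | None = None,
    closing_mm: float = 10.0,
) -> np.ndarray:
    """Body mask of the CBCT inside its valid field of view.

    Largest connected component above the threshold, morphologically
    closed, intersected with the valid-FOV region (taken from the
    volume's metadata or inferred as voxels not at the padding value).
    """
    if fov_mask is None:
        fov_mask = cbct.metadata.get("fov_mask")
    if fov_mask is None:
        pad = cbct.metadata.get("pad_value", -1000.0)
        fov_mask = cbct.values != pad
    fov_mask = fov_mask.astype(bool)

    above = (cbct.values > body_threshold_hu) & fov_mask
    if not above.any():
        raise ValueError("empty limiting contour: no voxels above threshold in FOV")
    labels, n = ndimage.label(above)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    body = labels == (1 + int(np.argmax(sizes)))
    it = max(1, int(round(closing_mm / max(cbct.grid.spacing))))
    body = ndimage.binary_closing(body, iterations=it)
    body &= fov_mask
    if not body.any():
        raise ValueError("empty limiting contour after FOV intersection")
    return body


def merge(
    pct: ImageVolume,
    cbct: ImageVolume,
    limiting: np.ndarray,
    params: RegistrationParams | None = None,
    source_week: int = 1,
    blend_band_mm: float = 6.0,
    rigid: RigidTransform | None = None,
    dvf: DisplacementField | None = None,
) -> MergedCBCT:
    """Deformably stitch a weekly CBCT into the planning CT.

    The registration (planning CT deformed to CBCT anatomy) only
    considers image data inside the limiting contour; beyond it the
    deformed planning CT supplies the anatomy.  A precomputed ``dvf``
    (and ``rigid``) can be passed to reuse an existing registration.
    """
    pct.grid.require_same_geometry(cbct.grid, "planning CT vs CBCT")
    if not limiting.any():
        raise ValueError("limiting contour is empty")
    if dvf is None:
        if rigid is None:
            rigid = rigid_register(cbct, pct)
        params = params or RegistrationParams()
        if params.restrict_mask is None:
            from dataclasses import replace as _replace

            it = max(1, int(round(10.0 / max(cbct.grid.spacing))))
            params = _replace(
                params, restrict_mask=ndimage.binary_dilation(limiting, iterations=it)
            )
        dvf = deformable_register(cbct, pct, params, init=rigid)
    if rigid is None:
        rigid = RigidTransform((0.0, 0.0, 0.0))

    warped_pct = apply_dvf(pct, dvf)

    if blend_band_mm > 0:
        dist_in = ndimage.distance_transform_edt(limiting, sampling=cbct.grid.spacing)
        alpha = np.clip(dist_in / blend_band_mm, 0.0, 1.0)
    else:
        alpha = limiting.astype(float)

    merged_vals = alpha * cbct.values + (1.0 - alpha) * warped_pct.values
    provenance = np.full(cbct.grid.shape, PROV_PCT, dtype=np.uint8)
    provenance[alpha >= 1.0] = PROV_CBCT
    provenance[(alpha > 0.0) & (alpha < 1.0)] = PROV_BLEND

    vol = ImageVolume(cbct.grid, merged_vals, role="mCBCT")
    return MergedCBCT(vol, provenance, source_week, dvf, rigid)


def measure_roi_hu(volume: ImageVolume, roi: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean and sample SD (ddof=1) of HU over an ROI."""
    roi = roi.astype(bool)
    if roi.shape != volume.grid.shape:
        raise ValueError("ROI geometry does not match volume")
    if not roi.any():
        raise ValueError("empty ROI")
    vals = volume.values[roi].astype(np.float64)
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return float(vals.mean()), sd


def check_hu_tolerance(
    a: tuple[float, float], b: tuple[float, float], tol_hu: float = 40.0
) -> tuple[bool, float]:
    """Institutional HU agreement check: pass iff |mean_a - mean_b| <= tol."""
    diff = a[0] - b[0]
    return abs(diff) <= tol_hu, diff


def fit_hu_calibration(pairs) -> HUCalibration:
    """Least-squares line through (cbct_hu, ct_hu) pairs."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(np.unique(arr[:, 0])) < 2:
        raise ValueError("need >= 2 pairs with distinct CBCT HU values")
    slope, intercept = np.polyfit(arr[:, 0], arr[:, 1], 1)
    resid = arr[:, 1] - (slope * arr[:, 0] + intercept)
    return HUCalibration(
        slope=float(slope),
        intercept=float(intercept),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
    )


def apply_hu_calibration(volume: ImageVolume, cal: HUCalibration) -> ImageVolume:
    """v' = slope * v + intercept, applied voxel-wise."""
    out = volume.copy()
    out.values = (cal.slope * volume.values.astype(np.float64) + cal.intercept).astype(
        np.float32
    )
    return out
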