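"""File I/O: NIfTI volumes, displacement fields, landmark CSVs, and the
bundled 20-patient cohort summary tables.

On-disk grid convention: axis-aligned, 0-based indices, world =
origin + index * spacing (mm), stored in the NIfTI affine as a diagonal
spacing matrix plus origin translation.  Oblique affines are rejected.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import DoseGrid, Grid, ImageVolume
from .registration import DisplacementField

__all__ = [
    "read_volume",
    "write_volume",
    "read_dose",
    "write_dose",
    "read_mask",
    "write_mask",
    "read_dvf",
    "write_dvf",
    "read_landmarks",
    "write_landmarks",
    "load_cohort_table",
    "COHORT_TABLES",
]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape) -> Grid:
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("oblique NIfTI orientations are not supported")
    spacing = np.diag(rot)
    if np.any(spacing <= 0):
        raise ValueError("non-positive spacing in NIfTI affine")
    return Grid(tuple(shape[:3]), tuple(spacing), tuple(aff[:3, 3]))


def write_volume(path, volume: ImageVolume) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float32), _affine(volume.grid))
    nib.save(img, str(path))


def read_volume(path, expect_grid: Grid | None = None, role: str = "image") -> ImageVolume:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    if expect_grid is not None and not grid.same_geometry(expect_grid):
        raise ValueError(f"{path}: header grid does not match the declared grid")
    return ImageVolume(grid, np.asarray(img.dataobj, dtype=np.float32), role=role)


def write_dose(path, dose: DoseGrid) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.grid))
    img.header["descrip"] = b"absorbed dose [Gy]"
    nib.save(img, str(path))


def read_dose(path, expect_grid: Grid | None = None, role: str = "dose") -> DoseGrid:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    if expect_grid is not None and not grid.same_geometry(expect_grid):
        raise ValueError(f"{path}: header grid does not match the declared grid")
    return DoseGrid(grid, np.asarray(img.dataobj, dtype=np.float64), role=role)


def write_mask(path, mask: np.ndarray, grid: Grid) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(grid))
    nib.save(img, str(path))


def read_mask(path, expect_grid: Grid | None = None) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    if expect_grid is not None and not grid.same_geometry(expect_grid):
        raise ValueError(f"{path}: header grid does not match the declared grid")
    return np.asarray(img.dataobj) > 0, grid


def write_dvf(path, dvf: DisplacementField) -> None:
    """Persist as a 4-component NIfTI (x, y, z displacement in mm)."""
    img = nib.Nifti1Image(dvf.vectors.astype(np.float32), _affine(dvf.grid))
    img.header["descrip"] = b"displacement [mm], pull-back"
    nib.save(img, str(path))


def read_dvf(path, expect_grid: Grid | None = None) -> DisplacementField:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape)
    if expect_grid is not None and not grid.same_geometry(expect_grid):
        raise ValueError(f"{path}: header grid does not match the declared grid")
    return DisplacementField(grid, np.asarray(img.dataobj, dtype=np.float64))


def write_landmarks(path, landmarks: dict[str, np.ndarray]) -> None:
    rows = [{"name": n, "x_mm": p[0], "y_mm": p[1], "z_mm": p[2]} for n, p in landmarks.items()]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path)
    return {
        r["name"]: np.array([r["x_mm"], r["y_mm"], r["z_mm"]], dtype=float)
        for _, r in df.iterrows()
    }


# ---------------------------------------------------------------------------
# cohort summary tables
# ---------------------------------------------------------------------------

_PATIENTS = [f"P{i}" for i in range(1, 21)]

COHORT_TABLES = {
    "T1": ("cohort_volumes_t1.csv", ["patient", "organ", "pct_cc", "w1", "w2", "w3", "w4", "w5", "median"], 40),
    "T3": ("cohort_bladder_pctdiff_t3.csv", ["patient", "metric", "comparison", "value"], 240),
    "T4": ("cohort_rectum_pctdiff_t4.csv", ["patient", "metric", "comparison", "value"], 180),
    "T5": ("cohort_ptv_pctdiff_t5.csv", ["patient", "metric", "comparison", "value"], 120),
    "T6": ("cohort_gamma_t6.csv", ["patient", "structure", "comparison", "pass_rate"], 80),
    "T7": ("cohort_hu_t7.csv", ["patient", "material", "image", "mean", "sd"], 45),
}


def load_cohort_table(table_id: str) -> pd.DataFrame:
    """Load one of the bundled published-cohort summary tables.

    ``table_id`` is one of T1 (organ volumes), T3/T4/T5 (bladder /
    rectum / PTV percent differences), T6 (gamma pass rates), T7 (ROI
    HU measurements).  The parsed table is validated structurally
    (columns, row count, patient labels) before it is returned.
    """
    if table_id not in COHORT_TABLES:
        raise KeyError(f"unknown cohort table {table_id!r}; choose from {sorted(COHORT_TABLES)}")
    fname, columns, nrows = COHORT_TABLES[table_id]
    with importlib.resources.files("doseaccum.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh)
    if list(df.columns) != columns or len(df) != nrows:
        raise ValueError(f"cohort table {table_id} failed integrity check (shape/columns)")
    bad = set(df["patient"].unique()) - set(_PATIENTS)
    if bad:
        raise ValueError(f"cohort table {table_id} has unexpected patient labels {bad}")
    if df.isna().any().any():
        raise ValueError(f"cohort table {table_id} contains missing cells")
    return df
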