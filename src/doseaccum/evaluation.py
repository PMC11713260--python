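"""Dosimetric evaluation: DVH metrics, percent-difference bands, paired
nonparametric testing, 3D gamma analysis, and summary report tables.

Conventions (stated because they decide boundary cases):

* DVH Dx values use the voxel-boundary convention — voxel doses are
  sorted hot-to-cold, the cumulative-volume axis runs through the points
  (k * v_voxel, d_(k)), and Dx / D2cc interpolate linearly on that axis.
* Percent-difference bands are inclusive downward: |pd| = 2.0 falls in
  the <=2 band and |pd| = 5.0 in the 2-5 band.
* The Wilcoxon signed-rank test is two-sided, drops zero differences,
  midranks ties, and enumerates the exact null for n <= 25.
* Gamma uses global normalization to the reference-dose maximum and a
  dense trilinear search (step <= dist_crit / 10, radius 3 x dist_crit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from .grid import DoseGrid, Grid

__all__ = [
    "DVHCurve",
    "GammaResult",
    "compute_dvh",
    "dvh_metric",
    "percent_diff",
    "band",
    "count_within",
    "wilcoxon_signed_rank",
    "gamma_analysis",
    "build_report",
]


# ---------------------------------------------------------------------------
# DVH
# ---------------------------------------------------------------------------


@dataclass
class DVHCurve:
    """Cumulative DVH: volume (relative and absolute) receiving >= dose."""

    dose_edges_gy: np.ndarray
    volume_cc: np.ndarray
    volume_rel: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.volume_cc) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")


def _masked_doses(dose: DoseGrid, mask: np.ndarray) -> np.ndarray:
    if mask.shape != dose.grid.shape:
        raise ValueError("mask geometry does not match dose grid")
    if not mask.any():
        raise ValueError("empty structure mask")
    return dose.values[mask.astype(bool)]


def compute_dvh(dose: DoseGrid, mask: np.ndarray, bin_width_gy: float = 0.01) -> DVHCurve:
    """Cumulative DVH by voxel counting."""
    d = _masked_doses(dose, mask)
    vvox = dose.grid.voxel_volume_cc
    edges = np.arange(0.0, d.max() + 2 * bin_width_gy, bin_width_gy)
    counts = np.array([np.count_nonzero(d >= e) for e in edges], dtype=float)
    vol = counts * vvox
    return DVHCurve(edges, vol, vol / vol[0])


_METRICS = ("Dmax", "Dmean", "D50", "D90", "D98", "D2cc", "V45")


def dvh_metric(dose: DoseGrid, mask: np.ndarray, which: str) -> float:
    """One DVH metric (Gy, or cc for Vx) with the stated conventions."""
    d = _masked_doses(dose, mask)
    vvox = dose.grid.voxel_volume_cc
    total_cc = d.size * vvox

    if which == "Dmax":
        return float(d.max())
    if which == "Dmean":
        return float(d.mean())
    if which.startswith("V"):
        thr = float(which[1:])
        return float(np.count_nonzero(d >= thr) * vvox)
    if which == "D2cc":
        if total_cc <= 2.0:
            raise ValueError(
                f"D2cc undefined for a {total_cc:.2f} cc structure (needs > 2 cc)"
            )
        target_cc = 2.0
    elif which.startswith("D"):
        target_cc = float(which[1:]) / 100.0 * total_cc
    else:
        raise ValueError(f"unknown DVH metric {which!r}")

    sorted_desc = np.sort(d)[::-1]
    cum_cc = (np.arange(d.size) + 1) * vvox
    return float(np.interp(target_cc, cum_cc, sorted_desc))


# ---------------------------------------------------------------------------
# percent differences and bands
# ---------------------------------------------------------------------------


def percent_diff(value: float, reference: float) -> float:
    """Signed 100 (value - reference) / reference."""
    if reference == 0:
        raise ZeroDivisionError("zero reference in percent difference")
    return 100.0 * (value - reference) / reference


BANDS = ("<=2", "2-5", ">5")


def band(pd_value: float) -> str:
    """Band |pd|: <=2, 2-5 (boundaries inclusive downward), or >5."""
    a = abs(pd_value)
    if a <= 2.0:
        return "<=2"
    if a <= 5.0:
        return "2-5"
    return ">5"


def count_within(
    table: pd.DataFrame,
    metric: str,
    threshold: float,
    comparisons: set[str] | list[str],
) -> int:
    """Patients whose |percent difference| <= threshold for *every* listed
    comparison of one metric (tidy table: patient / metric / comparison / value)."""
    sub = table[(table["metric"] == metric) & table["comparison"].isin(set(comparisons))]
    patients = sub["patient"].unique()
    expected = len(set(comparisons))
    count = 0
    for p in patients:
        vals = sub.loc[sub["patient"] == p, "value"]
        if len(vals) != expected or vals.isna().any():
            raise ValueError(f"missing cells for patient {p}, metric {metric}")
        if (vals.abs() <= threshold).all():
            count += 1
    return count


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by DP over all sign assignments (midranks doubled
    to integers so tied ranks stay exact)."""
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    n_patterns = dist.sum()
    w2 = 2 * w_plus
    lo = dist[: int(round(w2)) + 1].sum() / n_patterns
    hi = dist[int(round(w2)):].sum() / n_patterns
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_signed_rank(a, b) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped (Wilcoxon's treatment), ties midranked.
    Exact enumeration for n <= 25 effective pairs, normal approximation
    with tie correction above.  Returns (W+, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    order = np.abs(d)
    ranks = pd.Series(order).rank(method="average").to_numpy()
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= 25:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(order, return_counts=True)
    tie_corr = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    return w_plus, float(2 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# gamma analysis
# ---------------------------------------------------------------------------


@dataclass
class GammaResult:
    """Per-voxel gamma index within the evaluated region and the pass rate."""

    gamma_map: np.ndarray  # nan outside the evaluated region
    pass_rate: float       # percent of evaluated voxels with gamma <= 1
    n_evaluated: int
    passed: bool           # pass rate >= the configured pass threshold
    criteria: dict


def _resample_dose_to(reference: Grid, dose: DoseGrid) -> np.ndarray:
    if dose.grid.same_geometry(reference):
        return dose.values
    xs, ys, zs = reference.coordinate_arrays()
    pts = np.stack(np.broadcast_arrays(xs, ys, zs), axis=-1).reshape(-1, 3)
    idx = dose.grid.world_to_index(pts).T
    vals = ndimage.map_coordinates(dose.values, idx, order=1, mode="constant", cval=0.0)
    return vals.reshape(reference.shape)


def _search_offsets(dist_crit_mm: float, step_mm: float) -> tuple[np.ndarray, np.ndarray]:
    radius = 3.0 * dist_crit_mm
    n = int(np.floor(radius / step_mm + 1e-9))
    g = np.arange(-n, n + 1, dtype=float) * step_mm  # exact 0 at the centre
    ox, oy, oz = np.meshgrid(g, g, g, indexing="ij")
    offs = np.stack([ox.ravel(), oy.ravel(), oz.ravel()], axis=1)
    norms = np.linalg.norm(offs, axis=1)
    keep = norms <= radius
    offs, norms = offs[keep], norms[keep]
    order = np.argsort(norms, kind="stable")
    return offs[order], norms[order]


def gamma_analysis(
    reference: DoseGrid,
    evaluated: DoseGrid,
    mask: np.ndarray,
    dose_crit_pct: float = 3.0,
    dist_crit_mm: float = 2.0,
    low_threshold_pct: float = 20.0,
    pass_threshold_pct: float = 90.0,
    search_step_mm: float | None = None,
) -> GammaResult:
    """3D gamma between a reference and an evaluated dose inside a mask.

    Global normalization to the reference maximum; only reference voxels
    inside ``mask`` with dose >= ``low_threshold_pct`` % of the
    normalization are evaluated.  The evaluated dose is minimized over a
    dense trilinearly interpolated neighborhood; voxels retire from the
    search as soon as the remaining spatial term alone exceeds their
    best gamma so far.
    """
    if not mask.any():
        raise ValueError("empty gamma mask")
    grid = reference.grid
    ev = _resample_dose_to(grid, evaluated)
    d_norm = float(reference.values.max())
    if d_norm <= 0:
        raise ValueError("reference dose is identically zero")
    dd = dose_crit_pct / 100.0 * d_norm

    eval_sel = mask.astype(bool) & (reference.values >= low_threshold_pct / 100.0 * d_norm)
    if not eval_sel.any():
        raise ValueError("no voxels above the low-dose threshold inside the mask")

    idx = np.argwhere(eval_sel)
    pts_idx = idx.astype(float)
    ref_vals = reference.values[eval_sel]
    spacing = np.asarray(grid.spacing)

    step = search_step_mm if search_step_mm is not None else dist_crit_mm / 10.0
    offsets, norms = _search_offsets(dist_crit_mm, step)

    best = np.full(len(idx), np.inf)
    active = np.arange(len(idx))
    for off, dist in zip(offsets, norms):
        if active.size == 0:
            break
        spatial = dist / dist_crit_mm
        # retire voxels whose best gamma cannot improve any more
        keep = best[active] > spatial
        active = active[keep]
        if active.size == 0:
            break
        coords = (pts_idx[active] + off / spacing).T
        ev_here = ndimage.map_coordinates(ev, coords, order=1, mode="constant", cval=0.0)
        g2 = ((ev_here - ref_vals[active]) / dd) ** 2 + spatial**2
        best[active] = np.minimum(best[active], np.sqrt(g2))

    gamma_map = np.full(grid.shape, np.nan)
    gamma_map[eval_sel] = best
    pass_rate = 100.0 * float(np.mean(best <= 1.0 + 1e-12))
    return GammaResult(
        gamma_map=gamma_map,
        pass_rate=pass_rate,
        n_evaluated=int(len(idx)),
        passed=pass_rate >= pass_threshold_pct,
        criteria={
            "dose_crit_pct": dose_crit_pct,
            "dist_crit_mm": dist_crit_mm,
            "low_threshold_pct": low_threshold_pct,
            "pass_threshold_pct": pass_threshold_pct,
            "normalization_gy": d_norm,
            "search_step_mm": step,
        },
    )


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def summarize_gamma(gamma_table: pd.DataFrame) -> pd.DataFrame:
    """Mean pass rate per structure per comparison (tidy input:
    patient / structure / comparison / pass_rate)."""
    if gamma_table.empty:
        return pd.DataFrame(columns=["structure", "comparison", "mean_pass_rate"])
    out = (
        gamma_table.groupby(["structure", "comparison"])["pass_rate"]
        .mean()
        .reset_index()
        .rename(columns={"pass_rate": "mean_pass_rate"})
    )
    return out


def band_counts(metrics_table: pd.DataFrame) -> pd.DataFrame:
    """Band tally per metric per comparison from a tidy percent-difference table."""
    if metrics_table.empty:
        return pd.DataFrame(columns=["metric", "comparison", "band", "count"])
    t = metrics_table.copy()
    t["band"] = t["value"].map(band)
    out = (
        t.groupby(["metric", "comparison", "band"])
        .size()
        .reset_index(name="count")
    )
    return out


def build_report(
    metrics_table: pd.DataFrame | None = None,
    gamma_table: pd.DataFrame | None = None,
    geometry_table: pd.DataFrame | None = None,
    volume_table: pd.DataFrame | None = None,
) -> dict:
    """Assemble the summary tables and a text summary from tidy inputs.

    Accepts any subset; empty inputs produce empty tables without error.
    """
    metrics_table = metrics_table if metrics_table is not None else pd.DataFrame()
    gamma_table = gamma_table if gamma_table is not None else pd.DataFrame()
    lines = []
    report: dict = {
        "metrics": metrics_table,
        "bands": band_counts(metrics_table),
        "gamma_summary": summarize_gamma(gamma_table),
        "gamma": gamma_table,
    }
    if volume_table is not None:
        report["volumes"] = volume_table
    if geometry_table is not None and not geometry_table.empty:
        report["geometry"] = geometry_table
        if "mean_dsc" in geometry_table:
            summ = geometry_table[geometry_table.get("kind") == "summary"]
            if len(summ):
                lines.append(
                    f"mean DSC {summ['mean_dsc'].iloc[0]:.3f} +/- {summ['sd_dsc'].iloc[0]:.3f}; "
                    f"mean TRE {summ['mean_tre_mm'].iloc[0]:.2f} +/- "
                    f"{summ['sd_tre_mm'].iloc[0]:.2f} mm"
                )
    for _, row in report["gamma_summary"].iterrows():
        lines.append(
            f"mean gamma pass rate {row['structure']} {row['comparison']}: "
            f"{row['mean_pass_rate']:.1f}%"
        )
    report["summary_text"] = "\n".join(lines)
    return report
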