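"""DVH metrics, banding, signed-rank test, and gamma analysis oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import doseaccum as da
from doseaccum.evaluation import (
    band,
    build_report,
    count_within,
    gamma_analysis,
    wilcoxon_signed_rank,
)
from doseaccum.grid import DoseGrid, Grid
from doseaccum.io import load_cohort_table


def dose_on(grid, values):
    return DoseGrid(grid, np.asarray(values, float))


def line_grid(n, vox_cc=1.0):
    # 1 x 1 x n voxels, each vox_cc cc
    side = (vox_cc * 1000.0) ** (1.0 / 3.0)
    return Grid((1, 1, n), (side, side, side))


def brute_force_metric(doses_gy, vox_cc, which):
    """Independent sort-based oracle with the voxel-boundary convention."""
    d = np.asarray(doses_gy, float)
    if which == "Dmax":
        return d.max()
    if which == "Dmean":
        return d.mean()
    if which.startswith("V"):
        return float(np.sum(d >= float(which[1:]))) * vox_cc
    total = d.size * vox_cc
    target = 2.0 if which == "D2cc" else float(which[1:]) / 100.0 * total
    s = np.sort(d)[::-1]
    cum = (np.arange(d.size) + 1) * vox_cc
    if target <= cum[0]:
        return float(s[0])
    for k in range(d.size - 1):
        if cum[k] <= target <= cum[k + 1]:
            f = (target - cum[k]) / (cum[k + 1] - cum[k])
            return float(s[k] + f * (s[k + 1] - s[k]))
    return float(s[-1])


class TestDVH:
    def test_uniform_dose_step_curve(self):
        g = line_grid(100)
        d = dose_on(g, np.full(g.shape, 45.0))
        mask = np.ones(g.shape, bool)
        curve = da.compute_dvh(d, mask, bin_width_gy=0.5)
        below = curve.dose_edges_gy <= 45.0
        assert np.all(curve.volume_rel[below] == 1.0)
        assert np.all(curve.volume_rel[~below] == 0.0)

    def test_two_voxel_v45(self):
        g = line_grid(2)
        d = dose_on(g, np.array([[[40.0, 50.0]]]))
        mask = np.ones(g.shape, bool)
        curve = da.compute_dvh(d, mask, bin_width_gy=1.0)
        at_45 = np.searchsorted(curve.dose_edges_gy, 45.0)
        assert curve.volume_rel[at_45] == pytest.approx(0.5)

    def test_curve_non_increasing_for_random_dose(self, rng):
        g = line_grid(200)
        d = dose_on(g, rng.uniform(0, 60, g.shape))
        curve = da.compute_dvh(d, np.ones(g.shape, bool), 0.25)
        assert np.all(np.diff(curve.volume_cc) <= 1e-12)

    def test_ten_voxel_example_metrics(self):
        g = line_grid(10)
        d = dose_on(g, np.arange(1.0, 11.0).reshape(g.shape))
        mask = np.ones(g.shape, bool)
        assert da.dvh_metric(d, mask, "D2cc") == pytest.approx(9.0)
        assert da.dvh_metric(d, mask, "Dmax") == pytest.approx(10.0)
        assert da.dvh_metric(d, mask, "Dmean") == pytest.approx(5.5)
        assert da.dvh_metric(d, mask, "D50") == pytest.approx(6.0)

    def test_uniform_45_v45_and_d90(self):
        g = line_grid(100)
        d = dose_on(g, np.full(g.shape, 45.0))
        mask = np.ones(g.shape, bool)
        assert da.dvh_metric(d, mask, "V45") == pytest.approx(100.0)
        assert da.dvh_metric(d, mask, "D90") == pytest.approx(45.0)

    def test_d2cc_on_small_structure_raises(self):
        g = line_grid(3, vox_cc=0.5)
        d = dose_on(g, np.zeros(g.shape))
        with pytest.raises(ValueError, match="D2cc"):
            da.dvh_metric(d, np.ones(g.shape, bool), "D2cc")

    @pytest.mark.parametrize("which", ["Dmax", "Dmean", "D50", "D90", "D98",
                                       "D2cc", "V45"])
    def test_matches_bruteforce_oracle_on_random_masks(self, which, rng):
        g = Grid((10, 10, 10), (10.0, 10.0, 10.0))  # 1 cc voxels
        vals = rng.uniform(0, 60, g.shape)
        mask = rng.random(g.shape) > 0.4
        d = dose_on(g, vals)
        got = da.dvh_metric(d, mask, which)
        want = brute_force_metric(vals[mask], 1.0, which)
        assert got == pytest.approx(want, abs=1e-9)


class TestBands:
    def test_percent_diff_examples(self):
        assert da.percent_diff(51.5, 50.0) == pytest.approx(3.0)
        assert da.percent_diff(50.0, 50.0) == 0.0
        with pytest.raises(ZeroDivisionError):
            da.percent_diff(1.0, 0.0)

    @pytest.mark.parametrize("pd_val,expected", [
        (1.9, "<=2"), (-4.6, "2-5"), (5.0, "2-5"), (2.0, "<=2"),
        (15.3, ">5"), (-15.3, ">5"), (0.0, "<=2"), (-2.0001, "2-5"),
    ])
    def test_band_boundaries_inclusive_downward(self, pd_val, expected):
        assert band(pd_val) == expected

    def test_count_within_cohort_examples(self):
        t3 = load_cohort_table("T3")
        assert count_within(t3, "D2cc", 5.0, {"ecD-pD", "mdD-pD"}) == 19
        t4 = load_cohort_table("T4")
        assert count_within(t4, "Dmax", 5.0, {"ecD-pD", "mdD-pD"}) == 13
        assert count_within(t3, "D2cc", 1000.0, {"ecD-pD", "mdD-pD"}) == 20

    def test_count_within_missing_cells_raises(self):
        t = pd.DataFrame({"patient": ["P1"], "metric": ["D2cc"],
                          "comparison": ["ecD-pD"], "value": [1.0]})
        with pytest.raises(ValueError, match="missing"):
            count_within(t, "D2cc", 5.0, {"ecD-pD", "mdD-pD"})


class TestWilcoxon:
    def test_equal_samples_p_one(self):
        a = np.arange(1.0, 9.0)
        assert wilcoxon_signed_rank(a, a) == (0.0, 1.0)

    def test_all_positive_n6_exact(self):
        b = np.zeros(6)
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        w, p = wilcoxon_signed_rank(a, b)
        assert w == 21.0
        assert p == pytest.approx(2.0 / 64.0)

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_exact_branch_matches_full_enumeration(self, n, rng):
        d = rng.normal(0.3, 1.0, n)
        d[d == 0] = 0.1
        a = d
        b = np.zeros(n)
        _, p = wilcoxon_signed_rank(a, b)
        # oracle: enumerate all sign patterns of the ranked |d|
        ranks = pd.Series(np.abs(d)).rank(method="average").to_numpy()
        w_obs = ranks[d > 0].sum()
        ws = []
        for bits in range(2**n):
            w = sum(ranks[i] for i in range(n) if (bits >> i) & 1)
            ws.append(w)
        ws = np.asarray(ws)
        lo = np.mean(ws <= w_obs + 1e-12)
        hi = np.mean(ws >= w_obs - 1e-12)
        assert p == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self, rng):
        d = rng.normal(0.5, 1.0, 15)
        d = np.where(np.abs(d) < 1e-6, 0.5, d)
        _, p = wilcoxon_signed_rank(d, np.zeros_like(d))
        ref = stats.wilcoxon(d, np.zeros_like(d), mode="exact",
                             zero_method="wilcox")
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_power_under_one_sd_shift(self):
        hits = 0
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            b = rng.normal(0.0, 1.0, 20)
            a = b + rng.normal(1.0, 1.0, 20)  # paired shift of 1 SD
            _, p = wilcoxon_signed_rank(a, b)
            hits += p < 0.05
        assert hits >= 190  # >= 95% of replicates

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [0.0, 0.0])


class TestGamma:
    def test_identical_doses_full_pass(self, rng):
        g = Grid((16, 16, 16), (2.5, 2.5, 2.5))
        d = dose_on(g, rng.uniform(10, 50, g.shape))
        r = gamma_analysis(d, d, np.ones(g.shape, bool))
        assert r.pass_rate == 100.0
        assert np.nanmax(r.gamma_map) == 0.0

    def test_uniform_3pct_offset_boundary_pass(self):
        g = Grid((12, 12, 12), (3.0, 3.0, 3.0))
        ref = dose_on(g, np.full(g.shape, 50.0))
        ev = dose_on(g, np.full(g.shape, 51.5))
        r = gamma_analysis(ref, ev, np.ones(g.shape, bool))
        assert r.pass_rate == 100.0
        vals = r.gamma_map[~np.isnan(r.gamma_map)]
        assert np.allclose(vals, 1.0)

    def test_translated_gradient_matches_bruteforce_oracle(self):
        """Per-voxel gamma against an exhaustive dense search on a 32-cube."""
        g = Grid((32, 32, 32), (2.0, 2.0, 2.0))
        xs, ys, zs = g.coordinate_arrays()
        ref_vals = 50.0 + 0.4 * xs + 0.2 * ys + 0.1 * zs + 0.0 * (xs + ys + zs)
        ref_vals = np.broadcast_to(ref_vals, g.shape).copy()
        ev_vals = np.roll(ref_vals, 1, axis=0) * 1.01  # ~2 mm shift + 1% offset
        ref = dose_on(g, ref_vals)
        ev = dose_on(g, ev_vals)
        mask = np.zeros(g.shape, bool)
        mask[12:18, 12:18, 12:18] = True
        r = gamma_analysis(ref, ev, mask, search_step_mm=0.2)

        # oracle: direct dense minimization per voxel
        from scipy.ndimage import map_coordinates

        d_norm = ref_vals.max()
        dd = 0.03 * d_norm
        offs = np.mgrid[-6:6.2:0.2, -6:6.2:0.2, -6:6.2:0.2].reshape(3, -1).T
        offs = offs[np.linalg.norm(offs, axis=1) <= 6.0]
        idx = np.argwhere(mask)
        for vox in idx[::37]:
            coords = (vox[None, :] + offs / np.asarray(g.spacing)).T
            ev_i = map_coordinates(ev_vals, coords, order=1, mode="constant",
                                   cval=0.0)
            gam = np.sqrt(((ev_i - ref_vals[tuple(vox)]) / dd) ** 2
                          + (np.linalg.norm(offs, axis=1) / 2.0) ** 2).min()
            assert abs(r.gamma_map[tuple(vox)] - gam) < 0.02

    def test_pass_rate_non_increasing_with_tighter_criteria(self, default_weekly):
        g = Grid((20, 20, 20), (3.0, 3.0, 3.0))
        rng = np.random.default_rng(8)
        base = 50.0 + np.cumsum(rng.normal(0, 0.1, g.shape), axis=0)
        ref = dose_on(g, base)
        ev = dose_on(g, base * (1 + rng.normal(0, 0.02, g.shape)))
        mask = np.ones(g.shape, bool)
        r32 = gamma_analysis(ref, ev, mask, 3.0, 2.0).pass_rate
        r22 = gamma_analysis(ref, ev, mask, 2.0, 2.0).pass_rate
        r31 = gamma_analysis(ref, ev, mask, 3.0, 1.0).pass_rate
        assert r22 <= r32 and r31 <= r32

    def test_scale_consistency(self, rng):
        g = Grid((14, 14, 14), (3.0, 3.0, 3.0))
        a = rng.uniform(20, 50, g.shape)
        b = a * (1 + rng.normal(0, 0.02, g.shape))
        m = np.ones(g.shape, bool)
        g1 = gamma_analysis(dose_on(g, a), dose_on(g, b), m).gamma_map
        g2 = gamma_analysis(dose_on(g, 3.7 * a), dose_on(g, 3.7 * b), m).gamma_map
        assert np.nanmax(np.abs(g1 - g2)) < 1e-9

    def test_empty_region_after_threshold_raises(self):
        g = Grid((8, 8, 8), (3.0, 3.0, 3.0))
        ref = dose_on(g, np.zeros(g.shape) + 1e-9)
        ref.values[0, 0, 0] = 50.0
        mask = np.zeros(g.shape, bool)
        mask[4:, 4:, 4:] = True  # all below 20% threshold
        with pytest.raises(ValueError, match="threshold"):
            gamma_analysis(ref, ref, mask)


class TestReport:
    def test_cohort_gamma_summary_means(self):
        t6 = load_cohort_table("T6")
        rep = build_report(gamma_table=t6)
        s = rep["gamma_summary"]
        val = s[(s.structure == "bladder") & (s.comparison == "pD-ecD")
                ].mean_pass_rate.iloc[0]
        assert round(val) == 94

    def test_empty_inputs_no_crash(self):
        rep = build_report()
        assert rep["bands"].empty and rep["gamma_summary"].empty
        assert rep["summary_text"] == ""

    def test_single_patient_means_equal_values(self):
        t6 = load_cohort_table("T6")
        one = t6[t6.patient == "P5"]
        rep = build_report(gamma_table=one)
        assert np.allclose(rep["gamma_summary"].mean_pass_rate, 100.0)
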