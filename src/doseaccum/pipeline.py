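"""End-to-end workflow driver.

Stages (each runnable standalone on the previous stage's artifacts):

1. ``phantom``     - synthesize planning CT, weekly CBCTs, ground truth
2. ``register``    - rigid + deformable registration pCT -> each CBCT
3. ``merge``       - build the merged (extended-FOV) CBCTs
4. ``dose``        - planning dose, weekly recalculated (ecD) and
                     deformed (mdD) doses
5. ``accumulate``  - warp weekly doses to the week-1 reference and sum
6. ``evaluate``    - DVH metrics, percent differences, gamma, geometry
7. ``report``      - CSV tables + text summary

A :class:`Pipeline` keeps an in-memory cache and, when given a working
directory, persists/loads every artifact so stages can resume across
processes.  All randomness flows from the phantom seed; rerunning with
the same configuration is reproducible.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .dose import accumulate, compute_dose, deform_dose, generate_plan, normalize_plan
from .evaluation import build_report, dvh_metric, gamma_analysis, percent_diff
from .grid import DoseGrid
from .merged_cbct import make_limiting_contour, merge
from .phantom import PhantomConfig, generate_planning_ct, generate_weekly_series
from .registration import (
    DisplacementField,
    RegistrationParams,
    RigidTransform,
    deformable_register,
    rigid_register,
)
from .structures import StructureSet, dice, propagate, transfer, volume_stats

log = logging.getLogger("doseaccum")

STRUCTURE_METRICS = {
    "bladder": ("D2cc", "Dmax", "Dmean", "D50", "V45"),
    "rectum": ("D2cc", "Dmax", "Dmean", "D50"),
    "ptv45": ("D90", "D98", "Dmax", "Dmean"),
}
COMPARISONS = (("ecD-pD", "ecd", "pd"), ("mdD-pD", "mdd", "pd"), ("mdD-ecD", "mdd", "ecd"))


@dataclass(frozen=True)
class EvalCriteria:
    dose_crit_pct: float = 3.0
    dist_crit_mm: float = 2.0
    low_threshold_pct: float = 20.0
    pass_threshold_pct: float = 90.0
    gamma_search_step_mm: float | None = None  # None -> dist_crit / 10

    def __post_init__(self) -> None:
        if min(self.dose_crit_pct, self.dist_crit_mm, self.low_threshold_pct) <= 0:
            raise ValueError("gamma criteria must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    registration: RegistrationParams = field(default_factory=RegistrationParams)
    prescription_gy: float = 45.0
    n_fractions: int = 25
    ptv_margin_mm: float = 7.0
    criteria: EvalCriteria = field(default_factory=EvalCriteria)

    def with_seed(self, seed: int) -> "PipelineConfig":
        return replace(self, phantom=replace(self.phantom, seed=int(seed)))

    @property
    def n_weeks(self) -> int:
        return len(self.phantom.weekly_params)

    @property
    def fractions_per_week(self) -> float:
        return self.n_fractions / self.n_weeks


class StageError(RuntimeError):
    pass


class Pipeline:
    """Stage runner with lazy artifact persistence."""

    def __init__(self, config: PipelineConfig, workdir: str | Path | None = None):
        self.config = config
        self.workdir = Path(workdir) if workdir is not None else None
        self.cache: dict = {}

    # -- persistence helpers ------------------------------------------------

    def _dir(self, stage: str) -> Path | None:
        if self.workdir is None:
            return None
        d = self.workdir / stage
        d.mkdir(parents=True, exist_ok=True)
        return d

    def _need(self, key: str, loader, stage: str):
        if key in self.cache:
            return self.cache[key]
        if self.workdir is not None:
            try:
                value = loader()
            except FileNotFoundError as exc:
                raise StageError(
                    f"artifact {key!r} not found; run the {stage!r} stage first"
                ) from exc
            self.cache[key] = value
            return value
        raise StageError(f"artifact {key!r} missing; run the {stage!r} stage first")

    # -- stage 1: phantom ---------------------------------------------------

    def phantom(self) -> None:
        cfg = self.config.phantom
        t0 = time.time()
        pct, structs = generate_planning_ct(cfg)
        weekly, truth = generate_weekly_series(pct, structs, cfg)
        self.cache.update(pct=pct, structs=structs, weekly=weekly, truth=truth)
        d = self._dir("phantom")
        if d is not None:
            dio.write_volume(d / "pct.nii.gz", pct)
            for name, m in structs.masks.items():
                dio.write_mask(d / f"mask_{name}.nii.gz", m, pct.grid)
            dio.write_landmarks(d / "landmarks.csv", structs.landmarks)
            for i, wk in enumerate(weekly, 1):
                dio.write_volume(d / f"cbct_w{i}.nii.gz", wk)
                dio.write_dvf(d / f"dvf_true_w{i}.nii.gz", truth.dvf_true[i - 1])
                for name, m in truth.masks_true[i - 1].masks.items():
                    dio.write_mask(d / f"mask_true_w{i}_{name}.nii.gz", m, pct.grid)
                dio.write_landmarks(
                    d / f"landmarks_true_w{i}.csv", truth.landmarks_true[i - 1]
                )
        log.info("phantom stage: %d weeks in %.1f s", len(weekly), time.time() - t0)

    def _load_phantom(self) -> None:
        cfg = self.config.phantom
        d = self.workdir / "phantom"
        grid = cfg.grid
        pct = dio.read_volume(d / "pct.nii.gz", grid, role="pCT")
        mask_names = [p.stem.split(".")[0][5:] for p in sorted(d.glob("mask_[a-z]*.nii.gz"))
                      if not p.name.startswith("mask_true")]
        structs = StructureSet(
            grid,
            {n: dio.read_mask(d / f"mask_{n}.nii.gz", grid)[0] for n in mask_names},
            dio.read_landmarks(d / "landmarks.csv"),
        )
        weekly, dvfs, masks_true, lms = [], [], [], []
        for i in range(1, self.config.n_weeks + 1):
            wk = dio.read_volume(d / f"cbct_w{i}.nii.gz", grid, role="CBCT")
            wk.metadata["pad_value"] = cfg.fov_pad_hu
            weekly.append(wk)
            dvfs.append(dio.read_dvf(d / f"dvf_true_w{i}.nii.gz", grid))
            tm = {
                n: dio.read_mask(d / f"mask_true_w{i}_{n}.nii.gz", grid)[0]
                for n in mask_names
            }
            lm = dio.read_landmarks(d / f"landmarks_true_w{i}.csv")
            masks_true.append(StructureSet(grid, tm, lm))
            lms.append(lm)
        from .phantom import GroundTruth

        self.cache.update(
            pct=pct, structs=structs, weekly=weekly,
            truth=GroundTruth(dvfs, masks_true, lms, []),
        )

    def _phantom_artifacts(self):
        if "pct" not in self.cache:
            if self.workdir is None:
                raise StageError("run the 'phantom' stage first")
            try:
                self._load_phantom()
            except FileNotFoundError as exc:
                raise StageError("run the 'phantom' stage first") from exc
        return (self.cache["pct"], self.cache["structs"], self.cache["weekly"],
                self.cache["truth"])

    # -- stage 2: registration ---------------------------------------------

    def register(self) -> None:
        pct, _, weekly, _ = self._phantom_artifacts()
        t0 = time.time()
        rigids, dvfs = [], []
        for i, wk in enumerate(weekly, 1):
            rigid = rigid_register(wk, pct)
            dvf = deformable_register(wk, pct, self.config.registration, init=rigid)
            rigids.append(rigid)
            dvfs.append(dvf)
            log.info("registered pCT -> CBCT week %d (%.1f s)", i, time.time() - t0)
        self.cache.update(rigids=rigids, dvfs=dvfs)
        d = self._dir("register")
        if d is not None:
            for i, (rigid, dvf) in enumerate(zip(rigids, dvfs), 1):
                dio.write_dvf(d / f"dvf_w{i}.nii.gz", dvf)
                (d / f"rigid_w{i}.yaml").write_text(
                    yaml.safe_dump(
                        {"translation_mm": [float(v) for v in rigid.translation_mm],
                         "rotation_deg": [float(v) for v in rigid.rotation_deg],
                         "center_mm": [float(v) for v in rigid.center_mm]}
                    )
                )

    def _registrations(self):
        grid = self.config.phantom.grid

        def load():
            d = self.workdir / "register"
            rigids, dvfs = [], []
            for i in range(1, self.config.n_weeks + 1):
                data = yaml.safe_load((d / f"rigid_w{i}.yaml").read_text())
                rigids.append(
                    RigidTransform(
                        tuple(data["translation_mm"]), tuple(data["rotation_deg"]),
                        tuple(data["center_mm"]),
                    )
                )
                dvfs.append(dio.read_dvf(d / f"dvf_w{i}.nii.gz", grid))
            self.cache.update(rigids=rigids, dvfs=dvfs)
            return rigids

        if "dvfs" not in self.cache:
            try:
                load()
            except (FileNotFoundError, TypeError) as exc:
                raise StageError("run the 'register' stage first") from exc
        return self.cache["rigids"], self.cache["dvfs"]

    # -- stage 3: merge -----------------------------------------------------

    def merge(self) -> None:
        pct, _, weekly, _ = self._phantom_artifacts()
        rigids, dvfs = self._registrations()
        merged = []
        for i, wk in enumerate(weekly):
            limiting = make_limiting_contour(wk)
            merged.append(
                merge(pct, wk, limiting, source_week=i + 1, rigid=rigids[i], dvf=dvfs[i])
            )
        self.cache["merged"] = merged
        d = self._dir("merge")
        if d is not None:
            for i, m in enumerate(merged, 1):
                dio.write_volume(d / f"mcbct_w{i}.nii.gz", m.volume)
                dio.write_mask(d / f"provenance_cbct_w{i}.nii.gz",
                               m.provenance == 2, m.volume.grid)

    def _merged_volumes(self):
        grid = self.config.phantom.grid

        def load():
            d = self.workdir / "merge"
            vols = []
            for i in range(1, self.config.n_weeks + 1):
                vols.append(dio.read_volume(d / f"mcbct_w{i}.nii.gz", grid, role="mCBCT"))
            return vols

        if "merged" in self.cache:
            return [m.volume for m in self.cache["merged"]]
        return self._need("merged_volumes", load, "merge")

    # -- stage 4: dose ------------------------------------------------------

    def dose(self) -> None:
        pct, structs, _, _ = self._phantom_artifacts()
        _, dvfs = self._registrations()
        mvols = self._merged_volumes()
        plan = generate_plan(
            structs, self.config.prescription_gy, self.config.n_fractions,
            self.config.ptv_margin_mm,
        )
        plan = normalize_plan(plan, pct)
        pd_total = compute_dose(pct, plan, fractions=self.config.n_fractions, role="pD")
        pd_fx = compute_dose(pct, plan, fractions=1.0, role="pD_fraction")
        ecd, mdd = [], []
        for i, mv in enumerate(mvols):
            ecd.append(compute_dose(mv, plan, fractions=1.0, role=f"ecd_{i + 1}"))
            wk_mdd = deform_dose(pd_fx, dvfs[i])
            wk_mdd.role = f"mdd_{i + 1}"
            mdd.append(wk_mdd)
        self.cache.update(plan=plan, pd_total=pd_total, ecd=ecd, mdd=mdd)
        d = self._dir("dose")
        if d is not None:
            dio.write_dose(d / "pd.nii.gz", pd_total)
            for i in range(len(ecd)):
                dio.write_dose(d / f"ecd_w{i + 1}.nii.gz", ecd[i])
                dio.write_dose(d / f"mdd_w{i + 1}.nii.gz", mdd[i])

    def _doses(self):
        grid = self.config.phantom.grid

        def load():
            d = self.workdir / "dose"
            pd_total = dio.read_dose(d / "pd.nii.gz", grid, role="pD")
            ecd = [dio.read_dose(d / f"ecd_w{i}.nii.gz", grid, role=f"ecd_{i}")
                   for i in range(1, self.config.n_weeks + 1)]
            mdd = [dio.read_dose(d / f"mdd_w{i}.nii.gz", grid, role=f"mdd_{i}")
                   for i in range(1, self.config.n_weeks + 1)]
            self.cache.update(pd_total=pd_total, ecd=ecd, mdd=mdd)
            return pd_total

        if "pd_total" not in self.cache:
            self._need("pd_total", load, "dose")
        return self.cache["pd_total"], self.cache["ecd"], self.cache["mdd"]

    # -- stage 5: accumulate -------------------------------------------------

    def accumulate(self) -> None:
        _, _, weekly, _ = self._phantom_artifacts()
        pd_total, ecd, mdd = self._doses()
        ref = weekly[0]
        dvf_ref = [DisplacementField.zero(ref.grid)]
        for i, wk in enumerate(weekly[1:], 2):
            rigid = rigid_register(ref, wk)
            dvf_ref.append(deformable_register(ref, wk, self.config.registration, init=rigid))
            log.info("registered mCBCT week %d -> reference", i)
        w = [self.config.fractions_per_week] * len(weekly)
        sum_ecd = accumulate(ecd, dvf_ref, w, role="sum_ecD")
        sum_mdd = accumulate(mdd, dvf_ref, w, role="sum_mdD")
        self.cache.update(dvf_ref=dvf_ref, sum_ecd=sum_ecd, sum_mdd=sum_mdd)
        d = self._dir("accumulate")
        if d is not None:
            for i, f in enumerate(dvf_ref, 1):
                dio.write_dvf(d / f"dvf_ref_w{i}.nii.gz", f)
            dio.write_dose(d / "sum_ecd.nii.gz", sum_ecd)
            dio.write_dose(d / "sum_mdd.nii.gz", sum_mdd)

    def _sums(self):
        grid = self.config.phantom.grid

        def load():
            d = self.workdir / "accumulate"
            self.cache["sum_ecd"] = dio.read_dose(d / "sum_ecd.nii.gz", grid, "sum_ecD")
            self.cache["sum_mdd"] = dio.read_dose(d / "sum_mdd.nii.gz", grid, "sum_mdD")
            return self.cache["sum_ecd"]

        if "sum_ecd" not in self.cache:
            self._need("sum_ecd", load, "accumulate")
        return self.cache["sum_ecd"], self.cache["sum_mdd"]

    # -- stage 6: evaluate ---------------------------------------------------

    def _reference_structures(self) -> StructureSet:
        pct, structs, _, truth = self._phantom_artifacts()
        rigids, _ = self._registrations()
        ref = truth.masks_true[0].copy()
        # the PTV is transferred rigidly, never deformed
        ptv = transfer(structs, rigids[0], ["ptv45"])
        ref.masks["ptv45"] = ptv.masks["ptv45"]
        return ref

    def evaluate(self) -> None:
        pct, structs, weekly, truth = self._phantom_artifacts()
        _, dvfs = self._registrations()
        pd_total, _, _ = self._doses()
        sum_ecd, sum_mdd = self._sums()
        crit = self.config.criteria
        ref_structs = self._reference_structures()

        rows = []
        for struct, metrics in STRUCTURE_METRICS.items():
            ref_mask = ref_structs.masks[struct]
            pct_mask = structs.masks[struct]
            vals = {}
            for m in metrics:
                vals[("pd", m)] = dvh_metric(pd_total, pct_mask, m)
                vals[("ecd", m)] = dvh_metric(sum_ecd, ref_mask, m)
                vals[("mdd", m)] = dvh_metric(sum_mdd, ref_mask, m)
            for m in metrics:
                for label, num, den in COMPARISONS:
                    try:
                        pdiff = percent_diff(vals[(num, m)], vals[(den, m)])
                    except ZeroDivisionError:
                        pdiff = float("nan")  # e.g. V45 = 0 cc in the reference
                    rows.append(
                        {"structure": struct, "metric": m, "comparison": label,
                         "value": pdiff,
                         "numerator_gy": vals[(num, m)], "reference_gy": vals[(den, m)]}
                    )
        metrics_table = pd.DataFrame(rows)

        gamma_rows = []
        for struct in ("bladder", "rectum"):
            mask = ref_structs.masks[struct]
            for label, ev in (("pD-ecD", sum_ecd), ("pD-mdD", sum_mdd)):
                res = gamma_analysis(
                    pd_total, ev, mask,
                    dose_crit_pct=crit.dose_crit_pct,
                    dist_crit_mm=crit.dist_crit_mm,
                    low_threshold_pct=crit.low_threshold_pct,
                    pass_threshold_pct=crit.pass_threshold_pct,
                    search_step_mm=crit.gamma_search_step_mm,
                )
                gamma_rows.append(
                    {"patient": "phantom", "structure": struct, "comparison": label,
                     "pass_rate": res.pass_rate, "n_evaluated": res.n_evaluated,
                     "passed": res.passed}
                )
        gamma_table = pd.DataFrame(gamma_rows)

        vol_rows, dsc_rows = [], []
        for struct in ("bladder", "rectum"):
            vs = volume_stats(
                [t.masks[struct] for t in truth.masks_true],
                structs.masks[struct], pct.grid,
            )
            vol_rows.append(
                {"structure": struct, "pct_cc": vs.pct_volume_cc,
                 **{f"w{i + 1}_pct_diff": v for i, v in enumerate(vs.percent_diffs)},
                 "median_pct_diff": vs.median_percent_diff}
            )
            for i, dvf in enumerate(dvfs):
                moved = propagate(
                    StructureSet(pct.grid, {struct: structs.masks[struct]}), dvf
                )
                dsc_rows.append(
                    {"structure": struct, "week": i + 1,
                     "dsc": dice(moved.masks[struct], truth.masks_true[i].masks[struct])}
                )
        self.cache.update(
            metrics_table=metrics_table, gamma_table=gamma_table,
            volume_table=pd.DataFrame(vol_rows), dsc_table=pd.DataFrame(dsc_rows),
        )
        d = self._dir("evaluate")
        if d is not None:
            metrics_table.to_csv(d / "metrics.csv", index=False)
            gamma_table.to_csv(d / "gamma.csv", index=False)
            self.cache["volume_table"].to_csv(d / "volumes.csv", index=False)
            self.cache["dsc_table"].to_csv(d / "dsc.csv", index=False)

    def _evaluation_tables(self):
        def load():
            d = self.workdir / "evaluate"
            for key, fname in (
                ("metrics_table", "metrics.csv"), ("gamma_table", "gamma.csv"),
                ("volume_table", "volumes.csv"), ("dsc_table", "dsc.csv"),
            ):
                path = d / fname
                if not path.exists():
                    raise FileNotFoundError(path)
                self.cache[key] = pd.read_csv(path)
            return self.cache["metrics_table"]

        if "metrics_table" not in self.cache:
            self._need("metrics_table", load, "evaluate")
        return (self.cache["metrics_table"], self.cache["gamma_table"],
                self.cache["volume_table"], self.cache["dsc_table"])

    # -- stage 7: report -----------------------------------------------------

    def report(self) -> dict:
        metrics, gamma, volumes, dsc = self._evaluation_tables()
        rep = build_report(metrics_table=metrics, gamma_table=gamma, volume_table=volumes)
        rep["dsc"] = dsc
        d = self._dir("report")
        if d is not None:
            for name in ("metrics", "bands", "gamma", "gamma_summary", "volumes", "dsc"):
                if name in rep and isinstance(rep[name], pd.DataFrame):
                    rep[name].to_csv(d / f"{name}.csv", index=False)
            (d / "summary.txt").write_text(rep["summary_text"] + "\n")
        self.cache["report"] = rep
        return rep

    STAGES = ("phantom", "register", "merge", "dose", "accumulate", "evaluate", "report")

    def run_all(self) -> dict:
        for stage in self.STAGES:
            t0 = time.time()
            try:
                out = getattr(self, stage)()
            except Exception as exc:  # abort with the failing stage's name
                raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc
            log.info("stage %-10s done in %6.1f s", stage, time.time() - t0)
        return out


def run_pipeline(config: PipelineConfig | None = None,
                 workdir: str | Path | None = None,
                 seed: int | None = None) -> Pipeline:
    """Run every stage; returns the finished :class:`Pipeline` (with
    ``.cache['report']`` holding the tables)."""
    config = config or PipelineConfig()
    if seed is not None:
        config = config.with_seed(seed)
    pipe = Pipeline(config, workdir)
    pipe.run_all()
    return pipe
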