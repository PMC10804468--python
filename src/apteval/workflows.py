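"""End-to-end study orchestration on phantom cohorts.

Two studies mirror the clinical workflow:

* the *validation* study checks that proton dose calculated on the
  synthetic CT agrees with the deformed-repeat-CT gold standard (3D gamma
  at 3%/3mm and 2%/2mm inside the >10%-of-prescription region), and scores
  DIR-propagated contours against the ground truth (DSC, dose-index
  deviations);
* the *adaptation* study compares weekly re-planning against recalculating
  the initial plan on each weekly sCT, accumulates both arms on the
  planning CT through the inverse DVFs, and reports coverage tracks,
  accumulated dose-volume indices, NTCP per endpoint and paired t-tests
  across the cohort.

Everything is deterministic under a fixed master seed; per-phantom seeds
are derived by a simple counter scheme.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dose import compute_dose
from .evaluation import (
    GammaConfig,
    accumulate_dose,
    check_constraints,
    dose_indices,
    gamma_3d,
    load_ntcp_params,
    ntcp_from_dose,
    paired_ttest,
    weekly_fraction_schedule,
)
from .grids import StructureSet, VoxelImage, dice
from .phantom import PhantomSpec, build_planning_phantom, sample_weekly_anatomy, simulate_cbct
from .planning import (
    DEFAULT_CONSTRAINTS,
    PlanConfig,
    adapt_plan,
    create_plan,
    evaluate_plan_robustness,
)
from .registration import (
    InversionConfig,
    RegistrationConfig,
    deformable_register,
    invert_dvf,
)
from .sct import SctInputs, apply_artifact_override, build_sct, build_rct_def, propagate_contours

OAR_NAMES = ("spinal_cord", "larynx", "constrictors", "parotid_l", "parotid_r",
             "esophagus", "mandible")


@dataclass
class StudyConfig:
    """Cohort, weeks and sub-configs of one study run."""

    phantoms: Sequence[PhantomSpec]
    weeks: int = 3
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    plan: PlanConfig = field(default_factory=PlanConfig)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    gamma_criteria: Tuple[Tuple[float, float], ...] = ((3.0, 3.0), (2.0, 2.0))
    ntcp_params_path: Optional[str] = None
    out_dir: Optional[str] = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.phantoms) < 1:
            raise ValueError("cohort size must be >= 1")
        if self.weeks < 1:
            raise ValueError("need at least one weekly sample")


def default_cohort(master_seed: int = 0, grid=None,
                   which: Optional[Sequence[str]] = None) -> List[PhantomSpec]:
    """The six-trajectory phantom cohort.

    Static control, weight loss, tumor growth, tumor shrink, combined
    change, and a phantom whose tertiary CTV is partly outside the CBCT
    FOV — one phantom per phenomenon the studies exercise.
    """
    recipes = {
        "static": {},
        "weight_loss": {"weekly_body_shrink": 0.02},
        "tumor_growth": {"weekly_tumor_change": 0.03},
        "tumor_shrink": {"weekly_tumor_change": -0.03},
        "combined": {"weekly_body_shrink": 0.015, "weekly_tumor_change": 0.02},
        "fov_truncated": {"weekly_body_shrink": 0.015},
    }
    names = list(recipes) if which is None else list(which)
    cohort = []
    for i, name in enumerate(names):
        kw = dict(recipes[name])
        kw["seed"] = master_seed * 100 + i
        if grid is not None:
            kw["grid"] = grid
        spec = PhantomSpec(**kw)
        if name == "fov_truncated":
            # tumor shifted inferiorly and a tight FOV: tertiary CTV sticks out
            spec = dataclasses.replace(
                spec,
                tumor_center_mm=(spec.tumor_center_mm[0], spec.tumor_center_mm[1],
                                 spec.tumor_center_mm[2] - 0.18 * spec.grid.extent_mm[2]),
                cbct=dataclasses.replace(spec.cbct,
                                         fov_axial_mm=0.6 * spec.grid.extent_mm[2]),
            )
        cohort.append(spec)
    return cohort


@dataclass
class EvaluationReport:
    """Bundle of tabular study outputs (one DataFrame per aspect)."""

    tables: Dict[str, pd.DataFrame]

    def __getitem__(self, name: str) -> pd.DataFrame:
        return self.tables[name]

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(os.path.join(out_dir, f"{name}.csv"), index=False)


def _weekly_pipeline(spec: PhantomSpec, week: int, pct: VoxelImage,
                     cfg: StudyConfig):
    """Shared weekly steps: ground truth, CBCT, DIR, sCT."""
    gt_dvf, deformed_ct, gt_contours = sample_weekly_anatomy(spec, week)
    cbct, fov = simulate_cbct(deformed_ct, spec, week)
    dvf = deformable_register(cbct, pct, cfg.registration, fov)
    sct, _prov = build_sct(SctInputs(
        pct, dvf, fov,
        artifact_mask=None,  # override applied on the planning CT upstream
        override_hu=cfg.plan.artifact_override_hu,
    ))
    return gt_dvf, deformed_ct, gt_contours, cbct, fov, dvf, sct


def run_validation_study(cfg: StudyConfig) -> EvaluationReport:
    """sCT dose-calculation validation: gamma, DSC and index deviations.

    Per phantom-week the initial plan is recalculated on the sCT and on
    the deformed-CT gold standard; deviations are tabulated for three
    comparisons: gold−planned(pCT), gold−sCT(uncorrected contours) and
    gold−sCT(corrected contours).
    """
    gamma_rows, dsc_rows, idx_rows = [], [], []
    for p_i, spec in enumerate(cfg.phantoms):
        pct, structures = build_planning_phantom(spec)
        pct_ov = apply_artifact_override(pct, structures["artifact"],
                                         cfg.plan.artifact_override_hu)
        plan = create_plan(pct_ov, structures, cfg.plan)
        rx = max(v[0] for v in structures.prescriptions.values())
        body = structures["body"]
        planned = compute_dose(pct_ov, plan.beams, plan.spots_per_beam,
                               plan.weights, voxel_mask=body, rbe=plan.rbe,
                               curve=cfg.plan.curve)
        for week in range(1, cfg.weeks + 1):
            (gt_dvf, deformed_ct, gt_contours, cbct, fov, dvf, sct
             ) = _weekly_pipeline(spec, week, pct_ov, cfg)
            rct_def, _ = build_rct_def(deformed_ct, cbct, cfg.registration,
                                       fov, gt_contours)
            body_w = gt_contours["body"] | body
            dose_sct = compute_dose(sct, plan.beams, plan.spots_per_beam,
                                    plan.weights, voxel_mask=body_w,
                                    rbe=plan.rbe, curve=cfg.plan.curve)
            dose_gold = compute_dose(rct_def, plan.beams, plan.spots_per_beam,
                                     plan.weights, voxel_mask=body_w,
                                     rbe=plan.rbe, curve=cfg.plan.curve)
            for dd, dta in cfg.gamma_criteria:
                rate, _gmap = gamma_3d(dose_gold, dose_sct,
                                       GammaConfig(dose_pct=dd, dta_mm=dta,
                                                   norm_dose_gy=rx))
                gamma_rows.append({
                    "phantom": p_i, "week": week,
                    "criteria": f"{dta:g}mm/{dd:g}%", "pass_rate_pct": rate,
                })
            propagated = propagate_contours(structures, dvf)
            for name in gt_contours.names():
                if name in ("artifact", "entry_avoidance"):
                    continue
                dsc_rows.append({
                    "phantom": p_i, "week": week, "structure": name,
                    "dsc": dice(propagated[name], gt_contours[name]),
                    "gt_voxels": int(gt_contours[name].sum()),
                })
            # dose-volume index deviations for the three comparisons
            for name in list(structures.ctv_names()) + [n for n in OAR_NAMES
                                                        if n in structures]:
                rx_s = structures.prescriptions.get(name, (None,))[0]
                gold_m = gt_contours[name]
                unc_m = propagated[name]
                plan_m = structures[name]
                if not (gold_m.any() and unc_m.any() and plan_m.any()):
                    continue
                gold = dose_indices(dose_gold, gold_m, rx_s)
                on_pct = dose_indices(planned, plan_m, rx_s)
                on_sct_unc = dose_indices(dose_sct, unc_m, rx_s)
                on_sct_cor = dose_indices(dose_sct, gold_m, rx_s)
                for index in ("Dmean", "Dmax", "V95", "V100"):
                    if index not in gold:
                        continue
                    scale = 100.0 / rx if index in ("Dmean", "Dmax") else 1.0
                    for comp, other in (("rctdef_minus_pct", on_pct),
                                        ("rctdef_minus_sct_uncorr", on_sct_unc),
                                        ("rctdef_minus_sct", on_sct_cor)):
                        idx_rows.append({
                            "phantom": p_i, "week": week, "structure": name,
                            "index": index, "comparison": comp,
                            "delta": (gold[index] - other[index]) * scale
                            if index in ("Dmean", "Dmax")
                            else gold[index] - other[index],
                        })
    report = EvaluationReport({
        "gamma": pd.DataFrame(gamma_rows),
        "dsc": pd.DataFrame(dsc_rows),
        "index_deviation": pd.DataFrame(idx_rows),
    })
    if cfg.out_dir:
        report.save(cfg.out_dir)
    return report


def run_adaptation_study(cfg: StudyConfig) -> EvaluationReport:
    """Adapt-vs-non-adapt comparison with inverse-DVF dose accumulation.

    Non-adapt: initial plan recalculated on each weekly sCT.  Adapt: full
    re-plan on each weekly sCT with the ground-truth ("physician
    corrected") weekly contours.  Both arms are accumulated on the
    planning CT with fraction weights; NTCP and paired t-tests compare
    the arms across the cohort.
    """
    ntcp_params = load_ntcp_params(cfg.ntcp_params_path)
    coverage_rows, acc_rows, ntcp_rows, robust_rows = [], [], [], []
    constraint_rows: List[Dict] = []
    per_phantom_acc: List[Dict] = []

    for p_i, spec in enumerate(cfg.phantoms):
        pct, structures = build_planning_phantom(spec)
        pct_ov = apply_artifact_override(pct, structures["artifact"],
                                         cfg.plan.artifact_override_hu)
        plan, nom_infl, scen_infl = create_plan(pct_ov, structures, cfg.plan,
                                                return_influences=True)
        rx = max(v[0] for v in structures.prescriptions.values())
        body = structures["body"]
        planned = compute_dose(pct_ov, plan.beams, plan.spots_per_beam,
                               plan.weights, voxel_mask=body, rbe=plan.rbe,
                               curve=cfg.plan.curve)
        fx = weekly_fraction_schedule(spec.n_fractions, cfg.weeks)
        weekly_nonadapt, weekly_adapt, inv_dvfs = [], [], []
        for week in range(1, cfg.weeks + 1):
            (gt_dvf, deformed_ct, gt_contours, cbct, fov, dvf, sct
             ) = _weekly_pipeline(spec, week, pct_ov, cfg)
            body_w = gt_contours["body"] | body
            dose_na = compute_dose(sct, plan.beams, plan.spots_per_beam,
                                   plan.weights, voxel_mask=body_w,
                                   rbe=plan.rbe, curve=cfg.plan.curve)
            wplan, wnom, wscen = adapt_plan(sct, gt_contours, cfg.plan,
                                            return_influences=True)
            dose_ad = compute_dose(sct, wplan.beams, wplan.spots_per_beam,
                                   wplan.weights, voxel_mask=body_w,
                                   rbe=wplan.rbe, curve=cfg.plan.curve)
            rob = evaluate_plan_robustness(wplan, gt_contours, wnom, wscen)
            for name, rep in rob.items():
                robust_rows.append({
                    "phantom": p_i, "week": week, "structure": name,
                    "worst_case_v95": rep["worst_case_v95"],
                    "pass": rep["pass"],
                })
            for name in gt_contours.ctv_names():
                rx_s = gt_contours.prescriptions[name][0]
                for arm, dose_img in (("non_adapt", dose_na), ("adapt", dose_ad)):
                    v = dose_indices(dose_img, gt_contours[name], rx_s)
                    coverage_rows.append({
                        "phantom": p_i, "week": week, "structure": name,
                        "arm": arm, "V95": v["V95"], "V100": v["V100"],
                    })
            # audit the weekly OAR doses against the clinical constraint table
            for arm, dose_img in (("non_adapt", dose_na), ("adapt", dose_ad)):
                idx = {
                    name: dose_indices(dose_img, gt_contours[name])
                    for name in OAR_NAMES
                    if name in gt_contours and gt_contours[name].any()
                }
                for rec in check_constraints(idx, DEFAULT_CONSTRAINTS, rx):
                    rec.update(phantom=p_i, week=week, arm=arm)
                    constraint_rows.append(rec)
            weekly_nonadapt.append(dose_na)
            weekly_adapt.append(dose_ad)
            inv_dvfs.append(invert_dvf(dvf, cfg.inversion))

        acc_na = accumulate_dose(weekly_nonadapt, inv_dvfs, fx)
        acc_ad = accumulate_dose(weekly_adapt, inv_dvfs, fx)
        arms = {"plan": planned, "non_adapt": acc_na, "adapt": acc_ad}
        acc_entry = {"phantom": p_i}
        for name in list(structures.ctv_names()) + [n for n in OAR_NAMES
                                                    if n in structures]:
            rx_s = structures.prescriptions.get(name, (None,))[0]
            for arm, dimg in arms.items():
                idx = dose_indices(dimg, structures[name], rx_s)
                for index in ("Dmean", "Dmax", "V95", "V100", "V20Gy"):
                    if index not in idx:
                        continue
                    acc_rows.append({
                        "phantom": p_i, "structure": name, "arm": arm,
                        "index": index, "value": idx[index],
                    })
                    acc_entry[(name, index, arm)] = idx[index]
        for key, params in ntcp_params.items():
            sname = params.structure
            cands = [sname] if sname in structures else [
                n for n in structures.names() if n.startswith(sname)]
            for cand in cands:
                if not structures[cand].any():
                    continue
                for arm, dimg in arms.items():
                    val = 100.0 * ntcp_from_dose(dimg, structures[cand], params)
                    ntcp_rows.append({
                        "phantom": p_i, "endpoint": key, "structure": cand,
                        "arm": arm, "ntcp_pct": val,
                    })
                    acc_entry[("ntcp_" + key + "_" + cand, "NTCP", arm)] = val
        per_phantom_acc.append(acc_entry)

    # paired tests across the cohort: non-adapt vs plan, adapt vs non-adapt
    test_rows = []
    if len(per_phantom_acc) >= 2:
        keys = sorted({k for e in per_phantom_acc for k in e if k != "phantom"},
                      key=str)
        for key in keys:
            name, index, arm = key
            if arm != "plan":
                continue
            trip = {}
            for a in ("plan", "non_adapt", "adapt"):
                vals = [e.get((name, index, a)) for e in per_phantom_acc]
                if any(v is None for v in vals):
                    break
                trip[a] = vals
            if len(trip) < 3:
                continue
            for pair in (("non_adapt", "plan"), ("adapt", "non_adapt")):
                res = paired_ttest(trip[pair[0]], trip[pair[1]])
                test_rows.append({
                    "structure": name, "index": index,
                    "comparison": f"{pair[0]}_vs_{pair[1]}",
                    "mean_difference": res.mean_difference,
                    "p_value": res.p_value,
                    "zero_variance": res.zero_variance,
                })

    report = EvaluationReport({
        "weekly_coverage": pd.DataFrame(coverage_rows),
        "weekly_constraints": pd.DataFrame(constraint_rows),
        "adapted_robustness": pd.DataFrame(robust_rows),
        "accumulated_indices": pd.DataFrame(acc_rows),
        "ntcp": pd.DataFrame(ntcp_rows),
        "paired_tests": pd.DataFrame(test_rows),
    })
    if cfg.out_dir:
        report.save(cfg.out_dir)
    return report
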