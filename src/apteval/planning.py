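"""Robust IMPT planning: objectives, spot-weight optimization, normalization.

Objective generation is rule based: per CTV a robust minimum-dose
objective at prescription and a maximum at 103% of prescription; per OAR
an objective at a stated fraction (default 90%) of its clinical
constraint.  Only the targets are robustly optimized — their penalties
are aggregated as the worst case over the 12 setup/range uncertainty
scenarios (±3 mm cardinal shifts × ±3% range) plus the nominal scenario —
while OAR penalties are evaluated on the nominal dose only.  Weights are
non-negative and optimized deterministically (L-BFGS-B with bound
constraints, uniform initialisation, fixed iteration budget).

Plans are normalised so that 95% of the primary CTV receives 100% of its
prescription (V100 = 95%), then robustly evaluated (every CTV must keep
V95 > 95% in the worst scenario).  Weekly adaptation is a full re-run of
spot placement, objective generation, optimization and normalization on
the weekly synthetic CT — no warm start from the initial plan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize as sciopt

from .dose import (
    NOMINAL,
    Beam,
    InfluenceMatrix,
    RSPCurve,
    Scenario,
    Spot,
    compute_influence,
    place_spots,
)
from .grids import StructureSet, VoxelImage

# Clinical dose-volume constraint table for head-and-neck IMPT planning.
# 'limit_pct' values are relative to the primary prescription.
DEFAULT_CONSTRAINTS: Tuple[Dict, ...] = (
    {"structure": "body", "metric": "Dmax", "limit_pct": 115.0},
    {"structure": "brainstem", "metric": "Dmax", "limit_gy": 54.0},
    {"structure": "cochlea", "metric": "Dmean", "limit_gy": 40.0},
    {"structure": "constrictors", "metric": "Dmean", "limit_gy": 50.0},
    {"structure": "larynx", "metric": "Dmean", "limit_gy": 50.0},
    {"structure": "mandible", "metric": "Dmax", "limit_gy": 75.0},
    {"structure": "oral_cavity", "metric": "Dmean", "limit_gy": 50.0},
    {"structure": "spinal_cord", "metric": "Dmax", "limit_gy": 48.0},
    {"structure": "parotid", "metric": "Dmean", "limit_gy": 26.0},
    {"structure": "parotid", "metric": "V20Gy", "limit_pct_volume": 50.0},
    {"structure": "esophagus", "metric": "Dmean", "limit_gy": 40.0},
    {"structure": "eye", "metric": "Dmax", "limit_gy": 45.0},
    {"structure": "optic_nerve", "metric": "Dmax", "limit_gy": 50.0},
    {"structure": "optic_chiasm", "metric": "Dmax", "limit_gy": 50.0},
    {"structure": "submandibular", "metric": "Dmean", "limit_gy": 39.0},
)


@dataclass
class Objective:
    """One optimization objective on a named structure."""

    structure: str
    kind: str  # target-min | target-max | oar-max | oar-mean | oar-dvh-point
    dose_gy: float
    volume_pct: Optional[float] = None  # dvh-point only
    weight: float = 1.0
    robust: bool = False

    def __post_init__(self) -> None:
        kinds = ("target-min", "target-max", "oar-max", "oar-mean", "oar-dvh-point")
        if self.kind not in kinds:
            raise ValueError(f"unknown objective kind '{self.kind}'")
        if self.dose_gy < 0 or self.weight < 0:
            raise ValueError("dose level and weight must be >= 0")
        if self.kind == "oar-dvh-point" and self.volume_pct is None:
            raise ValueError("dvh-point objective needs a volume level")


@dataclass
class ScenarioSet:
    """The robustness scenario set plus the nominal reference."""

    scenarios: Tuple[Scenario, ...]
    nominal: Scenario = NOMINAL

    def __len__(self) -> int:
        return len(self.scenarios)


def enumerate_scenarios(setup_mm: float = 3.0,
                        range_fraction: float = 0.03) -> ScenarioSet:
    """Cartesian product of the 6 signed cardinal shifts with the 2 range
    scales — 12 scenarios for (3 mm, 3%); degenerate magnitudes deduplicate."""
    if setup_mm < 0 or range_fraction < 0:
        raise ValueError("uncertainty magnitudes must be >= 0")
    shifts = []
    for axis in range(3):
        for sgn in (+1.0, -1.0):
            v = [0.0, 0.0, 0.0]
            v[axis] = sgn * setup_mm
            shifts.append(tuple(v))
    scales = (1.0 - range_fraction, 1.0 + range_fraction)
    seen = []
    for sh in shifts:
        for sc in scales:
            s = Scenario(sh, sc)
            if s not in seen:
                seen.append(s)
    if len(seen) == 1 and seen[0] == NOMINAL:
        return ScenarioSet((NOMINAL,))
    return ScenarioSet(tuple(seen))


def _match_constraints(name: str, table: Sequence[Dict]) -> List[Dict]:
    base = name
    for suffix in ("_l", "_r", "_ips", "_con"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return [c for c in table if c["structure"] in (name, base)]


def generate_objectives(
    structures: StructureSet,
    constraints: Sequence[Dict] = DEFAULT_CONSTRAINTS,
    oar_fraction: float = 0.9,
    target_min_weight: float = 1000.0,
    target_max_weight: float = 10.0,
    oar_weight: float = 3.0,
) -> List[Objective]:
    """Deterministic rule-based objective list.

    CTVs get robust target-min at prescription and target-max at 103% of
    prescription.  Each OAR with a constraint gets an objective at
    ``oar_fraction`` of the constraint level (non-robust).  Structures
    with no matching constraint are skipped.
    """
    objs: List[Objective] = []
    rx_primary = None
    for name in structures.ctv_names():
        rx, _ = structures.prescriptions[name]
        if rx_primary is None or rx > rx_primary:
            rx_primary = rx
        objs.append(Objective(name, "target-min", rx,
                              weight=target_min_weight, robust=True))
        objs.append(Objective(name, "target-max", 1.03 * rx,
                              weight=target_max_weight, robust=True))
    aux = {"artifact", "entry_avoidance", "fov"}
    for name in structures.names():
        if name in structures.prescriptions or name in aux:
            continue
        if not structures[name].any():
            continue
        for c in _match_constraints(name, constraints):
            metric = c["metric"]
            if metric == "Dmax":
                limit = c.get("limit_gy")
                if limit is None:
                    limit = c["limit_pct"] / 100.0 * rx_primary
                w = oar_weight * (5.0 if name == "body" else 1.0)
                objs.append(Objective(name, "oar-max", oar_fraction * limit, weight=w))
            elif metric == "Dmean":
                objs.append(Objective(name, "oar-mean",
                                      oar_fraction * c["limit_gy"],
                                      weight=oar_weight))
            elif metric.startswith("V") and metric.endswith("Gy"):
                at = float(metric[1:-2])
                objs.append(Objective(
                    name, "oar-dvh-point", at,
                    volume_pct=oar_fraction * c["limit_pct_volume"],
                    weight=oar_weight,
                ))
    return objs


@dataclass
class OptimizerConfig:
    max_iterations: int = 120
    robust_aggregation: str = "worst"  # "worst" | "expected"
    include_nominal_in_worst_case: bool = True

    def __post_init__(self) -> None:
        if self.robust_aggregation not in ("worst", "expected"):
            raise ValueError("robust_aggregation must be 'worst' or 'expected'")


def _penalty_and_grad(d: np.ndarray, obj: Objective) -> Tuple[float, np.ndarray]:
    """One-sided quadratic penalty (normalised by the dose level) and its
    gradient with respect to the voxel doses."""
    n = d.size
    lvl = max(obj.dose_gy, 1e-6)
    if obj.kind == "target-min":
        short = np.clip(lvl - d, 0.0, None)
        val = float((short**2).sum()) / (n * lvl**2)
        grad = -2.0 * short / (n * lvl**2)
    elif obj.kind in ("target-max", "oar-max"):
        over = np.clip(d - lvl, 0.0, None)
        val = float((over**2).sum()) / (n * lvl**2)
        grad = 2.0 * over / (n * lvl**2)
    elif obj.kind == "oar-mean":
        m = float(d.mean())
        over = max(m - lvl, 0.0)
        val = (over / lvl) ** 2
        grad = np.full(n, 2.0 * over / (n * lvl**2))
    elif obj.kind == "oar-dvh-point":
        frac_allowed = obj.volume_pct / 100.0
        above = d >= lvl
        n_above = int(above.sum())
        n_allowed = int(np.floor(frac_allowed * n))
        grad = np.zeros(n)
        if n_above <= n_allowed:
            val = 0.0
        else:
            # penalise the excess voxels just above the dose level
            excess = n_above - n_allowed
            idx_above = np.flatnonzero(above)
            order = np.argsort(d[idx_above], kind="stable")
            hit = idx_above[order[:excess]]
            over = d[hit] - lvl
            val = float((over**2).sum()) / (n * lvl**2)
            grad[hit] = 2.0 * over / (n * lvl**2)
    else:  # pragma: no cover
        raise ValueError(obj.kind)
    return obj.weight * val, obj.weight * grad


def optimize_weights(
    nominal: InfluenceMatrix,
    scenario_influences: Sequence[InfluenceMatrix],
    objectives: Sequence[Objective],
    structure_rows: Dict[str, np.ndarray],
    scenario_structure_rows: Dict[str, np.ndarray],
    cfg: Optional[OptimizerConfig] = None,
) -> np.ndarray:
    """Minimise the weighted penalty sum over non-negative spot weights.

    ``structure_rows`` maps structure names to row indices of the nominal
    influence matrix; ``scenario_structure_rows`` likewise for the
    scenario matrices (robust target terms only).  Deterministic: uniform
    initial weights and a fixed L-BFGS-B iteration budget.
    """
    cfg = cfg or OptimizerConfig()
    n_spots = nominal.matrix.shape[1]
    if n_spots == 0:
        raise ValueError("no spots to optimize")

    live = [
        (i, obj) for i, obj in enumerate(objectives)
        if structure_rows.get(obj.structure) is not None
        and structure_rows[obj.structure].size > 0
    ]
    any_robust = any(obj.robust for _, obj in live)
    scen_mats = [infl.matrix for infl in scenario_influences] if any_robust else []

    # uniform initialisation: mean dose of the first target at its level
    w0_val = 1.0
    for _, obj in live:
        if obj.kind == "target-min":
            rows = structure_rows[obj.structure]
            sub_sum = float(nominal.matrix[rows].sum())
            md = sub_sum / rows.size
            if md > 0:
                w0_val = obj.dose_gy / md
            break
    w0 = np.full(n_spots, w0_val)

    def fun(w: np.ndarray) -> Tuple[float, np.ndarray]:
        # one matvec per matrix; gradients scattered into per-matrix row
        # vectors and pulled back with one transposed matvec each
        total = 0.0
        d_nom = nominal.matrix @ w
        g_nom = np.zeros(d_nom.size)
        d_scen = [m @ w for m in scen_mats]
        g_scen: List[Optional[np.ndarray]] = [None] * len(scen_mats)
        for _, obj in live:
            rows = structure_rows[obj.structure]
            v_n, grad_n = _penalty_and_grad(d_nom[rows], obj)
            if not obj.robust or not scen_mats:
                total += v_n
                g_nom[rows] += grad_n
                continue
            srows = scenario_structure_rows[obj.structure]
            cands = [(v_n, grad_n, -1)]
            if not cfg.include_nominal_in_worst_case:
                cands = []
            for j, d_s in enumerate(d_scen):
                v_s, grad_s = _penalty_and_grad(d_s[srows], obj)
                cands.append((v_s, grad_s, j))
            if cfg.robust_aggregation == "worst":
                cands = [max(cands, key=lambda t: t[0])]
                share = 1.0
            else:
                share = 1.0 / len(cands)
            for v_s, grad_s, j in cands:
                total += share * v_s
                if j < 0:
                    g_nom[rows] += share * grad_s
                else:
                    if g_scen[j] is None:
                        g_scen[j] = np.zeros(d_scen[j].size)
                    g_scen[j][srows] += share * grad_s
        grad = nominal.matrix.T @ g_nom
        for j, gs in enumerate(g_scen):
            if gs is not None:
                grad += scen_mats[j].T @ gs
        if not np.isfinite(total):
            raise RuntimeError("non-finite objective value")
        return total, grad

    res = sciopt.minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * n_spots,
        options={"maxiter": cfg.max_iterations, "ftol": 1e-12, "gtol": 1e-10},
    )
    return np.clip(res.x, 0.0, None)


def normalization_factor(ctv_dose: np.ndarray, rx_gy: float) -> float:
    """Scale factor s so that after scaling, V100 of the CTV is 95%.

    Sorting convention: with N voxels, m = ceil(0.95 N) voxels must reach
    the prescription, so s = rx / d_(N-m) (ascending order) — ties break
    toward satisfying V100 >= 95%.
    """
    d = np.sort(np.asarray(ctv_dose, dtype=float))
    n = d.size
    if n == 0 or d[-1] <= 0:
        raise ValueError("zero dose in the primary CTV: cannot normalise")
    m = int(np.ceil(0.95 * n))
    ref = d[n - m]
    if ref <= 0:
        raise ValueError("the 95% coverage quantile of the CTV dose is zero")
    return float(rx_gy / ref)


def normalize_plan(plan: "Plan", ctv_primary_dose: np.ndarray,
                   rx_gy: float) -> float:
    """Rescale a plan in place so the primary CTV reaches V100 = 95%.

    ``ctv_primary_dose`` is the plan's nominal dose inside the primary
    CTV.  Returns the applied scale factor (also folded into the plan's
    stored normalization).  Idempotent: applying it to an already
    normalised plan returns 1.0.
    """
    s = normalization_factor(ctv_primary_dose, rx_gy)
    plan.weights = plan.weights * s
    for spots in plan.spots_per_beam:
        for sp in spots:
            sp.weight *= s
    plan.normalization *= s
    return s


def load_constraints(path: str) -> Tuple[Dict, ...]:
    """Load a clinical constraint table from YAML (list of records with
    ``structure``, ``metric`` and a limit field)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return tuple(raw)


def save_constraints(table: Sequence[Dict], path: str) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump([dict(c) for c in table], fh)


def v_at(dose: np.ndarray, level_gy: float) -> float:
    """% of voxels with dose >= level."""
    d = np.asarray(dose)
    if d.size == 0:
        raise ValueError("empty dose sample")
    return 100.0 * float((d >= level_gy).mean())


def robust_evaluate(
    ctv_scenario_doses: Dict[str, Sequence[np.ndarray]],
    prescriptions: Dict[str, Tuple[float, int]],
    threshold_pct: float = 95.0,
) -> Dict[str, Dict]:
    """Worst-case CTV coverage report.

    ``ctv_scenario_doses[name]`` holds the voxel doses of that CTV under
    every scenario (nominal included by the caller).  Each CTV passes when
    its V95 exceeds the threshold in the worst scenario.
    """
    report = {}
    for name, doses in ctv_scenario_doses.items():
        rx = prescriptions[name][0]
        v95s = [v_at(d, 0.95 * rx) for d in doses]
        worst = min(v95s)
        report[name] = {
            "v95_per_scenario": v95s,
            "worst_case_v95": worst,
            "pass": bool(worst > threshold_pct),
        }
    return report


# ---------------------------------------------------------------------------
# end-to-end plan creation


@dataclass
class PlanConfig:
    """Everything that defines how a plan is created."""

    beams: Tuple[Beam, ...] = (
        Beam(direction=(1.0, 0.0, 0.0), lateral_spacing_mm=8.0,
             layer_spacing_mm=6.0, name="left_lateral"),
        Beam(direction=(-1.0, 0.0, 0.0), lateral_spacing_mm=8.0,
             layer_spacing_mm=6.0, name="right_lateral"),
    )
    setup_uncertainty_mm: float = 3.0
    range_uncertainty: float = 0.03
    spot_lateral_margin_mm: float = 4.0  # extra spot coverage for the penumbra
    rbe: float = 1.1
    oar_fraction: float = 0.9
    curve: RSPCurve = field(default_factory=RSPCurve)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    artifact_override_hu: float = 40.0
    objective_margin_mm: float = 10.0  # hot-spot control region around the targets


@dataclass
class Plan:
    """An optimized, normalised IMPT plan."""

    beams: Tuple[Beam, ...]
    spots_per_beam: Tuple[Tuple[Spot, ...], ...]
    weights: np.ndarray
    scenario_set: ScenarioSet
    normalization: float
    prescriptions: Dict[str, Tuple[float, int]]
    rbe: float = 1.1

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("spot weights must be >= 0")
        if self.normalization <= 0:
            raise ValueError("normalization factor must be > 0")

    @property
    def n_spots(self) -> int:
        return int(self.weights.size)

    def to_json(self, path: str) -> None:
        d = {
            "beams": [asdict(b) for b in self.beams],
            "spots_per_beam": [
                [{"lateral_mm": list(s.lateral_mm), "range_mm": s.range_mm}
                 for s in spots]
                for spots in self.spots_per_beam
            ],
            "weights": [float(w) for w in self.weights],
            "scenarios": [
                {"shift_mm": list(s.shift_mm), "range_scale": s.range_scale}
                for s in self.scenario_set.scenarios
            ],
            "normalization": self.normalization,
            "prescriptions": {k: list(v) for k, v in self.prescriptions.items()},
            "rbe": self.rbe,
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "Plan":
        with open(path) as fh:
            d = json.load(fh)
        beams = tuple(Beam(**b) for b in d["beams"])
        spots = tuple(
            tuple(Spot(tuple(s["lateral_mm"]), s["range_mm"]) for s in lst)
            for lst in d["spots_per_beam"]
        )
        scen = ScenarioSet(tuple(
            Scenario(tuple(s["shift_mm"]), s["range_scale"]) for s in d["scenarios"]
        ))
        return cls(
            beams, spots, np.asarray(d["weights"], dtype=float), scen,
            d["normalization"],
            {k: (v[0], int(v[1])) for k, v in d["prescriptions"].items()},
            d.get("rbe", 1.1),
        )


def _rows_in(voxel_index: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row indices (within a matrix built on voxel_index) of the masked voxels."""
    flat = np.flatnonzero(mask.ravel())
    pos = np.searchsorted(voxel_index, flat)
    pos = pos[pos < voxel_index.size]
    keep = voxel_index[pos] == flat[: pos.size]
    return pos[keep]


def create_plan(
    ct: VoxelImage,
    structures: StructureSet,
    cfg: Optional[PlanConfig] = None,
    return_influences: bool = False,
):
    """Full planning pass: spot placement, robust optimization, normalization.

    The CT should already carry the dental-artifact HU override.  Returns
    the :class:`Plan` (and, optionally, the influence matrices used, so
    callers can evaluate robustness without recomputation).
    """
    cfg = cfg or PlanConfig()
    from .phantom import _dilate_mm

    avoidance = structures["entry_avoidance"] if "entry_avoidance" in structures else None
    body = structures["body"] if "body" in structures else np.ones(ct.grid.dims, bool)

    spots_per_beam: List[List[Spot]] = []
    field_union = np.zeros(ct.grid.dims, dtype=bool)
    for beam in cfg.beams:
        spots, ftarget = place_spots(
            structures, beam, ct, cfg.curve,
            setup_margin_mm=cfg.setup_uncertainty_mm,
            range_margin=cfg.range_uncertainty,
            avoidance_mask=avoidance,
            lateral_margin_mm=cfg.spot_lateral_margin_mm,
        )
        spots_per_beam.append(spots)
        field_union |= ftarget

    objectives = generate_objectives(structures, oar_fraction=cfg.oar_fraction)
    obj_names = {o.structure for o in objectives}
    obj_mask = _dilate_mm(field_union, ct.grid, cfg.objective_margin_mm) & body
    for name in obj_names:
        if name in structures:
            obj_mask |= structures[name]
    ctv_union = np.zeros(ct.grid.dims, dtype=bool)
    for name in structures.ctv_names():
        ctv_union |= structures[name]

    scen_set = enumerate_scenarios(cfg.setup_uncertainty_mm, cfg.range_uncertainty)
    nominal = compute_influence(ct, cfg.beams, spots_per_beam, obj_mask,
                                scenario=NOMINAL, rbe=cfg.rbe, curve=cfg.curve)
    scen_infl = [
        compute_influence(ct, cfg.beams, spots_per_beam, ctv_union,
                          scenario=s, rbe=cfg.rbe, curve=cfg.curve)
        for s in scen_set.scenarios
    ]

    structure_rows = {
        name: _rows_in(nominal.voxel_index, structures[name])
        for name in obj_names if name in structures
    }
    scen_rows = {
        name: _rows_in(scen_infl[0].voxel_index, structures[name])
        for name in structures.ctv_names()
    } if scen_infl else {}

    weights = optimize_weights(nominal, scen_infl, objectives,
                               structure_rows, scen_rows, cfg.optimizer)

    # normalise: primary CTV V100 = 95%
    primary = max(structures.prescriptions,
                  key=lambda n: structures.prescriptions[n][0])
    rx = structures.prescriptions[primary][0]
    d_primary = nominal.matrix[structure_rows[primary]] @ weights
    s = normalization_factor(d_primary, rx)
    weights = weights * s

    flat_i = 0
    for spots in spots_per_beam:
        for sp in spots:
            sp.weight = float(weights[flat_i])
            flat_i += 1

    plan = Plan(
        beams=tuple(cfg.beams),
        spots_per_beam=tuple(tuple(s) for s in spots_per_beam),
        weights=weights,
        scenario_set=scen_set,
        normalization=s,
        prescriptions=dict(structures.prescriptions),
        rbe=cfg.rbe,
    )
    if return_influences:
        return plan, nominal, scen_infl
    return plan


def evaluate_plan_robustness(
    plan: Plan,
    structures: StructureSet,
    nominal: InfluenceMatrix,
    scenario_influences: Sequence[InfluenceMatrix],
) -> Dict[str, Dict]:
    """Worst-case V95 report for every CTV from precomputed influences."""
    doses: Dict[str, List[np.ndarray]] = {}
    for name in structures.ctv_names():
        rows_n = _rows_in(nominal.voxel_index, structures[name])
        per = [nominal.matrix[rows_n] @ plan.weights]
        for infl in scenario_influences:
            rows_s = _rows_in(infl.voxel_index, structures[name])
            per.append(infl.matrix[rows_s] @ plan.weights)
        doses[name] = per
    return robust_evaluate(doses, plan.prescriptions)


def adapt_plan(
    weekly_ct: VoxelImage,
    weekly_structures: StructureSet,
    cfg: Optional[PlanConfig] = None,
    return_influences: bool = False,
):
    """Weekly re-plan: a full, cold-start planning pass on the weekly sCT."""
    for name in weekly_structures.ctv_names():
        if not weekly_structures[name].any():
            raise ValueError(f"weekly CTV '{name}' is empty: cannot adapt")
    return create_plan(weekly_ct, weekly_structures, cfg,
                       return_influences=return_influences)
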