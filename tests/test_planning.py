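"""Scenario enumeration, objective rules, optimization, normalization."""

import numpy as np
import pytest
from scipy import sparse

import apteval as apt
from apteval.dose import InfluenceMatrix, NOMINAL, Scenario
from apteval.grids import Grid, StructureSet
from apteval.planning import (
    Objective,
    OptimizerConfig,
    adapt_plan,
    enumerate_scenarios,
    evaluate_plan_robustness,
    generate_objectives,
    normalization_factor,
    optimize_weights,
    robust_evaluate,
)


# ------------------------------------------------------------- scenarios


def test_twelve_scenarios_for_3mm_3pct():
    s = enumerate_scenarios(3.0, 0.03)
    assert len(s) == 12
    assert s.nominal == NOMINAL
    for sc in s.scenarios:
        shift = np.asarray(sc.shift_mm)
        assert np.count_nonzero(shift) == 1
        assert np.linalg.norm(shift) == pytest.approx(3.0)
        assert sc.range_scale in (0.97, 1.03)
    assert len(set(s.scenarios)) == 12


def test_degenerate_magnitudes_deduplicate():
    s = enumerate_scenarios(0.0, 0.0)
    assert len(s) == 1 and s.scenarios[0] == NOMINAL


# ------------------------------------------------------------- objectives


def _toy_structures(names):
    g = Grid((0, 0, 0), (1, 1, 1), (4, 4, 4))
    masks = {}
    rx = {}
    for i, n in enumerate(names):
        m = np.zeros(g.dims, bool)
        m[i, :, :] = True
        masks[n] = m
        if n.startswith("ctv"):
            rx[n] = (70.0, 35)
    return StructureSet(g, masks, rx)


def test_objective_rules_follow_constraint_table():
    ss = _toy_structures(["ctv_primary", "spinal_cord"])
    objs = generate_objectives(ss)
    assert len(objs) == 3
    by_kind = {o.kind: o for o in objs}
    assert by_kind["target-min"].dose_gy == 70.0 and by_kind["target-min"].robust
    assert by_kind["target-max"].dose_gy == pytest.approx(1.03 * 70.0)
    cord = by_kind["oar-max"]
    assert cord.structure == "spinal_cord" and not cord.robust
    assert cord.dose_gy == pytest.approx(0.9 * 48.0)  # 43.2 Gy


def test_targets_only_when_no_oars():
    ss = _toy_structures(["ctv_primary"])
    objs = generate_objectives(ss)
    assert len(objs) == 2 and all(o.robust for o in objs)


def test_parotid_gets_dvh_point_objective():
    ss = _toy_structures(["ctv_primary", "parotid_l"])
    objs = generate_objectives(ss)
    dvh = [o for o in objs if o.kind == "oar-dvh-point"]
    assert len(dvh) == 1
    assert dvh[0].dose_gy == 20.0
    assert dvh[0].volume_pct == pytest.approx(0.9 * 50.0)
    assert [o for o in objs if o.kind == "oar-mean"][0].dose_gy == pytest.approx(
        0.9 * 26.0)


def test_unknown_structure_skipped():
    ss = _toy_structures(["ctv_primary", "thyroid"])
    objs = generate_objectives(ss)
    assert all(o.structure != "thyroid" for o in objs)


# ------------------------------------------------------------- optimizer


def _influence_from_dense(a, grid=None, scenario=NOMINAL):
    a = np.atleast_2d(np.asarray(a, dtype=float))
    g = grid or Grid((0, 0, 0), (1, 1, 1), (a.shape[0], 1, 1))
    return InfluenceMatrix(sparse.csr_matrix(a), np.arange(a.shape[0]), g,
                           scenario)


def test_single_spot_closed_form():
    # one voxel, one spot, influence 1 Gy/MU, target-min at 60 Gy
    infl = _influence_from_dense([[1.0]])
    objs = [Objective("ctv", "target-min", 60.0, weight=1.0, robust=False)]
    w = optimize_weights(infl, [], objs, {"ctv": np.array([0])}, {},
                         OptimizerConfig(max_iterations=200))
    assert float((infl.matrix @ w)[0]) == pytest.approx(60.0, abs=0.1)


def test_objective_decreases_from_initial():
    rng = np.random.default_rng(0)
    a = rng.uniform(0.1, 1.0, size=(30, 8))
    infl = _influence_from_dense(a)
    rows = np.arange(30)
    objs = [Objective("ctv", "target-min", 60.0, weight=1.0, robust=False),
            Objective("ctv", "target-max", 61.8, weight=1.0, robust=False)]

    def penalty(w):
        d = a @ w
        return (np.clip(60.0 - d, 0, None) ** 2).mean() / 60.0**2 + (
            np.clip(d - 61.8, 0, None) ** 2).mean() / 61.8**2

    w = optimize_weights(infl, [], objs, {"ctv": rows}, {})
    w0 = np.full(8, 60.0 / (a.sum() / 30))
    assert penalty(w) <= penalty(w0) + 1e-12


def test_two_spot_matches_brute_force_grid():
    # 2 voxels x 2 spots, target-min only: compare with an exhaustive search
    a = np.array([[1.0, 0.2], [0.3, 1.0]])
    infl = _influence_from_dense(a)
    objs = [Objective("ctv", "target-min", 10.0, weight=1.0, robust=False),
            Objective("ctv", "target-max", 10.3, weight=1.0, robust=False)]
    w = optimize_weights(infl, [], objs, {"ctv": np.array([0, 1])}, {},
                         OptimizerConfig(max_iterations=300))

    def penalty(wv):
        d = a @ wv
        return ((np.clip(10.0 - d, 0, None) ** 2).mean() / 100.0
                + (np.clip(d - 10.3, 0, None) ** 2).mean() / 10.3**2)

    grid = np.linspace(0.0, 15.0, 200)
    best = min(penalty(np.array([w1, w2])) for w1 in grid for w2 in grid)
    assert penalty(w) <= best + 1e-4


def test_robust_term_uses_worst_scenario():
    # scenario halves the dose: worst-case optimization must compensate
    nom = _influence_from_dense([[1.0]])
    bad = _influence_from_dense([[0.5]], scenario=Scenario((3, 0, 0), 0.97))
    objs = [Objective("ctv", "target-min", 60.0, weight=1.0, robust=True)]
    rows = {"ctv": np.array([0])}
    w = optimize_weights(nom, [bad], objs, rows, rows,
                         OptimizerConfig(max_iterations=300))
    assert float((bad.matrix @ w)[0]) == pytest.approx(60.0, abs=0.5)


# ------------------------------------------------------------- normalization


def test_normalization_sorting_oracle():
    doses = 1.0 + 0.01 * np.arange(100)  # 1.00, 1.01, ..., 1.99
    s = normalization_factor(doses, 1.50)
    assert s == pytest.approx(1.50 / 1.05, rel=1e-12)
    scaled = doses * s
    assert 100.0 * np.mean(scaled >= 1.50) == pytest.approx(95.0)


def test_normalization_fixed_point_and_idempotence():
    rng = np.random.default_rng(1)
    doses = rng.uniform(50.0, 80.0, size=1000)
    rx = 66.0
    s = normalization_factor(doses, rx)
    scaled = doses * s
    v100 = 100.0 * np.mean(scaled >= rx)
    assert v100 == pytest.approx(95.0, abs=0.1)
    assert normalization_factor(scaled, rx) == pytest.approx(1.0, rel=1e-12)


def test_normalize_plan_scales_weights_and_is_idempotent():
    from apteval.dose import Beam, Spot
    from apteval.planning import Plan, normalize_plan

    spots = ((Spot((0.0, 0.0), 50.0, 1.0),),)
    plan = Plan((Beam((1, 0, 0)),), spots, np.array([2.0]),
                enumerate_scenarios(3.0, 0.03), 1.0, {"ctv_primary": (70.0, 35)})
    d = np.linspace(60.0, 80.0, 100)
    s = normalize_plan(plan, d, 70.0)
    assert plan.weights[0] == pytest.approx(2.0 * s)
    assert plan.spots_per_beam[0][0].weight == pytest.approx(s)
    assert normalize_plan(plan, d * s, 70.0) == pytest.approx(1.0, rel=1e-12)


def test_normalization_zero_dose_fails():
    with pytest.raises(ValueError):
        normalization_factor(np.zeros(10), 60.0)


# ------------------------------------------------------------- robust eval


def test_robust_evaluate_trivial_cases():
    rx = {"ctv": (70.0, 35)}
    uniform = np.full(50, 70.0)
    rep = robust_evaluate({"ctv": [uniform, uniform]}, rx)
    assert rep["ctv"]["worst_case_v95"] == 100.0 and rep["ctv"]["pass"]
    off = np.zeros(50)
    rep2 = robust_evaluate({"ctv": [uniform, off]}, rx)
    assert rep2["ctv"]["worst_case_v95"] == 0.0 and not rep2["ctv"]["pass"]


# ------------------------------------------------------------- end to end


def test_plan_is_normalised_and_robust(small_plan):
    """The optimized small-phantom plan: V100 = 95% (quantised) on the
    nominal dose and worst-case V95 > 95% for every CTV."""
    plan = small_plan["plan"]
    ss = small_plan["structures"]
    nominal = small_plan["nominal"]
    from apteval.planning import _rows_in

    rx = ss.prescriptions["ctv_primary"][0]
    d = nominal.matrix[_rows_in(nominal.voxel_index, ss["ctv_primary"])] @ plan.weights
    n = d.size
    v100 = 100.0 * np.mean(d >= rx)
    assert v100 == pytest.approx(95.0, abs=max(0.5, 100.0 / n))
    rob = evaluate_plan_robustness(plan, ss, nominal, small_plan["scenarios"])
    for name, rep in rob.items():
        assert rep["pass"], (name, rep["worst_case_v95"])


def test_plan_json_roundtrip(tmp_path, small_plan):
    plan = small_plan["plan"]
    p = str(tmp_path / "plan.json")
    plan.to_json(p)
    back = apt.Plan.from_json(p)
    np.testing.assert_allclose(back.weights, plan.weights)
    assert back.scenario_set.scenarios == plan.scenario_set.scenarios
    assert back.prescriptions == plan.prescriptions


def test_adapt_on_identical_anatomy_reproduces_plan(small_plan):
    """Re-planning on the unchanged planning CT is a cold-start re-run and
    must agree with the initial plan (same deterministic pipeline)."""
    plan = small_plan["plan"]
    re = adapt_plan(small_plan["pct_ov"], small_plan["structures"])
    ss = small_plan["structures"]
    nominal = small_plan["nominal"]
    from apteval.planning import _rows_in

    rows = _rows_in(nominal.voxel_index, ss["ctv_primary"])
    d_init = nominal.matrix[rows] @ plan.weights
    d_re = nominal.matrix[rows] @ re.weights
    assert abs(d_re.mean() - d_init.mean()) / d_init.mean() < 0.01
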