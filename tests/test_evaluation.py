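"""DVH indices, gamma analysis, accumulation, gEUD/NTCP, statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import apteval as apt
from apteval.evaluation import (
    DVHCurve,
    GammaConfig,
    accumulate_dose,
    check_constraints,
    dose_indices,
    gamma_3d,
    geud,
    lkb_ntcp,
    load_ntcp_params,
    ntcp_from_dose,
    paired_ttest,
    weekly_fraction_schedule,
)
from apteval.grids import Grid, VectorField, VoxelImage
from apteval.planning import DEFAULT_CONSTRAINTS


def _dose(grid, values):
    return VoxelImage(grid, values, kind="Gy")


@pytest.fixture()
def grid():
    return Grid((0, 0, 0), (2, 2, 2), (20, 20, 10))


# ------------------------------------------------------------- indices


def test_uniform_dose_indices(grid):
    rx = 66.0
    d = _dose(grid, np.full(grid.dims, rx))
    mask = np.ones(grid.dims, bool)
    idx = dose_indices(d, mask, rx)
    assert idx["V100"] == 100.0 and idx["V95"] == 100.0
    assert idx["Dmean"] == pytest.approx(rx) and idx["Dmax"] == pytest.approx(rx)


def test_vxgy_counting(grid):
    vals = np.zeros(grid.dims)
    vals[:10] = 40.0  # half the volume at 2 x 20 Gy
    idx = dose_indices(_dose(grid, vals), np.ones(grid.dims, bool),
                       v_levels_gy=(20.0,))
    assert idx["V20Gy"] == pytest.approx(50.0)


def test_linear_dvh_after_normalization(grid):
    from apteval.planning import normalization_factor

    doses = 1.0 + 0.01 * np.arange(100)
    s = normalization_factor(doses, 1.5)
    vals = np.zeros(grid.dims)
    mask = np.zeros(grid.dims, bool)
    mask.ravel()[:100] = True
    vals.ravel()[:100] = doses * s
    idx = dose_indices(_dose(grid, vals), mask, 1.5)
    assert idx["V100"] == pytest.approx(95.0)


def test_empty_mask_fails(grid):
    with pytest.raises(ValueError):
        dose_indices(_dose(grid, np.ones(grid.dims)), np.zeros(grid.dims, bool))


def test_dvh_curve_monotone(grid):
    rng = np.random.default_rng(0)
    d = rng.uniform(0, 70, size=grid.dims)[np.ones(grid.dims, bool)]
    c = DVHCurve.from_dose(d, "s")
    assert c.cum_volume_fraction[0] == 1.0
    assert np.all(np.diff(c.cum_volume_fraction) <= 1e-12)


# ------------------------------------------------------------- gamma


def test_gamma_identity(grid):
    rng = np.random.default_rng(0)
    ref = _dose(grid, rng.uniform(10, 60, grid.dims))
    rate, gmap = gamma_3d(ref, ref, GammaConfig(norm_dose_gy=60.0))
    assert rate == 100.0
    assert np.nanmax(gmap) == 0.0


def test_gamma_uniform_offset_boundary(grid):
    """eval = ref + dd*Dnorm exactly, no gradient: gamma = 1 passes."""
    ref = _dose(grid, np.full(grid.dims, 50.0))
    cfg = GammaConfig(dose_pct=3.0, dta_mm=3.0, norm_dose_gy=50.0)
    ev = _dose(grid, np.full(grid.dims, 50.0 + 0.03 * 50.0))
    rate, gmap = gamma_3d(ref, ev, cfg)
    assert rate == 100.0
    assert np.nanmin(gmap) == pytest.approx(1.0, abs=1e-9)


def test_gamma_brute_force_oracle():
    """1D profile pair: gamma from the implementation vs a dense
    brute-force search at 0.1*DTA resolution."""
    n = 20
    g = Grid((0, 0, 0), (2, 2, 2), (n, 1, 1))
    x = np.arange(n) * 2.0
    ref_vals = 50.0 * np.exp(-((x - 18.0) ** 2) / 200.0)
    ev_vals = 49.0 * np.exp(-((x - 20.5) ** 2) / 230.0)
    ref = _dose(g, ref_vals.reshape(n, 1, 1))
    ev = _dose(g, ev_vals.reshape(n, 1, 1))
    cfg = GammaConfig(dose_pct=3.0, dta_mm=3.0, norm_dose_gy=50.0,
                      threshold_fraction=0.10, search_radius_dta=2.0,
                      step_fraction_dta=0.1)
    rate, gmap = gamma_3d(ref, ev, cfg)

    # brute force: dense 1D interpolation of the evaluated profile at the
    # same stated search step (0.1 x DTA)
    dd = 0.03 * 50.0
    fine = np.arange(-6.0, 6.0 + 1e-9, 0.1 * 3.0)
    analysed = ref_vals >= 5.0
    for i in np.flatnonzero(analysed):
        cand = np.interp(x[i] + fine, x, ev_vals)
        gam = np.sqrt((fine / 3.0) ** 2 + ((cand - ref_vals[i]) / dd) ** 2).min()
        assert gmap[i, 0, 0] == pytest.approx(gam, abs=1e-3)


def test_gamma_criteria_ordering(grid):
    rng = np.random.default_rng(2)
    base = 60.0 * np.exp(-(((np.arange(20) - 10) / 8.0) ** 2))
    ref = _dose(grid, np.broadcast_to(base[:, None, None], grid.dims).copy())
    ev = _dose(grid, np.clip(ref.values * (1 + rng.normal(0, 0.02, grid.dims)),
                             0, None))
    loose, _ = gamma_3d(ref, ev, GammaConfig(3.0, 3.0, norm_dose_gy=60.0))
    tight, _ = gamma_3d(ref, ev, GammaConfig(2.0, 2.0, norm_dose_gy=60.0))
    assert loose >= tight


def test_gamma_translation_invariance(grid):
    rng = np.random.default_rng(3)
    vals_r = rng.uniform(20, 60, grid.dims)
    vals_e = vals_r * (1 + rng.normal(0, 0.02, grid.dims))
    cfg = GammaConfig(norm_dose_gy=60.0)
    r1, _ = gamma_3d(_dose(grid, vals_r), _dose(grid, np.clip(vals_e, 0, None)), cfg)
    # same pair translated by one voxel (toroidal roll keeps content identical)
    r2, _ = gamma_3d(_dose(grid, np.roll(vals_r, 3, axis=0)),
                     _dose(grid, np.clip(np.roll(vals_e, 3, axis=0), 0, None)), cfg)
    assert r1 == pytest.approx(r2, abs=0.5)


def test_gamma_zero_norm_fails(grid):
    z = _dose(grid, np.zeros(grid.dims))
    with pytest.raises(ValueError):
        gamma_3d(z, z, GammaConfig(norm_dose_gy=0.0))


# ------------------------------------------------------------- constraints


def test_constraint_auditing_strict_inequality():
    idx = {
        "spinal_cord": {"Dmax": 47.0},
        "parotid_l": {"V20Gy": 50.0, "Dmean": 20.0},
    }
    recs = check_constraints(idx, DEFAULT_CONSTRAINTS)
    by = {(r["structure"], r["metric"]): r for r in recs}
    assert by[("spinal_cord", "Dmax")]["pass"]
    assert not by[("parotid_l", "V20Gy")]["pass"]  # 50 is not < 50
    assert by[("parotid_l", "Dmean")]["pass"]
    assert check_constraints({}, DEFAULT_CONSTRAINTS) == []


# ------------------------------------------------------------- accumulation


def test_accumulation_identity_fixed_point(grid):
    d = _dose(grid, np.random.default_rng(0).uniform(0, 70, grid.dims))
    zeros = [VectorField.zeros(grid)] * 3
    acc = accumulate_dose([d, d, d], zeros, [10, 10, 10])
    np.testing.assert_allclose(acc.values, d.values, rtol=1e-6)


def test_weekly_fraction_schedule():
    assert weekly_fraction_schedule(30, 6) == [5, 5, 5, 5, 5, 5]
    assert weekly_fraction_schedule(35, 7) == [5] * 7
    assert sum(weekly_fraction_schedule(35, 3)) == 35


def test_accumulation_convex_bound(grid):
    rng = np.random.default_rng(4)
    doses = [_dose(grid, rng.uniform(0, 70, grid.dims)) for _ in range(3)]
    zeros = [VectorField.zeros(grid)] * 3
    mask = np.zeros(grid.dims, bool)
    mask[5:15, 5:15, 2:8] = True
    acc = accumulate_dose(doses, zeros, [5, 10, 15])
    means = [float(d.values[mask].mean()) for d in doses]
    assert min(means) <= float(acc.values[mask].mean()) <= max(means)


# ------------------------------------------------------------- radiobiology


@pytest.mark.parametrize("n", [0.1, 0.45, 1.0, 3.0])
def test_geud_uniform_is_dose(n):
    assert geud(np.full(50, 42.0), n) == pytest.approx(42.0, rel=1e-9)


def test_geud_hand_computations():
    d = np.array([20.0, 40.0])
    assert geud(d, 1.0) == pytest.approx(30.0)
    expected = (0.5 * 20.0**4 + 0.5 * 40.0**4) ** 0.25
    assert geud(d, 0.25) == pytest.approx(expected)
    assert expected == pytest.approx(34.1495, abs=0.001)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.2, 3.0))
def test_geud_between_min_and_max(seed, n):
    d = np.random.default_rng(seed).uniform(1.0, 70.0, size=40)
    g = geud(d, n)
    assert d.min() - 1e-9 <= g <= d.max() + 1e-9


def test_lkb_hand_values():
    p = apt.NTCPParams("e", "s", n=1.0, m=0.2, td50_gy=50.0)
    assert lkb_ntcp(50.0, p) == pytest.approx(0.5)
    assert lkb_ntcp(0.0, p) == pytest.approx(stats.norm.cdf(-5.0), rel=1e-9)
    assert lkb_ntcp(0.0, p) == pytest.approx(2.87e-7, rel=0.01)


def test_lkb_monotone_in_geud_and_td50():
    p = apt.NTCPParams("e", "s", n=1.0, m=0.25, td50_gy=46.3)
    xs = np.linspace(0, 80, 50)
    vals = [lkb_ntcp(x, p) for x in xs]
    assert all(a < b for a, b in zip(vals, vals[1:]))
    p2 = apt.NTCPParams("e", "s", n=1.0, m=0.25, td50_gy=60.0)
    assert lkb_ntcp(40.0, p2) < lkb_ntcp(40.0, p)


def test_ntcp_param_table_loads():
    params = load_ntcp_params()
    assert {"larynx_edema", "dysphagia", "xerostomia", "esophagitis"} <= set(params)
    for p in params.values():
        assert p.n > 0 and p.m > 0 and p.td50_gy > 0 and p.source


# ------------------------------------------------------------- statistics


def test_paired_ttest_hand_computation():
    x = np.array([11.0, 12.0, 13.0])
    y = np.array([10.0, 10.0, 10.0])
    res = paired_ttest(x, y)
    assert res.mean_difference == pytest.approx(2.0)
    assert res.t_statistic == pytest.approx(2 * math.sqrt(3), rel=1e-9)
    assert res.p_value == pytest.approx(0.0742, abs=0.0005)


def test_paired_ttest_degenerate_flagged():
    x = np.array([1.0, 2.0, 3.0])
    res = paired_ttest(x, x)
    assert res.p_value == 1.0 and res.zero_variance


def test_paired_ttest_antisymmetry():
    rng = np.random.default_rng(5)
    x = rng.normal(10, 2, 12)
    y = rng.normal(11, 2, 12)
    a = paired_ttest(x, y)
    b = paired_ttest(y, x)
    assert a.mean_difference == pytest.approx(-b.mean_difference)
    assert a.p_value == pytest.approx(b.p_value)
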