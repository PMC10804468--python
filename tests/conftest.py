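"""Shared fixtures: compact phantoms and cached expensive pipeline runs.

Heavy artefacts (optimized plans, study reports) are session-scoped so the
whole suite builds each of them exactly once.
"""

import numpy as np
import pytest

import apteval as apt
from apteval.sct import apply_artifact_override


def make_grid(spacing_mm: float = 2.0, dims=(48, 48, 32)) -> apt.Grid:
    origin = tuple(-(d - 1) * spacing_mm / 2 for d in dims)
    return apt.Grid(origin, (spacing_mm,) * 3, dims)


@pytest.fixture(scope="session")
def small_grid() -> apt.Grid:
    return make_grid(2.0)


@pytest.fixture(scope="session")
def small_spec(small_grid) -> apt.PhantomSpec:
    # half-size anatomy on a 48x48x32 grid: every organ class present
    return apt.PhantomSpec().scaled(0.5, grid=small_grid)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return apt.build_planning_phantom(small_spec)


@pytest.fixture(scope="session")
def small_plan(small_spec, small_phantom):
    """Optimized + normalised plan with its influence matrices (2 mm grid)."""
    pct, ss = small_phantom
    pct_ov = apply_artifact_override(pct, ss["artifact"], 40.0)
    plan, nominal, scenarios = apt.create_plan(
        pct_ov, ss, apt.PlanConfig(), return_influences=True
    )
    return {"plan": plan, "nominal": nominal, "scenarios": scenarios,
            "pct_ov": pct_ov, "structures": ss}


@pytest.fixture(scope="session")
def water_ct(small_grid):
    return apt.VoxelImage(small_grid, np.zeros(small_grid.dims), kind="HU")


def reduced_cohort(master_seed: int = 7, weeks: int = 3):
    """The 3-phantom anatomy-change cohort at a 4 mm grid."""
    grid = make_grid(4.0)
    cohort = apt.default_cohort(
        master_seed, grid=grid,
        which=("weight_loss", "tumor_growth", "tumor_shrink"),
    )
    return apt.StudyConfig(phantoms=cohort, weeks=weeks, master_seed=master_seed)


@pytest.fixture(scope="session")
def adaptation_report():
    """Adaptation study on the reduced anatomy-change cohort (4 mm, 3 weeks)."""
    return apt.run_adaptation_study(reduced_cohort())


@pytest.fixture(scope="session")
def static_reports():
    """Null-control: static-anatomy phantom through both studies (4 mm)."""
    grid = make_grid(4.0)
    cohort = apt.default_cohort(11, grid=grid, which=("static",))
    cfg = apt.StudyConfig(phantoms=cohort, weeks=2, master_seed=11)
    return {
        "validation": apt.run_validation_study(cfg),
        "adaptation": apt.run_adaptation_study(cfg),
    }


@pytest.fixture(scope="session")
def validation_report():
    """Validation study on {weight loss, tumor growth} phantoms (4 mm)."""
    grid = make_grid(4.0)
    cohort = apt.default_cohort(5, grid=grid, which=("weight_loss",
                                                     "tumor_growth"))
    cfg = apt.StudyConfig(phantoms=cohort, weeks=2, master_seed=5)
    return apt.run_validation_study(cfg)
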