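import numpy as np
import pytest

from shieldplan import (
    ApplicatorSpec,
    CohortSpec,
    CombinationSet,
    ScenarioSet,
    SourceModel,
    assemble_problem,
    build_scenario_matrices,
    default_penalties,
    generate_phantom,
    rasterize_phantom,
    solve,
)


@pytest.fixture(scope="session")
def applicator():
    return ApplicatorSpec()


@pytest.fixture(scope="session")
def source_model():
    return SourceModel()


@pytest.fixture(scope="session")
def small_cohort():
    """Small deterministic cohort used across solver tests."""
    return CohortSpec(n_phantoms=5, master_seed=7)


@pytest.fixture(scope="session")
def symmetric_phantom_pair(small_cohort, applicator):
    """Mirror-symmetric phantom (CTV sector centred at azimuth 0) at
    planning and evaluation resolution, sharing the same geometry."""
    geometry = {"tumor_angular_width": 120.0, "tumor_length": 40.0,
                "tumor_z_centre": 0.0}
    plan = rasterize_phantom(geometry, small_cohort, applicator,
                             small_cohort.planning_voxel)
    eval_ = rasterize_phantom(geometry, small_cohort, applicator,
                              small_cohort.evaluation_voxel)
    return plan, eval_


@pytest.fixture(scope="session")
def planned_phantom(small_cohort, applicator, source_model):
    """One phantom with its combination set, nominal planning matrix and
    solved quadratic-penalty plan — shared by downstream tests."""
    phantom = generate_phantom(small_cohort, 0, applicator)
    combos = CombinationSet.build(applicator)
    mats = build_scenario_matrices(phantom, combos, ScenarioSet.nominal_only(),
                                   source_model)
    problem = assemble_problem(mats, default_penalties())
    solution = solve(problem)
    return {
        "phantom": phantom,
        "combos": combos,
        "matrices": mats,
        "problem": problem,
        "solution": solution,
    }
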