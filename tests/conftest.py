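import numpy as np
import pytest

import dfcstates as d


@pytest.fixture(scope="session")
def roi_set():
    return d.default_roi_set()


@pytest.fixture(scope="session")
def blueprints():
    return d.default_blueprints()


@pytest.fixture(scope="session")
def blueprint_solution(blueprints):
    """The planted patterns packaged as a state solution, for matching."""
    feats = np.array([b.feature_vector() for b in blueprints])
    return d.StateSolution(5, feats, np.arange(1, 6), 0.0, 0, 1, 1)


@pytest.fixture(scope="session")
def small_design():
    """A reduced cohort (fewer subjects, shorter scans) for fast pipeline tests."""
    return d.CohortDesign(
        n_subjects=5,
        condition_geometry={"pre_rest": (150, 2.0), "task": (300, 1.5)},
        missing_cells=[],
        occupancy_profiles={
            "pre_rest": (0.172, 0.140, 0.381, 0.138, 0.169),
            "task": (0.172, 0.188, 0.251, 0.221, 0.168),
        },
        seed=99,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    scans, truths = d.simulate_cohort(small_design)
    return scans, truths


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size default cohort (15 subjects, 3 conditions, 1 missing scan)."""
    return d.simulate_cohort(d.CohortDesign(seed=11))


@pytest.fixture(scope="session")
def fitted_default(default_cohort):
    scans, _ = default_cohort
    model = d.DynamicStatesModel(scans, d.RunConfig(k=5, verbosity=0))
    return model.fit()
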