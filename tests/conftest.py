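import numpy as np
import pandas as pd
import pytest

import spatlogit as sl


@pytest.fixture(scope="session")
def lattice_8x8():
    return sl.generate_lattice_graph(8, 8)


@pytest.fixture(scope="session")
def lattice_4x4():
    return sl.generate_lattice_graph(4, 4)


@pytest.fixture(scope="session")
def path3():
    return sl.AdjacencyGraph([1, 2, 3], [(1, 2), (2, 3)])


def zero_smooth(t):
    return 0.0 * np.asarray(t, dtype=float)


@pytest.fixture()
def flat_truth():
    """All-zero effects: every record has p = 0.5."""
    return sl.TrueParameters(
        intercept=0.0, beta={},
        smooth_age_survey=zero_smooth, smooth_age_cohab=zero_smooth,
        sigma_b=0.0, sigma_h=0.0,
    )


@pytest.fixture(scope="session")
def binary_mix():
    return {"residence": {"rural": 0.6, "urban": 0.4}}


@pytest.fixture(scope="session")
def small_survey(lattice_4x4):
    """A small default-structure survey used across tests."""
    truth = sl.TrueParameters(
        intercept=-1.4,
        beta={"residence": {"urban": 0.5}, "occupation": {"working": -0.4}},
        smooth_age_survey=zero_smooth, smooth_age_cohab=zero_smooth,
        sigma_b=0.4, sigma_h=0.0,
    )
    mix = {
        "residence": {"rural": 0.6, "urban": 0.4},
        "occupation": {"not_working": 0.7, "working": 0.3},
    }
    return sl.simulate_survey(
        graph=lattice_4x4, truth=truth, n_per_district=120,
        covariate_mix=mix, seed=42,
    )


@pytest.fixture(scope="session")
def small_spec():
    return sl.ModelSpec(
        fixed_effects=[
            sl.FixedEffect("residence", "rural"),
            sl.FixedEffect("occupation", "not_working"),
        ],
        smooth_terms=[],
        random_structure="CAR",
    )


@pytest.fixture(scope="session")
def small_fit(small_survey, small_spec):
    model = sl.SpatialLogit.from_dataframe(
        small_survey.data, small_spec, small_survey.graph
    )
    return model.fit(draws=200, warmup=120, chains=1, seed=7)
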