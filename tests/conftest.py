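"""Shared fixtures: the default synthetic cohort and its feature matrices.

The cohort (10 users x 50 walks, master seed 11) matches the evaluation
protocol's default study conditions; it is simulated once per session and
shared by the evaluation and acceptance tests.
"""

import logging

import numpy as np
import pytest

import floorgait as fg

COHORT_SEED = 11
N_USERS = 10
SAMPLES_PER_USER = 50

logging.getLogger("floorgait").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def geom():
    return fg.FloorGeometry()


@pytest.fixture(scope="session")
def cohort(geom):
    return fg.simulate_dataset(geom, N_USERS, SAMPLES_PER_USER, master_seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_footsteps(geom, cohort):
    return [fg.segment_footsteps(s, geom) for s in cohort.samples]


@pytest.fixture(scope="session")
def cohort_features(geom, cohort, cohort_footsteps):
    """Raw walking (case 4) and stepping (case 4, dt 0.04) matrices + labels."""
    Xw, Xs = [], []
    for sample, steps in zip(cohort.samples, cohort_footsteps):
        wvec, svec = fg.extract_sample_features(
            steps, geom, walking_case=4, stepping_case=4, dt=0.04,
            sample_id=sample.sample_id,
        )
        Xw.append(wvec)
        Xs.append(svec)
    return np.array(Xw), np.array(Xs), np.array(cohort.labels)


@pytest.fixture(scope="session")
def tiny_separable_cohort(geom):
    """3 well-separated users x 10 walks for fast classifier checks."""
    population = fg.PopulationConfig(
        step_length=fg.Trait(62.0, 8.0, 1.0, lo=50.0, hi=76.0),
        stance_time=fg.Trait(0.55, 0.08, 0.01, lo=0.40, hi=0.70),
        foot_length=fg.Trait(25.0, 2.5, 0.0, lo=21.0, hi=29.5),
        foot_width=fg.Trait(9.5, 1.2, 0.0, lo=7.5, hi=12.0),
        rollover_fraction=fg.Trait(0.60, 0.12, 0.0, lo=0.35, hi=0.85),
    )
    ds = fg.simulate_dataset(
        geom, 3, 10, master_seed=5, population=population,
        noise=fg.NoiseConfig.none(),
    )
    Xw, Xs = [], []
    for s in ds.samples:
        steps = fg.segment_footsteps(s, geom)
        wvec, svec = fg.extract_sample_features(steps, geom, sample_id=s.sample_id)
        Xw.append(wvec)
        Xs.append(svec)
    return np.array(Xw), np.array(Xs), np.array(ds.labels)
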