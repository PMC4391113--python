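"""Shared fixtures: one simulated study (normative model + 16-patient
cohort + full comparison battery) at a fixed seed, reused session-wide."""

import numpy as np
import pytest

import perimsim as ps
from perimsim import pipeline

STUDY_SEED = 1


@pytest.fixture(scope="session")
def model():
    return ps.generate_normative_database(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def cohort(model):
    return ps.simulate_cohort(n=16, prevalence=6 / 16, seed=STUDY_SEED, model=model)


@pytest.fixture(scope="session")
def comparison(cohort, model):
    return pipeline.compare_cohort(list(cohort.fields), model)


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)


def make_field(sens, algorithm="full_threshold", visit=3, eye="right", **kw):
    """Helper: build a field from a scalar or full-length array."""
    s = np.full(len(ps.GRID_30_2), float(sens)) if np.isscalar(sens) else np.asarray(sens)
    return ps.VisualField(
        patient_id=kw.pop("patient_id", "T1"),
        algorithm=algorithm,
        visit=visit,
        eye=eye,
        sensitivities=s,
        **kw,
    )
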