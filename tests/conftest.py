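import numpy as np
import pytest

from adapk import DoseEvent, Observation, Subject, Cohort, final_parameters
from adapk.simulate import DesignSpec, generate_cohort


@pytest.fixture(scope="session")
def final_pop():
    return final_parameters()


@pytest.fixture(scope="session")
def study_cohort(final_pop):
    """A 54-subject cohort at the study design (sparse troughs)."""
    cohort, truth = generate_cohort(DesignSpec(seed=20230), final_pop)
    return cohort, truth


def make_subject(sid="S1", obs_times=(336.0, 672.0), conc=(5.0, 6.0),
                 albumin=3.77, aaa=0, doses=None):
    doses = doses or (
        DoseEvent(0.0, 160.0),
        DoseEvent(336.0, 80.0),
        DoseEvent(672.0, 40.0),
        DoseEvent(1008.0, 40.0),
    )
    observations = tuple(
        Observation(time=t, concentration=c) for t, c in zip(obs_times, conc)
    )
    return Subject(
        id=sid,
        doses=tuple(doses),
        observations=observations,
        albumin=albumin,
        aaa=aaa,
        albumin_samples=tuple(albumin for _ in observations),
        aaa_samples=tuple(float(aaa) for _ in observations),
    )


@pytest.fixture
def two_subject_cohort():
    return Cohort(
        subjects=(
            make_subject("A", (336.0, 672.0), (4.0, 6.0)),
            make_subject("B", (400.0, 700.0, 1000.0), (2.0, 3.0, 3.5), albumin=3.0, aaa=1),
        ),
        meta={},
    )
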