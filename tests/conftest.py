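import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ironavail as ia

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_individual(id="x1", sex="male", iron_intake=10.0, **kw):
    status = kw.pop("menopausal_status", "not_applicable" if sex == "male" else "premenopausal")
    return ia.Individual(
        id=id, study=kw.pop("study", "test"), sex=sex,
        menopausal_status=status, iron_intake=iron_intake, **kw
    )


def make_cohort(individuals, label="test"):
    return ia.Cohort(label=label, individuals=list(individuals))


@pytest.fixture
def small_cohort():
    return make_cohort(
        [
            make_individual("m1", "male", 13.0, sf=120.0, crp=1.0),
            make_individual("m2", "male", 15.0, sf=90.0, crp=2.0),
            make_individual("f1", "female", 10.0, menopausal_status="premenopausal",
                            sf=30.0, crp=0.5),
            make_individual("f2", "female", 11.0, menopausal_status="postmenopausal",
                            sf=80.0, crp=1.5),
        ]
    )


@pytest.fixture
def premeno_requirements():
    return ia.generate_requirement_distribution(ia.default_requirement_spec("premenopausal"))


def three_point_dist(values, group="men"):
    """Requirement distribution with three grid points at arbitrary percentiles."""
    return ia.RequirementDistribution(
        group=group, percentiles=np.array([25.0, 50.0, 75.0]),
        requirements=np.asarray(values, dtype=float),
    )
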