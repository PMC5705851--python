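import pytest

from bcellmon import (
    DOMAINS,
    BilagDomain,
    CohortParams,
    DomainGrade,
    VisitAssessment,
    simulate_cohort,
)


def make_grades(**overrides):
    """All-D grade map with per-domain overrides by lowercase domain name."""
    grades = {d: DomainGrade.D for d in DOMAINS}
    for name, letter in overrides.items():
        domain = BilagDomain[name.upper()]
        grades[domain] = DomainGrade(letter)
    return grades


def make_visit(week=0, patient_id="P1", **overrides):
    return VisitAssessment(
        patient_id=patient_id, week=week, grades=make_grades(**overrides)
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A quick default-parameter cohort for structural tests."""
    return simulate_cohort(CohortParams(n_patients=60, seed=11))


@pytest.fixture(scope="session")
def cohort_10k():
    """The full-size cohort used for marginal-recovery checks."""
    return simulate_cohort(CohortParams(n_patients=10_000, seed=7))
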