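import pytest

from tipsnet import (
    ShuntPosition,
    enumerate_cases,
    patient_fixtures,
    run_case,
    run_study,
)


@pytest.fixture(scope="session")
def patients():
    return patient_fixtures()


@pytest.fixture(scope="session")
def headline_case(patients):
    """Patient #1, shunt at MPV, Type A — the worked headline configuration."""
    p1, _ = patients
    case = next(
        c
        for c in enumerate_cases([p1])
        if c.shunt.position is ShuntPosition.MPV and c.simplification.label == "A"
    )
    network, solution, result = run_case(case)
    return case, network, solution, result


@pytest.fixture(scope="session")
def full_study(patients):
    """The complete 18-case study table."""
    return run_study(list(patients))
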