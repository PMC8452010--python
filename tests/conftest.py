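import pytest

import saltiodine as si


@pytest.fixture(scope="session")
def inputs() -> si.AssessmentInputs:
    return si.sri_lanka_fixture()


@pytest.fixture(scope="session")
def results(inputs) -> list:
    return si.assemble_assessment(inputs)


@pytest.fixture(scope="session")
def national(results) -> dict:
    """National IntakeResult keyed by scenario label."""
    return {r.scenario: r for r in results if r.region == "Sri Lanka"}
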