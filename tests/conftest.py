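import pytest

from thresholdpgg import TREATMENTS, make_treatment

TREATMENT_NAMES = sorted(TREATMENTS)


@pytest.fixture(params=TREATMENT_NAMES)
def treatment(request):
    """One canonical treatment config per parametrized run."""
    return make_treatment(request.param)


@pytest.fixture
def full_equality():
    return make_treatment("full_equality")
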