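import pytest

from aglearn import behavior, stimuli


@pytest.fixture(scope="session")
def fam_inventory():
    return stimuli.build_inventory("familiarization")


@pytest.fixture(scope="session")
def test_inventory():
    return stimuli.build_inventory("test")


@pytest.fixture(scope="session", params=stimuli.ORDERS)
def grammar(request):
    return stimuli.GrammarSpec(request.param)


@pytest.fixture(scope="session")
def small_trials():
    """A modest simulated trial table under the published coefficients."""
    return behavior.simulate_trials(seed=20160921)
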