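import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def toy2_nested_report():
    """The 23-qubit Nested Grover demonstration run, simulated once per session."""
    from qkmer.search import run, toy2_nested_instance

    return run(toy2_nested_instance(shots=1024, seed=11))


@pytest.fixture(scope="session")
def toy2_enumerate_report():
    from qkmer.search import run, toy2_enumerate_instance

    return run(toy2_enumerate_instance(shots=1024, seed=11))
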