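import pytest

from pausedelta.pipeline import run_study


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (2,000 units, 2 replicates/condition) shared
    by all tests that inspect pipeline recovery."""
    return run_study(seed=1)
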