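import pytest

from fobtscore import reconstruct_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    """The deterministic 112-record pseudo-cohort (solved once per session)."""
    return reconstruct_reference_cohort()
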