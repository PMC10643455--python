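import pytest

from phycokit import synth


@pytest.fixture(scope="session")
def antenna():
    """The published-abundance chromatogram scenario (peaks, windows, regions)."""
    return synth.antenna_scenario()


@pytest.fixture(scope="session")
def reference_set():
    """Synthetic stand-in for the 22-sequence mature alpha set, with truth."""
    return synth.reference_alpha_set()
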