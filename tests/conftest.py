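import pytest

from fucsim.synth import build_extended_mini_core, build_fuculose_motif, build_mini_core


@pytest.fixture
def mini_core():
    return build_mini_core()


@pytest.fixture
def extended():
    return build_extended_mini_core()


@pytest.fixture
def motif():
    return build_fuculose_motif()
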