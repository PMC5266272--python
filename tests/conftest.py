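import pytest

from stoichbuffer.kinetics import HeterodimerModel, default_model


@pytest.fixture(scope="session")
def model() -> HeterodimerModel:
    """The shipped default heterodimer calibration."""
    return default_model()
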