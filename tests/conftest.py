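import pytest


@pytest.fixture(scope="session")
def cation_model_best():
    """The best-fit chemiosmotic model: 10 cations per 3 ATP, 2 per Rnf."""
    from pelokit.energetics import CationModel

    return CationModel(10, 2)
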