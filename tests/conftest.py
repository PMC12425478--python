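import pytest

from nitroscape.synthetic_data import SynthConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition synthetic dataset shared by read-only tests."""
    return generate_dataset(SynthConfig(), seed=1)
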