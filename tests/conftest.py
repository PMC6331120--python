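import pytest

from calascan import GroundTruthModel, cal_a_reference


@pytest.fixture(scope="session")
def gene():
    return cal_a_reference()


@pytest.fixture(scope="session")
def noiseless_truth():
    return GroundTruthModel(noise_prob=0.0)
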