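import pytest

from logiprofile.fixtures import mini_cancer_model, toy_model


@pytest.fixture
def toy():
    """Three-node toy network (input A, B = A, C = !A) with default settings."""
    return toy_model()


@pytest.fixture
def mini():
    """Ten-node cancer-signaling network with phenotype read-outs."""
    return mini_cancer_model()
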