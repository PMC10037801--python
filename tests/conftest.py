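import numpy as np
import pytest

from mdapred import (
    ModelConfig,
    SyntheticSpec,
    generate_dataset,
    gip_kernel,
    worked_micro_example,
)


@pytest.fixture(scope="session")
def micro():
    """Fixed 4-miRNA x 3-disease instance with hand-checkable values."""
    return worked_micro_example()


@pytest.fixture(scope="session")
def micro_views(micro):
    gip_m = gip_kernel(micro.assoc.values, micro.assoc.mirna_names, "mirna")
    gip_d = gip_kernel(micro.assoc.values.T, micro.assoc.disease_names, "disease")
    return [micro.mirna_functional, gip_m], [micro.disease_semantic, gip_d]


@pytest.fixture(scope="session")
def small_dataset():
    """30x30 planted-block dataset, large enough for CV but fast to train on."""
    return generate_dataset(SyntheticSpec(nm=30, nd=30, rank=3, density=0.15,
                                          noise=0.01, seed=11))


@pytest.fixture
def tiny_config():
    """Reduced widths for fast end-to-end fits in unit tests."""
    return ModelConfig(c_out=8, f_tran=8, n_heads=2, epochs=30,
                       learning_rate=5e-3, n_steps=2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
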