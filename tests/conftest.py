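import pytest

from dsbscape import FactorKernel, make_sites, toy_genome


@pytest.fixture(scope="session")
def genome():
    return toy_genome()


@pytest.fixture(scope="session")
def sites100(genome):
    return make_sites(genome, n_sites=100, min_gap=50_000, seed=11)


@pytest.fixture(scope="session")
def exp_kernel():
    return FactorKernel(shape="exponential", decay_length_bp=2_000, amplitude=1.0)
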