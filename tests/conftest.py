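import numpy as np
import pytest

import amitrace as at


@pytest.fixture(scope="session")
def haploid_model():
    return at.build_model("haploid", ploidy_k=860)


@pytest.fixture(scope="session")
def chromosomal_model():
    return at.build_model("chromosomal", ploidy_k=860)


@pytest.fixture(scope="session")
def haploid_dist_200(haploid_model):
    """Exact distribution from IRS0 = 0.5 after 200 divisions, haploid model."""
    return at.propagate(haploid_model, 0.5, 200)


@pytest.fixture(scope="session")
def chromosomal_dist_200(chromosomal_model):
    return at.propagate(chromosomal_model, 0.5, 200)


@pytest.fixture(scope="session")
def toy_genome():
    """40 scaffolds x 300 kb in 1-kb windows (12k windows), default GC model."""
    return at.generate_genome(40, 300_000, seed=101)
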