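import numpy as np
import pytest

from caddregions.regions import GeneModel
from caddregions.simulate import (
    SyntheticSpec,
    generate_clinvar_like,
    generate_gene_model,
    truth_positions_by_region,
)


@pytest.fixture(scope="session")
def gene_fixture():
    """Toy gene model with its ground-truth region map."""
    transcripts, truth = generate_gene_model(8, seed=11)
    return transcripts, truth, GeneModel(transcripts)


@pytest.fixture(scope="session")
def truth_pools(gene_fixture):
    _, truth, _ = gene_fixture
    return truth_positions_by_region(truth)


@pytest.fixture(scope="session")
def clinvar_small():
    """Archive-like variant table small enough for fast per-test reuse."""
    return generate_clinvar_like(SyntheticSpec(n_variants=8000, seed=3))


@pytest.fixture(scope="session")
def clinvar_large():
    """Archive-like set at the default scale (rare regions well populated)."""
    spec = SyntheticSpec(n_variants=100_000, seed=7)
    return spec, generate_clinvar_like(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
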