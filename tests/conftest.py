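import numpy as np
import pytest

import perturbome as pb


@pytest.fixture(scope="session")
def small_dataset():
    """A small mixed synthetic study: effects + periodic baseline + noise."""
    design = pb.SyntheticDesign(
        n_genes=500,
        genome_length=500_000,
        replicates=3,
        noise_sd=0.1,
        seed=42,
    )
    expr, truth = pb.generate_expression(design)
    return design, expr, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
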