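import numpy as np
import pytest
from hypothesis import settings

import phenoswitch as ps

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_params() -> ps.MutationParams:
    """Baseline mutation parameters: U=4e-5, tau=100, n=5000, s=0.1."""
    return ps.MutationParams(U=4e-5, tau=100, n=5000, s=0.1)


@pytest.fixture(scope="session")
def pre_motif() -> ps.MotifLandscape:
    return ps.MotifLandscape(A=2, s=0.1, K=30, phase="pre")


@pytest.fixture(scope="session")
def post_valley(pre_motif) -> ps.MotifLandscape:
    return pre_motif.to_post((0.9, 1.1))


@pytest.fixture(scope="session")
def baseline_kernel(baseline_params, pre_motif) -> ps.MutationKernel:
    return ps.build_mutation_kernel(baseline_params, pre_motif)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_distribution(rng: np.random.Generator, n_genotypes: int
                        ) -> ps.PhenoGenotypeDistribution:
    f = rng.random((2, n_genotypes))
    return ps.PhenoGenotypeDistribution(f / f.sum())
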