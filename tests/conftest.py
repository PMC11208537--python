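import numpy as np
import pytest

from paddynet.synthetic import GeneratorParams, generate_dataset, paper_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    """The packaged 15-site soil/metal tables plus backgrounds."""
    return paper_fixture()


@pytest.fixture(scope="session")
def small_bundle():
    """A small synthetic bundle for fast I/O and diversity tests."""
    return generate_dataset(GeneratorParams(
        n_samples=30, n_taxa=300, n_modules=4, module_size_range=(15, 25),
        depth_range=(8000, 10000), seed=7))


@pytest.fixture(scope="session")
def default_bundle():
    """Full-scale bundle at the default generator conditions."""
    return generate_dataset(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def strong_bundle():
    """Full-scale bundle at strong module loading (recoverable truth)."""
    return generate_dataset(GeneratorParams(
        seed=7, module_loading=1.5, noise_sd=0.3))


def planted_block_correlation(seed=3, n_blocks=5, block_size=20):
    """Block-diagonal correlation matrix: within-block |r| in
    [0.85, 0.95], between-block |r| in [0, 0.4]."""
    rng = np.random.default_rng(seed)
    n = n_blocks * block_size
    r = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = i // block_size == j // block_size
            v = rng.uniform(0.85, 0.95) if same else rng.uniform(0.0, 0.4)
            r[i, j] = r[j, i] = v
    np.fill_diagonal(r, 1.0)
    labels = [f"O{i}" for i in range(n)]
    truth = [i // block_size for i in range(n)]
    return labels, r, truth
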