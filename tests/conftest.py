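import numpy as np
import pytest

from subridge import GenotypeMatrix, SimConfig, maf_filter, simulate_f2_population


def make_genotypes(n, p, seed):
    rng = np.random.default_rng(seed)
    values = rng.integers(0, 3, size=(n, p))
    return GenotypeMatrix(
        values,
        tuple(f"m{j + 1}" for j in range(p)),
        tuple(f"ind{i + 1}" for i in range(n)),
    )


def make_dataset(n, p, seed, h2=0.5):
    """Random unlinked genotypes with a dense additive trait."""
    rng = np.random.default_rng(seed)
    gm = make_genotypes(n, p, seed)
    b = rng.normal(0.0, 0.3, size=p)
    g = gm.as_float() @ b
    noise_sd = np.sqrt(np.var(g) * (1 - h2) / h2)
    y = 1.0 + g + rng.normal(0.0, noise_sd, size=n)
    return y, gm, b


@pytest.fixture(scope="session")
def small_dataset():
    return make_dataset(n=60, p=12, seed=101)


@pytest.fixture(scope="session")
def f2_population():
    """Default simulated F2 panel (n=400, p=500, 50 QTL, h2 target 0.5)."""
    return simulate_f2_population(SimConfig(seed=20240901))


@pytest.fixture(scope="session")
def f2_filtered(f2_population):
    gm = maf_filter(f2_population.marker_genotypes)
    return f2_population.phenotypes, gm
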