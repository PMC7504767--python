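import numpy as np
import pytest

from alsim import CompoundSet, SyntheticSpec, generate_dataset


def random_fingerprints(rng: np.random.Generator, n: int,
                        n_bits: int = 512, density: float = 0.08) -> list[set[int]]:
    """Random non-empty bit-index sets for property tests."""
    fps = []
    for _ in range(n):
        k = max(1, rng.binomial(n_bits, density))
        fps.append(set(rng.choice(n_bits, size=k, replace=False).tolist()))
    return fps


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


@pytest.fixture
def small_compound_set() -> CompoundSet:
    """A 40-compound, 4-series synthetic dataset (fast full-pipeline input)."""
    spec = SyntheticSpec(n_compounds=40, n_series=4, ruggedness=0.5,
                        potency_range=(4.0, 10.0), noise_sd=0.1, seed=7)
    cs, _ = generate_dataset(spec)
    return cs


@pytest.fixture
def random_distribution_pairs(rng):
    """100 pairs of strictly positive 8-bin probability vectors."""
    pairs = []
    for _ in range(100):
        p = rng.dirichlet(np.ones(8) * 2.0)
        q = rng.dirichlet(np.ones(8) * 2.0)
        # Dirichlet draws are strictly positive almost surely; renormalize
        # defensively so sums hit 1 within the checker's 1e-9
        pairs.append((p / p.sum(), q / q.sum()))
    return pairs
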