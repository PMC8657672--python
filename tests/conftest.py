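import numpy as np
import pytest

from rlfscan import M1, M2, GenomicSequence, generate_background


def random_corpus(n_seqs: int, seed: int, min_len: int = 100,
                  max_len: int = 2000):
    """Random sequences with mixed lengths and G fractions in [0.1, 0.5]."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_seqs):
        g = rng.uniform(0.1, 0.5)
        n = int(rng.integers(min_len, max_len + 1))
        out.append(generate_background(n, g, rng))
    return out


@pytest.fixture(scope="session")
def small_corpus():
    """200 random sequences for module-level invariant checks."""
    return random_corpus(200, seed=20240917)


@pytest.fixture(scope="session")
def both_models():
    return (M1, M2)


@pytest.fixture()
def planted_m1():
    """One clean m1 motif in a 3 kb low-G background."""
    from rlfscan import plant_rlfs

    bg = generate_background(3000, 0.10, seed=11)
    return plant_rlfs(bg, 800, "m1", seed=12)


def as_sequence(residues: str, name: str = "s") -> GenomicSequence:
    return GenomicSequence(name, residues)
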