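import numpy as np
import pytest

from phenonet.community import CommunityPreset, MonthlyInteractionTable, generate_community
from phenonet.seasonal import compute_seasonal_structure, flattened_structure


def make_table(I, Fp, Fh):
    I = np.asarray(I, dtype=float)
    t = MonthlyInteractionTable(
        plant_labels=[f"p{i}" for i in range(I.shape[0])],
        bird_labels=[f"b{j}" for j in range(I.shape[1])],
        I=I,
        Fp=np.asarray(Fp, dtype=float),
        Fh=np.asarray(Fh, dtype=float),
    )
    t.validate()
    return t


def constant_table(n_p, n_h, value=2.0):
    """Fully connected community in which every species is active in every
    month with the same count."""
    return make_table(
        np.ones((n_p, n_h)), np.full((n_p, 12), value), np.full((n_h, 12), value)
    )


@pytest.fixture
def pair_table():
    """Smallest community: one plant, one bird, constant phenologies."""
    return constant_table(1, 1)


@pytest.fixture
def pair_flat(pair_table):
    return flattened_structure(1, 1)


@pytest.fixture(scope="session")
def small_community():
    """A seeded 8x4 synthetic community with its seasonal structure."""
    table = generate_community(CommunityPreset("small", 8, 4, 16), seed=42)
    return table, compute_seasonal_structure(table)


def random_table(rng, n_p=None, n_h=None):
    """Random valid community for property tests."""
    n_p = n_p or int(rng.integers(1, 6))
    n_h = n_h or int(rng.integers(1, 5))
    preset = CommunityPreset(
        "rand",
        n_p,
        n_h,
        int(rng.integers(max(n_p, n_h), n_p * n_h + 1)),
    )
    return generate_community(preset, seed=int(rng.integers(2**31)))
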