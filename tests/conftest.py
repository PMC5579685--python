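import numpy as np
import pandas as pd
import pytest

from famdiet.config import SimulationConfig
from famdiet.pedigree import Family, Person
from famdiet.simulate import default_composition


@pytest.fixture(scope="session")
def composition():
    return default_composition()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_family(fid: str, roles_sexes_ages) -> Family:
    """Build a Family from (role, sex, age) tuples."""
    members = [
        Person(f"{fid}.{i}", fid, fid, role, sex, age, "SE")
        for i, (role, sex, age) in enumerate(roles_sexes_ages)
    ]
    return Family(fid, members)


@pytest.fixture
def trio():
    return make_family("T", [("mother", "F", 40), ("father", "M", 42), ("child", "F", 8)])


def random_family(fid: str, rng: np.random.Generator) -> Family:
    """A random valid nuclear family: 0-2 parents, enough children for >=2
    members."""
    n_parents = rng.integers(0, 3)
    roles = [("mother", "F"), ("father", "M")][: n_parents] if n_parents else []
    if n_parents == 1 and rng.random() < 0.5:
        roles = [("father", "M")]
    min_children = max(2 - n_parents, 1 if n_parents < 2 else 0)
    n_children = int(rng.integers(min_children, min_children + 4))
    member_spec = [(r, s, int(rng.integers(25, 66))) for r, s in roles]
    member_spec += [
        ("child", "F" if rng.random() < 0.5 else "M", int(rng.integers(2, 20)))
        for _ in range(n_children)
    ]
    return make_family(fid, member_spec)


@pytest.fixture(scope="session")
def big_sim():
    """One sizeable shared simulation: families + latent traits under the
    default variance components (0.40, 0.21, 0.39)."""
    from famdiet.simulate import sample_family_structures, simulate_latent_traits

    cfg = SimulationConfig(n_families=10_000, seed=424242)
    fams = sample_family_structures(cfg)
    traits = simulate_latent_traits(fams, cfg)
    return cfg, fams, traits
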