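import numpy as np
import pytest
from hypothesis import settings

from synchar import synthdata

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


def dp_levenshtein(a: str, b: str) -> int:
    """Independent quadratic dynamic-programming edit distance oracle."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1]


@pytest.fixture(scope="session")
def small_parts():
    """A dozen random flanked parts, fixed seed."""
    return synthdata.simulate_parts(synthdata.PartSimSpec(n_parts=12, seed=3))


@pytest.fixture(scope="session")
def family_parts():
    """Three families of five near-duplicate parts plus ground-truth labels."""
    return synthdata.simulate_part_families(
        n_families=3, parts_per_family=5, core_length=120, n_mutations=4, seed=11
    )


@pytest.fixture(scope="session")
def unimodal_cloud():
    ev, labels = synthdata.simulate_flow(
        synthdata.FlowSimSpec(n_events=20_000, seed=7)
    )
    return ev, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
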