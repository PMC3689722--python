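import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadnet import BehavioralStream, CodeBook, CombinedState, GROUP_A, GROUP_B

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def codebook() -> CodeBook:
    return CodeBook.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def make_stream(infant, mother, dyad_id="d1", group=GROUP_A) -> BehavioralStream:
    return BehavioralStream(
        dyad_id=dyad_id,
        group=group,
        infant_codes=tuple(infant),
        mother_codes=tuple(mother),
    )


def random_stream(rng, codebook, max_seconds=500, dyad_id="d1", group=GROUP_A):
    """An arbitrary valid stream, with 'other' codes mixed in."""
    n = int(rng.integers(1, max_seconds + 1))
    infant = rng.choice(sorted(codebook.infant_codes), size=n)
    mother = rng.choice(sorted(codebook.mother_codes), size=n)
    return make_stream(infant, mother, dyad_id=dyad_id, group=group)


def naive_transition_count(stream, codebook) -> int:
    """Independent oracle: count consecutive differing combined-state pairs
    where neither second holds an 'other' code."""
    states = list(zip(stream.infant_codes, stream.mother_codes))
    other = codebook.other_codes
    count = 0
    for (i1, m1), (i2, m2) in zip(states, states[1:]):
        if i1 in other or m1 in other or i2 in other or m2 in other:
            continue
        if (i1, m1) != (i2, m2):
            count += 1
    return count
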