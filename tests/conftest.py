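import random
import warnings

import pytest

from armfold.consensus import OrthologSet, call_consensus
from armfold.pipeline import annotate_trnas
from armfold.simulate import CladeConfig, generate_clade


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_clade():
    """A cached 3-species clade at 2% divergence."""
    return generate_clade(CladeConfig(seed=11, n_species=3, divergence=0.02))


@pytest.fixture(scope="session")
def small_clade_hits(small_clade):
    return {
        sp: annotate_trnas(ag, small_clade.order)
        for sp, ag in small_clade.species.items()
    }


@pytest.fixture(scope="session")
def small_clade_calls(small_clade, small_clade_hits):
    calls = {}
    for identity in small_clade.trnas:
        cands = {
            sp: hits[identity]
            for sp, hits in small_clade_hits.items()
            if hits[identity] is not None
        }
        if len(cands) >= 2:
            calls[identity] = call_consensus(OrthologSet(identity, cands))
    return calls


@pytest.fixture()
def rng():
    return random.Random(42)


def random_dna(rng, n, at=0.6):
    return "".join(
        rng.choice("AT") if rng.random() < at else rng.choice("GC") for _ in range(n)
    )
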