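import math

import numpy as np
import pytest

from exprkit import NucSeq, train_ensemble
from exprkit.accessibility import DEFAULT_ENERGY_MODEL, enumerate_structures
from exprkit.fixtures import sp_training_set


def random_nucseq(rng: np.random.Generator, n: int, name: str = "r") -> NucSeq:
    return NucSeq("".join(rng.choice(list("ACGT"), size=n)), name)


def oracle_opening_energy(seq: NucSeq, lo: int, hi: int,
                          model=DEFAULT_ENERGY_MODEL) -> float:
    """Opening energy by exhaustive structure enumeration (independent path)."""
    structs = enumerate_structures(seq, model)
    RT = model.RT
    z_full = sum(math.exp(-e / RT) for _, e in structs)
    z_con = sum(
        math.exp(-e / RT) for pairs, e in structs
        if all(i < lo or i >= hi for pair in pairs for i in pair)
    )
    return RT * (math.log(z_full) - math.log(z_con))


@pytest.fixture(scope="session")
def small_ensemble():
    """Primary ensemble trained on 300 synthetic labelled sequences."""
    return train_ensemble(sp_training_set(300, seed=17), seed=17)
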