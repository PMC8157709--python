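import numpy as np
import pytest

from suckerscreen.seqcore import Subgenome, Transcript


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_transcriptome(rng):
    """Ten random background transcripts of 200-400 nt."""
    from tests.oracles import random_dna

    return [
        Transcript(f"bg{i}", random_dna(rng, int(rng.integers(200, 401))))
        for i in range(10)
    ]


def make_pair(rng, length=500, n_subs=25, family_id="famX"):
    """An S/T homoeolog pair differing by exactly n_subs substitutions."""
    from tests.oracles import mutate, random_dna

    s = random_dna(rng, length)
    t = mutate(s, n_subs, rng)
    from suckerscreen.trigger_design import HomoeologPair

    return HomoeologPair(
        Transcript(f"{family_id}_S", s, Subgenome.S),
        Transcript(f"{family_id}_T", t, Subgenome.T),
        family_id,
    )
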