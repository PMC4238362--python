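import numpy as np
import pytest
from hypothesis import settings

import irptgs as G
from irptgs import simulate as S

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frag_pair():
    """Deterministic 342/372-nt trigger fragments (reporter + pigment gene)."""
    rng = np.random.default_rng(42)
    gus = G.TriggerFragment("gus", "reporter", S.random_dna(rng, 342))
    chs = G.TriggerFragment("chs", "pigment", S.random_dna(rng, 372))
    return gus, chs


@pytest.fixture(scope="session")
def construct(frag_pair):
    """gusS-chsS^chsA-gusA with a 120-nt intron."""
    gus, chs = frag_pair
    rng = np.random.default_rng(7)
    spec = G.HairpinSpec((("gus", "sense"), ("chs", "sense")), intron_length=120)
    return G.build_hairpin(spec, [gus, chs], S.random_dna(rng, 120))


@pytest.fixture(scope="session")
def codon_table():
    from irptgs.codons import CodonUsageTable

    return CodonUsageTable.builtin()


@pytest.fixture(scope="session")
def toy_genome():
    return S.gen_toy_genome(seed=11)
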