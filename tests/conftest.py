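import numpy as np
import pytest

import erosionscan as es
from erosionscan._codons import get_code


@pytest.fixture(scope="session")
def study():
    """The six-taxon study tree with its parasite/free-living partition."""
    return es.default_study_phylogeny()


@pytest.fixture(scope="session")
def code():
    return get_code(1)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_codon_alignment(n_codons: int, species, seed: int = 0):
    """Uniform random stop-free codon alignment (not tree-evolved)."""
    code = get_code(1)
    rng = np.random.default_rng(seed)
    return es.CodonAlignment(
        {
            sp: "".join(
                code.codons[i] for i in rng.integers(0, code.n, n_codons)
            )
            for sp in species
        }
    )
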