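import numpy as np
import pytest

from siterates import CodonAlignment, make_balanced_tree
from siterates.genetic_code import SENSE_CODONS


@pytest.fixture
def rng():
    return np.random.default_rng(20170530)


@pytest.fixture
def cherry():
    return make_balanced_tree(2, 0.3)


@pytest.fixture
def quartet():
    return make_balanced_tree(4, 0.2)


def random_codon_alignment(rng, n_taxa=4, n_sites=6, labels=None):
    states = rng.integers(0, len(SENSE_CODONS), size=(n_taxa, n_sites))
    labels = labels or [f"t{i + 1}" for i in range(n_taxa)]
    return CodonAlignment(labels=labels, states=states)
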