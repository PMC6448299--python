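import numpy as np
import pytest

from sparsemix import LcaDesign, TWO_CLASS_DESIGN, generate_lca_data, load_childrens_fear


@pytest.fixture(scope="session")
def fear_data():
    """The 93-record infant-temperament table: (codes, cardinalities)."""
    return load_childrens_fear()


@pytest.fixture(scope="session")
def lca_small():
    """A small two-class latent-class dataset with known labels."""
    design = LcaDesign(TWO_CLASS_DESIGN.weights, TWO_CLASS_DESIGN.probs, N=100)
    codes, labels = generate_lca_data(design, np.random.default_rng(123))
    return codes, labels, design


def set_partitions(items):
    """All set partitions of a sequence (test oracle for partition sums)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


@pytest.fixture(scope="session")
def all_set_partitions():
    return set_partitions
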