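import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from carotevol import LabeledTree, load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def quartet_tree():
    return LabeledTree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")


@pytest.fixture()
def rng():
    return np.random.default_rng(20100622)


def random_codon_sequence(rng, n_codons, allow_gaps=False):
    """A random in-frame sequence over sense codons (optionally with gaps/N)."""
    from carotevol.codons import sense_codons

    codons = sense_codons()
    parts = []
    for _ in range(n_codons):
        if allow_gaps and rng.random() < 0.05:
            parts.append(rng.choice(["---", "NNN"]))
        else:
            parts.append(codons[rng.integers(len(codons))])
    return "".join(parts)


def mutate_sequence(rng, seq, n_mutations):
    seq = list(seq)
    for _ in range(n_mutations):
        pos = int(rng.integers(len(seq)))
        seq[pos] = "ACGT"[rng.integers(4)]
    return "".join(seq)
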