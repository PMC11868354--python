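import numpy as np
import pytest

from tcrepspec.io import Clonotype


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_clonotype(cdr3="CASSLGQGAEAFF", v="TRBV19", j="TRBJ2-7", count=1,
                   donor="HD1", epitope=None):
    return Clonotype(cdr3_aa=cdr3, v_gene=v, j_gene=j, read_count=count,
                     donor_id=donor, epitope=epitope)


@pytest.fixture
def clonotype_factory():
    return make_clonotype


def random_cdr3(rng, length=None, alphabet="ASGLTQE", lengths=(12, 13, 14)):
    """Low-entropy random CDR3s so that Hamming-1 edges actually occur."""
    L = int(rng.choice(lengths)) if length is None else length
    inner = "".join(rng.choice(list(alphabet), size=L - 2))
    return "C" + inner + "F"


def brute_force_hamming1_edges(seqs):
    """Quadratic all-pairs oracle for the Hamming-1 graph."""
    seqs = sorted(set(seqs))
    edges = set()
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            if len(a) == len(b) and sum(x != y for x, y in zip(a, b)) == 1:
                edges.add(frozenset((a, b)))
    return edges
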