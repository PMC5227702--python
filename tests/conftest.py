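import numpy as np
import pytest

from littorina.popgen import HaplotypeDataset


def make_dataset(seq_pop_pairs, groups=None):
    """Build a HaplotypeDataset from (sequence, population) pairs."""
    seqs = [s for s, _ in seq_pop_pairs]
    pops = [p for _, p in seq_pop_pairs]
    ids = [f"{p}_i{j}" for j, p in enumerate(pops)]
    grp = None if groups is None else [groups[p] for p in pops]
    return HaplotypeDataset(sequences=seqs, sample_ids=ids, populations=pops, groups=grp)


@pytest.fixture
def two_pop_fixture():
    """2 populations x 3 sequences with within- and between-pop variation."""
    return make_dataset(
        [
            ("AAAAAAAAAA", "X"),
            ("AAAAAAAAAC", "X"),
            ("AAAAAAAAAA", "X"),
            ("GGAAAAAAAA", "Y"),
            ("GGAAAAAAAC", "Y"),
            ("GGTAAAAAAA", "Y"),
        ]
    )


@pytest.fixture
def hierarchical_fixture():
    """4 populations in 2 groups, 12 sequences, unbalanced sizes."""
    groups = {"p1": "north", "p2": "north", "p3": "south", "p4": "south"}
    return make_dataset(
        [
            ("AAAAAAAAAAAA", "p1"),
            ("AAAAAAAAAAAC", "p1"),
            ("AAAAAAAAAAAA", "p1"),
            ("AAAAAAAAAAAA", "p1"),
            ("AAGAAAAAAAAA", "p2"),
            ("AAGAAAAAAAAC", "p2"),
            ("AAGAAAAAAAAA", "p2"),
            ("TTTTAAAAAAAA", "p3"),
            ("TTTTAAAAAAAC", "p3"),
            ("TTTTGAAAAAAA", "p4"),
            ("TTTTGAAAAAAC", "p4"),
            ("TTTTGAAAAAAA", "p4"),
        ],
        groups=groups,
    )
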