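import numpy as np
import pytest

from navdup.parsimony_map import TrioAlignment
from navdup.sequence_io import CodonAlignment, read_newick


@pytest.fixture
def simple_trio() -> TrioAlignment:
    """Hand-built trio exercising every parsimony column class.

    Columns: 1 identity, 2 paralog1 substitution, 3 all-different,
    4 paralog2 substitution, 5 outgroup gap run (2 cols), 7 identity.
    """
    return TrioAlignment.from_records(
        outgroup=("dr_scn4ab", "MIAKR--A"),
        paralog1=("aa_scn4ab1", "MLVKRDEA"),
        paralog2=("aa_scn4ab2", "MIVKKDEA"),
    )


@pytest.fixture
def star_tree():
    """Unrooted 3-taxon tree with the paralog1 branch foreground."""
    return read_newick("(out:0.5,p1#1:0.15,p2:0.15);")


@pytest.fixture
def tiny_codon_alignment() -> CodonAlignment:
    return CodonAlignment([
        ("out", "ATGAAACTT"),
        ("p1", "ATGAAGCTC"),
        ("p2", "ATAAAACTT"),
    ])
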