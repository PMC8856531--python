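import random
from fractions import Fraction

import pytest

from mrptree.curation import InputTree
from mrptree.synthgen import generate_model_tree
from mrptree.treecore import Tree, parse_newick


def random_tree(n_leaves: int, seed: int) -> Tree:
    """Random rooted binary tree for property tests."""
    return generate_model_tree(n_leaves, seed)


def make_input(newick: str, tree_id: str, study: str = "s1", year: int = 2010,
               tags=("COI",), weight=Fraction(1)) -> InputTree:
    return InputTree(
        tree=parse_newick(newick),
        tree_id=tree_id,
        study_id=study,
        year=year,
        data_types=frozenset(tags),
        weight=weight,
    )


@pytest.fixture
def rng():
    return random.Random(20240101)
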