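"""Unordered parsimony: worked examples, oracle equivalence, invariants."""

import random

import pytest

from karyoevo import (
    CharacterMatrix,
    brute_force_length,
    brute_force_mpr,
    parse_newick,
    reconstruct,
    synapomorphies,
)
from karyoevo.errors import (
    CharacterNotFoundError,
    DegenerateInputError,
    InstanceTooLargeError,
)
from karyoevo.trees import Node, Phylogeny

from conftest import random_small_instance, random_tree


def one_char_matrix(cells: dict, alphabet):
    wrapped = {
        t: (None if v is None else frozenset(v if isinstance(v, (set, frozenset, list, tuple)) else {v}))
        for t, v in cells.items()
    }
    return CharacterMatrix(
        taxa=tuple(cells),
        characters=("c",),
        alphabets={"c": tuple(alphabet)},
        cells={"c": wrapped},
    )


def test_fitch_textbook_example():
    """((A,B),(C,D)) with 0,0,1,1: one change, ambiguous root {0,1}.

    Expected values confirmed by enumerating all 9 assignments of the three
    internal nodes: the minimum is 1 and both root states attain it.
    """
    tree = parse_newick("((A,B)ab,(C,D)cd)root;")
    matrix = one_char_matrix({"A": "0", "B": "0", "C": "1", "D": "1"}, ("0", "1"))
    result = reconstruct(tree, matrix, "c")
    assert result.length == 1
    assert result.mpr["root"] == frozenset({"0", "1"})
    assert result.mpr["ab"] == frozenset({"0"})
    assert result.mpr["cd"] == frozenset({"1"})
    assert brute_force_length(tree, matrix, "c") == 1
    assert brute_force_mpr(tree, matrix, "c")["root"] == frozenset({"0", "1"})


def test_uniform_character_zero_length():
    rng = random.Random(0)
    tree = random_tree(rng, 9)
    matrix = one_char_matrix(
        {leaf: "2" for leaf in tree.leaf_labels()}, ("0", "1", "2")
    )
    result = reconstruct(tree, matrix, "c")
    assert result.length == 0
    assert all(states == frozenset({"2"}) for states in result.mpr.values())
    assert result.transformations == []
    report = synapomorphies(result, tree)
    assert report.synapomorphies == []


def test_star_tree_distinct_states_closed_form():
    """A star tree with k distinct tip states needs exactly k - 1 changes."""
    for k in (2, 3, 4, 5):
        leaves = [Node(label=f"t{i}") for i in range(k)]
        tree = Phylogeny(root=Node(label="root", children=leaves))
        alphabet = tuple(str(i) for i in range(k))
        matrix = one_char_matrix({f"t{i}": str(i) for i in range(k)}, alphabet)
        assert reconstruct(tree, matrix, "c").length == k - 1
        assert brute_force_length(tree, matrix, "c") == k - 1


def test_missing_and_polymorphic_tips_cost_free():
    tree = parse_newick("((A,B),(C,D));")
    base = one_char_matrix({"A": "0", "B": "0", "C": "1", "D": "1"}, ("0", "1"))
    poly = one_char_matrix(
        {"A": "0", "B": {"0", "1"}, "C": "1", "D": "1"}, ("0", "1")
    )
    missing = one_char_matrix({"A": "0", "B": None, "C": "1", "D": "1"}, ("0", "1"))
    assert reconstruct(tree, poly, "c").length == 1
    assert reconstruct(tree, missing, "c").length == 1
    assert reconstruct(tree, base, "c").length == 1


def test_errors_for_bad_requests():
    tree = parse_newick("(A,B);")
    matrix = one_char_matrix({"A": "0", "B": "1"}, ("0", "1"))
    with pytest.raises(CharacterNotFoundError):
        reconstruct(tree, matrix, "nope")
    all_missing = one_char_matrix({"A": None, "B": None}, ("0", "1"))
    with pytest.raises(DegenerateInputError):
        reconstruct(tree, all_missing, "c")


def test_oracle_size_guard():
    rng = random.Random(1)
    tree = random_tree(rng, 40)
    matrix = one_char_matrix(
        {leaf: "0" for leaf in tree.leaf_labels()}, tuple(str(i) for i in range(8))
    )
    with pytest.raises(InstanceTooLargeError):
        brute_force_length(tree, matrix, "c")


def test_reconstruct_matches_oracle_on_random_instances():
    """Length AND per-node MPR sets agree with exhaustive enumeration."""
    rng = random.Random(2024)
    for _ in range(100):
        tree, matrix, char = random_small_instance(rng)
        result = reconstruct(tree, matrix, char)
        assert result.length == brute_force_length(tree, matrix, char)
        assert result.mpr == brute_force_mpr(tree, matrix, char)


def test_length_bounds_on_fully_observed_instances():
    """distinct_states - 1 <= length <= #tips carrying minority states."""
    rng = random.Random(77)
    checked = 0
    while checked < 50:
        tree, matrix, char = random_small_instance(rng)
        cells = [matrix.cells[char][t] for t in matrix.taxa]
        if any(c is None or len(c) != 1 for c in cells):
            continue  # the bounds are stated for singleton observations
        checked += 1
        states = [next(iter(c)) for c in cells]
        counts = {s: states.count(s) for s in set(states)}
        length = reconstruct(tree, matrix, char).length
        assert length >= len(counts) - 1
        assert length <= len(states) - max(counts.values())


def test_state_relabelling_permutes_mpr_but_keeps_length():
    rng = random.Random(5)
    for _ in range(30):
        tree, matrix, char = random_small_instance(rng)
        alphabet = list(matrix.alphabets[char])
        perm = alphabet[:]
        rng.shuffle(perm)
        mapping = dict(zip(alphabet, perm))
        relabelled = CharacterMatrix(
            taxa=matrix.taxa,
            characters=matrix.characters,
            alphabets={char: tuple(mapping[s] for s in alphabet)},
            cells={
                char: {
                    t: (None if c is None else frozenset(mapping[s] for s in c))
                    for t, c in matrix.cells[char].items()
                }
            },
        )
        base = reconstruct(tree, matrix, char)
        swapped = reconstruct(tree, relabelled, char)
        assert base.length == swapped.length
        for key, states in base.mpr.items():
            assert swapped.mpr[key] == frozenset(mapping[s] for s in states)


def test_missing_leaf_never_increases_length():
    rng = random.Random(6)
    for _ in range(30):
        tree, matrix, char = random_small_instance(rng)
        length = reconstruct(tree, matrix, char).length
        grown_root = Node(
            children=[tree.root, Node(label="extra missing leaf")]
        )
        grown_tree = Phylogeny(root=grown_root)
        cells = dict(matrix.cells[char])
        cells["extra missing leaf"] = None
        grown_matrix = CharacterMatrix(
            taxa=matrix.taxa + ("extra missing leaf",),
            characters=matrix.characters,
            alphabets=matrix.alphabets,
            cells={char: cells},
        )
        assert reconstruct(grown_tree, grown_matrix, char).length == length


def test_packaged_x_character_fixes_12_at_hylinae(dataset):
    result = reconstruct(dataset.tree, dataset.matrix, "x")
    assert result.mpr["Hylinae"] == frozenset({"12"})


def test_packaged_nor_synapomorphies_and_ambiguity(dataset):
    result = reconstruct(dataset.tree, dataset.matrix, "nor_pair")
    report = synapomorphies(result, dataset.tree)
    # the (caingua, prasina, pulchella) clade gains NOR state 12 on its stem
    assert report.states_on_stem_of("B. pulchella 12 clade") == frozenset({"12"})
    # the base of the A. albofrenatus group is ambiguous (arildae's position)
    assert "A. albofrenatus group" in report.ambiguous_nodes
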