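"""Shared fixtures: the packaged dataset and random-instance generators."""

from __future__ import annotations

import random
import string

import numpy as np
import pytest

from karyoevo import (
    BChromosome,
    CharacterMatrix,
    ChromosomePair,
    Karyotype,
    Morphology,
    NORAnnotation,
    centromeric_index,
    classify_morphology,
    load_dataset,
)
from karyoevo.trees import Node, Phylogeny


@pytest.fixture(scope="session")
def dataset():
    return load_dataset()


@pytest.fixture(scope="session")
def records_by_species(dataset):
    return {r.species: r for r in dataset.records}


def random_karyotype(rng: random.Random, species: str | None = None) -> Karyotype:
    """A random but internally consistent karyotype (all fields populated)."""
    n_pairs = rng.randint(1, 12)
    totals = sorted((rng.uniform(1.0, 12.0) for _ in range(n_pairs)), reverse=True)
    hap_total = sum(totals)
    pairs = []
    for i, total in enumerate(totals, start=1):
        ci = rng.uniform(0.0, 0.5)
        p = total * ci
        q = total - p
        nor = None
        if rng.random() < 0.2:
            nor = NORAnnotation(
                pair_index=i,
                arm=rng.choice(["p", "q", None]),
                position=rng.choice(["terminal", "interstitial", "centromeric"]),
            )
        bands = tuple(
            f"{rng.choice('pq')}:{rng.choice(['centromeric', 'interstitial', 'terminal'])}:C+"
            for _ in range(rng.randint(0, 2))
        )
        pairs.append(
            ChromosomePair(
                pair_index=i,
                p_len=p,
                q_len=q,
                ci=centromeric_index(p, q),
                morphology=classify_morphology(centromeric_index(p, q)),
                rel_length=100.0 * total / hap_total,
                nor=nor,
                bands=bands,
            )
        )
    bs = []
    if rng.random() < 0.3:
        ci = rng.uniform(0.0, 0.5)
        bs.append(
            BChromosome(
                rel_length=rng.uniform(1.0, 10.0),
                ci=ci,
                morphology=classify_morphology(ci),
                mitotic_stability=rng.choice([True, False, None]),
            )
        )
    return Karyotype(
        species=species or f"Taxon {rng.randint(0, 10**6)}",
        pairs=pairs,
        group=rng.choice(["group A", "group B", None]),
        ploidy=rng.choice([2, 2, 2, 3]),
        b_chromosomes=bs,
        sex_system=rng.choice([None, "XY", "ZW"]),
        source=rng.choice(["this_study", "literature"]),
    )


def random_matrix(rng: random.Random) -> CharacterMatrix:
    n_taxa = rng.randint(2, 8)
    n_chars = rng.randint(1, 3)
    taxa = tuple(f"taxon{i}{rng.choice(string.ascii_lowercase)}" for i in range(n_taxa))
    characters = tuple(f"char{i}" for i in range(n_chars))
    state_pool = ["0", "1", "2", "9", "10", "11", "4a", "4b", "X"]
    alphabets = {
        c: tuple(rng.sample(state_pool, rng.randint(2, 6))) for c in characters
    }
    cells = {}
    for c in characters:
        col = {}
        for t in taxa:
            if rng.random() < 0.15:
                col[t] = None
            else:
                k = rng.randint(1, min(3, len(alphabets[c])))
                col[t] = frozenset(rng.sample(list(alphabets[c]), k))
        cells[c] = col
    return CharacterMatrix(
        taxa=taxa, characters=characters, alphabets=alphabets, cells=cells
    )


def random_tree(
    rng: random.Random,
    n_leaves: int,
    label_internals: bool = False,
) -> Phylogeny:
    """A random rooted topology, multifurcations allowed."""
    nodes = [Node(label=f"t{i}") for i in range(n_leaves)]
    counter = 0
    while len(nodes) > 1:
        k = min(len(nodes), rng.choice([2, 2, 2, 3]))
        children = [nodes.pop(rng.randrange(len(nodes))) for _ in range(k)]
        label = f"n{counter}" if label_internals else None
        counter += 1
        nodes.append(Node(label=label, children=children))
    return Phylogeny(root=nodes[0])


def random_small_instance(rng: random.Random, max_internal: int = 6, max_states: int = 4):
    """A (tree, matrix, character) triple small enough for the brute-force oracle."""
    while True:
        n_leaves = rng.randint(2, 8)
        tree = random_tree(rng, n_leaves)
        if len(tree.internal_nodes()) <= max_internal:
            break
    n_states = rng.randint(2, max_states)
    alphabet = tuple(str(s) for s in range(n_states))
    cells = {}
    for leaf in tree.leaf_labels():
        r = rng.random()
        if r < 0.1:
            cells[leaf] = None  # missing
        elif r < 0.25:
            k = rng.randint(1, n_states)
            cells[leaf] = frozenset(rng.sample(list(alphabet), k))  # polymorphic
        else:
            cells[leaf] = frozenset({rng.choice(alphabet)})
    observed = [t for t, c in cells.items() if c is not None]
    if len(observed) < 2:  # reconstruct() needs at least two observed tips
        for leaf in tree.leaf_labels()[:2]:
            cells[leaf] = frozenset({rng.choice(alphabet)})
    matrix = CharacterMatrix(
        taxa=tuple(tree.leaf_labels()),
        characters=("c",),
        alphabets={"c": alphabet},
        cells={"c": cells},
    )
    return tree, matrix, "c"
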