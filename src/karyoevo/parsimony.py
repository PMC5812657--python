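"""Unordered-parsimony ancestral-state reconstruction (Fitch/Hartigan style).

Given a rooted, possibly multifurcating tree and an unordered multistate
character, the reconstruction minimizes the number of state changes over all
assignments of states to internal nodes.  The implementation is the
unit-cost dynamic program that generalizes Fitch's two-pass algorithm to
polytomies, missing data and polymorphic tips:

* down pass — for every node v and state s, ``down[v][s]`` is the minimum
  number of changes within the subtree of v given that v is assigned s
  (for a tip, 0 if s is among its observed states, otherwise infinity —
  a change on the terminal branch is charged to the branch, not the tip);
* up pass — ``above[v][s]`` is the minimum number of changes outside the
  subtree of v (including v's stem branch) given v = s.

The tree length is ``min_s down[root][s]`` and the MPR (most parsimonious
reconstruction) set of a node is ``{s : down[v][s] + above[v][s] == length}``
— exactly the states the node attains in at least one minimum-change
assignment.  Nodes with more than one MPR state are ambiguous; no
ACCTRAN/DELTRAN resolution is imposed.

Missing tips carry the full alphabet at zero cost and can never increase the
tree length; polymorphic tips contribute their observed state set the same
way (cost-free ambiguity).

A brute-force enumeration oracle (:func:`brute_force_length`,
:func:`brute_force_mpr`) is provided for verification on small instances.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

from .characters import CharacterMatrix
from .errors import (
    CharacterNotFoundError,
    DegenerateInputError,
    InstanceTooLargeError,
)
from .trees import Node, Phylogeny

__all__ = [
    "Transformation",
    "ReconstructionResult",
    "reconstruct",
    "synapomorphies",
    "SynapomorphyReport",
    "brute_force_length",
    "brute_force_mpr",
]

_INF = float("inf")


@dataclass(frozen=True)
class Transformation:
    """A branch along which the MPR set changes."""

    parent: str
    child: str
    from_states: frozenset
    to_states: frozenset


@dataclass
class ReconstructionResult:
    """Tree length, per-node MPR sets and branch transformations."""

    character: str
    length: int
    mpr: dict[str, frozenset]
    transformations: list[Transformation]
    ambiguous_nodes: list[str]
    alphabet: tuple[str, ...] = ()

    def states_at(self, node_key: str) -> frozenset:
        return self.mpr[node_key]

    def to_json(self) -> str:
        def order(states):
            return [s for s in self.alphabet if s in states] or sorted(states)

        return json.dumps(
            {
                "character": self.character,
                "length": self.length,
                "mpr": {k: order(v) for k, v in self.mpr.items()},
                "transformations": [
                    {
                        "parent": t.parent,
                        "child": t.child,
                        "from": order(t.from_states),
                        "to": order(t.to_states),
                    }
                    for t in self.transformations
                ],
                "ambiguous_nodes": self.ambiguous_nodes,
            },
            indent=2,
        )


def _leaf_sets(
    tree: Phylogeny, matrix: CharacterMatrix, character: str, min_observed: int = 2
) -> tuple[dict[int, frozenset], frozenset]:
    """Observed state set per leaf; missing leaves carry the full alphabet."""
    if character not in matrix.characters:
        raise CharacterNotFoundError(
            f"character {character!r} not in matrix {matrix.characters}"
        )
    alphabet = frozenset(matrix.alphabets[character])
    column = matrix.cells[character]
    sets: dict[int, frozenset] = {}
    n_observed = 0
    for leaf in tree.leaves():
        cell = column.get(leaf.label)
        if cell is None:
            sets[id(leaf)] = alphabet
        else:
            sets[id(leaf)] = cell
            n_observed += 1
    if n_observed == 0:
        raise DegenerateInputError(
            f"character {character!r} is missing for every leaf of the tree"
        )
    if n_observed < min_observed:
        raise DegenerateInputError(
            f"character {character!r} is observed for fewer than "
            f"{min_observed} leaves"
        )
    return sets, alphabet


def reconstruct(
    tree: Phylogeny, matrix: CharacterMatrix, character: str
) -> ReconstructionResult:
    """Ancestral-state reconstruction of one unordered character.

    Returns the minimum number of changes (tree length), the MPR state set
    of every node (keyed by node label, else ``node<postorder index>``),
    the branches whose MPR sets change, and the ambiguous nodes.
    """
    leaf_sets, alphabet_set = _leaf_sets(tree, matrix, character)
    alphabet = tuple(matrix.alphabets[character])
    keys = tree.node_keys()

    down: dict[int, dict[str, float]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            observed = leaf_sets[id(node)]
            down[id(node)] = {s: (0 if s in observed else _INF) for s in alphabet}
        else:
            costs = {}
            for s in alphabet:
                total = 0.0
                for child in node.children:
                    child_costs = down[id(child)]
                    best = min(child_costs.values())
                    total += min(child_costs[s], best + 1)
                costs[s] = total
            down[id(node)] = costs

    root = tree.root
    length = min(down[id(root)].values())

    above: dict[int, dict[str, float]] = {id(root): {s: 0.0 for s in alphabet}}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        node_above = above[id(node)]
        child_costs = [down[id(c)] for c in node.children]
        child_best = [min(c.values()) for c in child_costs]
        for i, child in enumerate(node.children):
            # cost contributed by the node's other children, per parent state
            sibling = {
                s: sum(
                    min(child_costs[j][s], child_best[j] + 1)
                    for j in range(len(node.children))
                    if j != i
                )
                for s in alphabet
            }
            above[id(child)] = {
                s: min(
                    node_above[p] + sibling[p] + (0 if p == s else 1)
                    for p in alphabet
                )
                for s in alphabet
            }

    mpr: dict[str, frozenset] = {}
    for node in tree.postorder():
        states = frozenset(
            s
            for s in alphabet
            if down[id(node)][s] + above[id(node)][s] == length
        )
        mpr[keys[id(node)]] = states

    transformations: list[Transformation] = []
    for node in tree.preorder():
        for child in node.children:
            from_states = mpr[keys[id(node)]]
            to_states = mpr[keys[id(child)]]
            if from_states != to_states:
                transformations.append(
                    Transformation(
                        parent=keys[id(node)],
                        child=keys[id(child)],
                        from_states=from_states,
                        to_states=to_states,
                    )
                )

    ambiguous = [
        keys[id(node)]
        for node in tree.postorder()
        if not node.is_leaf and len(mpr[keys[id(node)]]) > 1
    ]
    return ReconstructionResult(
        character=character,
        length=int(length),
        mpr=mpr,
        transformations=transformations,
        ambiguous_nodes=ambiguous,
        alphabet=alphabet,
    )


@dataclass
class SynapomorphyReport:
    """Candidate synapomorphies and ambiguous nodes for one character."""

    character: str
    synapomorphies: list[Transformation]
    ambiguous_nodes: list[str]

    def states_on_stem_of(self, clade_label: str) -> frozenset | None:
        for t in self.synapomorphies:
            if t.child == clade_label:
                return t.to_states
        return None


def synapomorphies(result: ReconstructionResult, tree: Phylogeny) -> SynapomorphyReport:
    """Branches where the state fixes to a single novel state.

    A candidate synapomorphy is a branch whose child MPR set is a single
    state not attained by the parent in any minimum-change assignment —
    i.e. a derived state originating on the clade's stem and shared by the
    clade.  Ambiguous nodes (|MPR| > 1) are reported alongside, since a
    synapomorphy claim at or near them depends on how the ambiguity is
    resolved.
    """
    keys = tree.node_keys()
    internal = {keys[id(n)] for n in tree.postorder() if not n.is_leaf}
    hits = [
        t
        for t in result.transformations
        if len(t.to_states) == 1
        and next(iter(t.to_states)) not in t.from_states
        and t.child in internal
    ]
    return SynapomorphyReport(
        character=result.character,
        synapomorphies=hits,
        ambiguous_nodes=list(result.ambiguous_nodes),
    )


# ------------------------------------------------------------------- oracle

MAX_ORACLE_ASSIGNMENTS = 2_000_000


def _oracle_enumerate(tree: Phylogeny, matrix: CharacterMatrix, character: str):
    leaf_sets, _ = _leaf_sets(tree, matrix, character, min_observed=1)
    alphabet = tuple(matrix.alphabets[character])
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    n_assignments = len(alphabet) ** len(internal)
    if n_assignments > MAX_ORACLE_ASSIGNMENTS:
        raise InstanceTooLargeError(
            f"{len(alphabet)} states ** {len(internal)} internal nodes = "
            f"{n_assignments} assignments exceeds the enumeration budget"
        )
    keys = tree.node_keys()
    parent = tree.parents()

    best = _INF
    best_states: dict[str, set] = {keys[id(n)]: set() for n in nodes}
    for combo in itertools.product(alphabet, repeat=len(internal)):
        assign = {id(n): s for n, s in zip(internal, combo)}
        cost = 0
        for node in internal:
            p = parent[id(node)]
            if p is not None and assign[id(p)] != assign[id(node)]:
                cost += 1
        leaf_choice: dict[int, set] = {}
        for leaf in (n for n in nodes if n.is_leaf):
            p = parent[id(leaf)]
            observed = leaf_sets[id(leaf)]
            if p is None:  # single-node tree
                leaf_choice[id(leaf)] = set(observed)
                continue
            ps = assign[id(p)]
            if ps in observed:
                leaf_choice[id(leaf)] = {ps}
            else:
                cost += 1
                leaf_choice[id(leaf)] = set(observed)
        if cost < best:
            best = cost
            best_states = {keys[id(n)]: set() for n in nodes}
        if cost == best:
            for node in internal:
                best_states[keys[id(node)]].add(assign[id(node)])
            for leaf in (n for n in nodes if n.is_leaf):
                best_states[keys[id(leaf)]].update(leaf_choice[id(leaf)])
    return int(best), {k: frozenset(v) for k, v in best_states.items()}


def brute_force_length(
    tree: Phylogeny, matrix: CharacterMatrix, character: str
) -> int:
    """Exact minimum changes by exhaustive enumeration (testing oracle).

    Enumerates every assignment of states to internal nodes, so it is only
    usable on small instances (the assignment count is guarded).  It shares
    no code path with :func:`reconstruct` beyond leaf-set extraction.
    """
    length, _ = _oracle_enumerate(tree, matrix, character)
    return length


def brute_force_mpr(
    tree: Phylogeny, matrix: CharacterMatrix, character: str
) -> dict[str, frozenset]:
    """Exact MPR sets by exhaustive enumeration (testing oracle)."""
    _, states = _oracle_enumerate(tree, matrix, character)
    return states
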