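"""Cytogenetic character coding for phylogenetic analysis.

Two characters are built from karyotype records:

* ``x`` — the basic chromosome number, with unordered states 9–13.  Equal
  basic numbers in different lineages may be products of different
  rearrangements, so treating x as a character is an explicit homology
  oversimplification; it is what allows the character to be optimized on a
  phylogeny at all.

* ``nor_pair`` — the chromosome pair bearing the nucleolar organizer region.
  Raw pair numbers are not homologous across karyotypes with different
  chromosome counts, so raw observations pass through explicit homology
  rules before becoming states:

  - the NOR-bearing pair 9 of *Aplastodiscus* is treated as homeologous to
    the pair 11 of most cophomantines, and coded as state ``11``;
  - the pair-4 NORs of *Bokermannohyla alvarengai*, *Hyloscirtus alytolylax*
    and *H. palmeri* are conspicuously different from one another and are
    coded as three private states (``4a``/``4b``/``4c``), i.e. independent
    transformations on an unordered character;
  - medium-pair observations (pairs 6/7) collapse to one state per genus
    (a genus-scoped homology hypothesis); the rule set is data, so an
    alternative reading can be swapped in;
  - polymorphic NORs (more than one bearing pair in a species) become
    multi-state cells, which are cost-free ambiguity under parsimony.

Missing data is the ``?`` cell (``None`` in memory), distinct from every
state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import CodingError

__all__ = [
    "MISSING",
    "X_ALPHABET",
    "DEFAULT_NOR_ALPHABET",
    "CharacterMatrix",
    "NorRule",
    "NorHomologyRules",
    "default_nor_rules",
    "encode_basic_number",
    "encode_nor_position",
    "build_matrix",
]

MISSING = None  # cell sentinel; serialized as "?"

X_ALPHABET: tuple[str, ...] = ("9", "10", "11", "12", "13")

DEFAULT_NOR_ALPHABET: tuple[str, ...] = (
    "1", "2", "6", "7", "8", "9", "11", "12", "4a", "4b", "4c",
)


@dataclass(frozen=True)
class CharacterMatrix:
    """Taxa x characters matrix of unordered state sets with missing data.

    ``cells[character][taxon]`` is a frozenset of state labels, or ``None``
    for missing.  All characters are unordered.
    """

    taxa: tuple[str, ...]
    characters: tuple[str, ...]
    alphabets: Mapping[str, tuple[str, ...]]
    cells: Mapping[str, Mapping[str, frozenset | None]]

    def __post_init__(self):
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        for char in self.characters:
            alphabet = set(self.alphabets[char])
            for taxon in self.taxa:
                cell = self.cells[char].get(taxon)
                if cell is None:
                    continue
                if not cell:
                    raise ValueError(f"empty (non-missing) cell at {taxon}/{char}")
                extra = set(cell) - alphabet
                if extra:
                    raise ValueError(
                        f"cell {taxon}/{char} has states {sorted(extra)} outside "
                        f"the declared alphabet"
                    )

    def cell(self, taxon: str, character: str) -> frozenset | None:
        return self.cells[character].get(taxon)

    def to_frame(self):
        """Human-readable DataFrame view ("a|b" multistate, "?" missing)."""
        import pandas as pd

        def show(cell, alphabet):
            if cell is None:
                return "?"
            return "|".join(s for s in alphabet if s in cell)

        return pd.DataFrame(
            {
                char: [show(self.cells[char].get(t), self.alphabets[char]) for t in self.taxa]
                for char in self.characters
            },
            index=list(self.taxa),
        )


@dataclass(frozen=True)
class NorRule:
    """Map one raw NOR-bearing pair to a coded state.

    Scope narrows from species (most specific) to genus to any taxon.
    """

    raw_pair: int
    state: str
    genus: str | None = None
    species: str | None = None


@dataclass(frozen=True)
class NorHomologyRules:
    """An ordered rule set plus the declared state alphabet.

    ``map`` applies the most specific matching rule; a raw pair with no rule
    is a coding error (the observation has no homology hypothesis), never a
    silent literal state.
    """

    rules: tuple[NorRule, ...]
    alphabet: tuple[str, ...] = DEFAULT_NOR_ALPHABET

    def __post_init__(self):
        seen: dict[tuple, str] = {}
        for r in self.rules:
            key = (r.species, r.genus, r.raw_pair)
            if key in seen and seen[key] != r.state:
                raise ValueError(
                    f"conflicting rules for {key}: {seen[key]!r} vs {r.state!r}"
                )
            seen[key] = r.state
            if r.state not in self.alphabet:
                raise ValueError(
                    f"rule state {r.state!r} not in declared alphabet"
                )

    def map(self, raw_pair: int, genus: str | None, species: str | None) -> str:
        best = None
        best_rank = -1
        for r in self.rules:
            if r.raw_pair != raw_pair:
                continue
            if r.species is not None:
                if species != r.species:
                    continue
                rank = 2
            elif r.genus is not None:
                if genus != r.genus:
                    continue
                rank = 1
            else:
                rank = 0
            if rank > best_rank:
                best, best_rank = r, rank
        if best is None:
            raise CodingError(
                f"no NOR homology rule for pair {raw_pair} in "
                f"{species or genus or 'unknown taxon'}"
            )
        return best.state

    def to_json(self) -> str:
        return json.dumps(
            {
                "alphabet": list(self.alphabet),
                "rules": [
                    {
                        "raw_pair": r.raw_pair,
                        "state": r.state,
                        "genus": r.genus,
                        "species": r.species,
                    }
                    for r in self.rules
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "NorHomologyRules":
        doc = json.loads(text)
        return cls(
            rules=tuple(NorRule(**r) for r in doc["rules"]),
            alphabet=tuple(doc["alphabet"]),
        )


def default_nor_rules() -> NorHomologyRules:
    """The default NOR homology hypothesis for Cophomantini (see module docs)."""
    literal = tuple(
        NorRule(raw_pair=p, state=str(p)) for p in (1, 2, 8, 11, 12)
    )
    return NorHomologyRules(
        rules=literal
        + (
            # Aplastodiscus pair 9 is homeologous to the cophomantine pair 11.
            NorRule(raw_pair=9, state="11", genus="Aplastodiscus"),
            # Medium-pair NORs: one state per genus-scoped homology hypothesis.
            NorRule(raw_pair=6, state="6", genus="Aplastodiscus"),
            NorRule(raw_pair=7, state="6", genus="Aplastodiscus"),
            NorRule(raw_pair=7, state="7", genus="Boana"),
            # Boana pair 9 (the B. prasina polymorphism) has no homeology
            # hypothesis; it stays a literal state of its own.
            NorRule(raw_pair=9, state="9", genus="Boana"),
            # Conspicuously different pair-4 NORs: three private states,
            # i.e. independent transformations on an unordered character.
            NorRule(raw_pair=4, state="4a", species="Bokermannohyla alvarengai"),
            NorRule(raw_pair=4, state="4b", species="Hyloscirtus alytolylax"),
            NorRule(raw_pair=4, state="4c", species="Hyloscirtus palmeri"),
        )
    )


def _taxon_label(record) -> str:
    for attr in ("taxon_label", "taxon", "species"):
        value = getattr(record, attr, None)
        if value:
            return value
    raise CodingError(f"record {record!r} has no taxon label")


def _genus(record) -> str | None:
    g = getattr(record, "genus", None)
    if g:
        return g
    label = _taxon_label(record)
    return label.split()[0] if " " in label else None


def encode_basic_number(
    records: Iterable, alphabet: Sequence[str] = X_ALPHABET
) -> dict[str, frozenset | None]:
    """Code basic chromosome number x into one unordered state per taxon.

    Records need a ``basic_number_x`` (or ``x``) attribute; taxa without data
    code as missing.  An x outside the declared alphabet is a coding error
    naming the taxon, not a silent alphabet extension.
    """
    column: dict[str, frozenset | None] = {}
    for rec in records:
        taxon = _taxon_label(rec)
        x = getattr(rec, "basic_number_x", None)
        if x is None:
            x = getattr(rec, "x", None)
        if x is None:
            column[taxon] = MISSING
            continue
        state = str(int(x))
        if state not in alphabet:
            raise CodingError(
                f"{taxon}: basic number x={x} outside the state alphabet "
                f"{tuple(alphabet)}"
            )
        column[taxon] = frozenset({state})
    return column


def encode_nor_position(
    records: Iterable, rules: NorHomologyRules | None = None
) -> dict[str, frozenset | None]:
    """Code NOR-bearing pairs into unordered states via the homology rules.

    Records need a ``nor_pairs_raw`` attribute (iterable of raw pair numbers;
    more than one means a polymorphic multi-state cell) or a ``nor_pairs()``
    method returning annotations with ``pair_index``.
    """
    if rules is None:
        rules = default_nor_rules()
    column: dict[str, frozenset | None] = {}
    for rec in records:
        taxon = _taxon_label(rec)
        raw = getattr(rec, "nor_pairs_raw", None)
        if raw is None and hasattr(rec, "nor_pairs"):
            raw = [a.pair_index for a in rec.nor_pairs()]
        if not raw:
            column[taxon] = MISSING
            continue
        states = frozenset(
            rules.map(int(p), _genus(rec), _taxon_label(rec)) for p in raw
        )
        column[taxon] = states
    return column


def build_matrix(
    records: Sequence,
    rules: NorHomologyRules | None = None,
    x_alphabet: Sequence[str] = X_ALPHABET,
) -> CharacterMatrix:
    """Build the two-character (x, nor_pair) matrix from karyotype records.

    Coding is deterministic and order-independent: permuting the input
    records permutes matrix rows only.
    """
    if rules is None:
        rules = default_nor_rules()
    taxa = tuple(_taxon_label(r) for r in records)
    return CharacterMatrix(
        taxa=taxa,
        characters=("x", "nor_pair"),
        alphabets={"x": tuple(x_alphabet), "nor_pair": tuple(rules.alphabet)},
        cells={
            "x": encode_basic_number(records, x_alphabet),
            "nor_pair": encode_nor_position(records, rules),
        },
    )
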