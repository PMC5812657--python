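"""Character coding: basic number x and NOR homology mapping."""

import pytest

from karyoevo import (
    NorHomologyRules,
    NorRule,
    build_matrix,
    default_nor_rules,
    encode_basic_number,
    encode_nor_position,
)
from karyoevo.errors import CodingError


class Rec:
    """Minimal record for coding tests."""

    def __init__(self, taxon, x=None, nor=(), genus=None):
        self.taxon_label = taxon
        self.basic_number_x = x
        self.nor_pairs_raw = tuple(nor)
        self.genus = genus or taxon.split()[0]


def test_encode_basic_number_values_and_missing():
    col = encode_basic_number(
        [
            Rec("Hyloscirtus alytolylax", x=10),
            Rec("Boana leucocheila", x=11),
            Rec("Myersiohyla", x=None),
        ]
    )
    assert col["Hyloscirtus alytolylax"] == frozenset({"10"})
    assert col["Boana leucocheila"] == frozenset({"11"})
    assert col["Myersiohyla"] is None


def test_encode_basic_number_rejects_out_of_alphabet():
    with pytest.raises(CodingError, match="Weird taxon"):
        encode_basic_number([Rec("Weird taxon", x=15)])


def test_nor_homeology_and_private_states():
    col = encode_nor_position(
        [
            Rec("Aplastodiscus leucopygius", nor=[9]),
            Rec("Hyloscirtus alytolylax", nor=[4]),
            Rec("Hyloscirtus palmeri", nor=[4]),
            Rec("Bokermannohyla alvarengai", nor=[4]),
            Rec("Boana faber", nor=[11]),
            Rec("Boana boans", nor=[7]),
            Rec("Aplastodiscus eugenioi", nor=[6]),
            Rec("Aplastodiscus albofrenatus", nor=[7]),
            Rec("Boana prasina", nor=[9, 12]),
            Rec("Myersiohyla", nor=[]),
        ]
    )
    # Aplastodiscus pair 9 is homeologous to the cophomantine pair 11
    assert col["Aplastodiscus leucopygius"] == frozenset({"11"})
    # pair-4 NORs are three independent transformations (private states)
    four_states = {
        next(iter(col[t]))
        for t in (
            "Hyloscirtus alytolylax",
            "Hyloscirtus palmeri",
            "Bokermannohyla alvarengai",
        )
    }
    assert four_states == {"4a", "4b", "4c"}
    # genus-scoped medium-pair collapse: Aplastodiscus 6 and 7 are one state,
    # distinct from the Boana pair-7 state
    assert col["Aplastodiscus eugenioi"] == col["Aplastodiscus albofrenatus"]
    assert col["Boana boans"] != col["Aplastodiscus eugenioi"]
    # polymorphism becomes a multi-state cell; no data becomes missing
    assert col["Boana prasina"] == frozenset({"9", "12"})
    assert col["Myersiohyla"] is None


def test_nor_unmapped_pair_is_a_coding_error():
    with pytest.raises(CodingError, match="pair 10"):
        encode_nor_position([Rec("Boana atlantica", nor=[10])])


def test_rules_roundtrip_json_and_reject_conflicts():
    rules = default_nor_rules()
    assert NorHomologyRules.from_json(rules.to_json()) == rules
    with pytest.raises(ValueError, match="conflicting"):
        NorHomologyRules(
            rules=(
                NorRule(raw_pair=6, state="6", genus="Boana"),
                NorRule(raw_pair=6, state="7", genus="Boana"),
            ),
            alphabet=("6", "7"),
        )


def test_alternative_medium_pair_reading_is_configurable():
    """The literal M&M-style reading (pair 7 coded with pair 6) is one rule swap."""
    literal = NorHomologyRules(
        rules=(NorRule(raw_pair=7, state="6"), NorRule(raw_pair=6, state="6")),
        alphabet=("6",),
    )
    col = encode_nor_position([Rec("Boana boans", nor=[7])], literal)
    assert col["Boana boans"] == frozenset({"6"})


def test_coding_is_order_independent():
    recs = [
        Rec("Boana faber", x=12, nor=[11]),
        Rec("Boana boans", x=12, nor=[7]),
        Rec("Aplastodiscus arildae", x=11, nor=[11]),
    ]
    forward = build_matrix(recs)
    backward = build_matrix(list(reversed(recs)))
    assert set(forward.taxa) == set(backward.taxa)
    for char in forward.characters:
        for taxon in forward.taxa:
            assert forward.cell(taxon, char) == backward.cell(taxon, char)


def test_packaged_nor_alphabet_contains_published_states(dataset):
    alphabet = set(dataset.matrix.alphabets["nor_pair"])
    assert {"1", "2", "6", "8", "11", "12"} <= alphabet
    assert {"4a", "4b", "4c"} <= alphabet
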