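"""Karyotype morphometrics: CI, morphology classes, FN, relative length."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoevo import (
    ChromosomePair,
    CIThresholds,
    Karyotype,
    Morphology,
    centromeric_index,
    classify_morphology,
    fundamental_number,
    idiogram_coords,
    relative_length,
    validate_karyotype,
)
from karyoevo.errors import (
    IncompleteKaryotypeError,
    InvalidMeasurementError,
)

from conftest import random_karyotype


@pytest.mark.parametrize(
    "p, q, expected",
    [
        (1.0, 1.0, 0.5),      # perfectly metacentric symmetry
        (0.0, 2.3, 0.0),      # telocentric limit
        (0.41, 0.59, 0.41),   # arithmetic identity
    ],
)
def test_centromeric_index_values(p, q, expected):
    assert centromeric_index(p, q) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "p, q",
    [(-0.1, 1.0), (1.0, 0.0), (0.6, 0.4)],
)
def test_centromeric_index_rejects_bad_measurements(p, q):
    with pytest.raises(InvalidMeasurementError):
        centromeric_index(p, q)


@pytest.mark.parametrize(
    "ci, expected",
    [
        # published CI -> class pairings this classifier must reproduce
        (0.41, Morphology.METACENTRIC),
        (0.46, Morphology.METACENTRIC),
        (0.35, Morphology.SUBMETACENTRIC),
        (0.34, Morphology.SUBMETACENTRIC),
        (0.25, Morphology.SUBMETACENTRIC),  # "almost subtelocentric"
        # boundary behaviour of the default thresholds
        (0.5, Morphology.METACENTRIC),
        (0.37, Morphology.METACENTRIC),
        (0.2, Morphology.SUBTELOCENTRIC),
        (0.125, Morphology.SUBTELOCENTRIC),
        (0.0, Morphology.TELOCENTRIC),
    ],
)
def test_classify_morphology(ci, expected):
    assert classify_morphology(ci) is expected


def test_classify_morphology_domain_error():
    with pytest.raises(InvalidMeasurementError):
        classify_morphology(0.6)
    with pytest.raises(InvalidMeasurementError):
        classify_morphology(-0.01)


def test_classify_morphology_custom_thresholds():
    strict = CIThresholds(metacentric_min=0.45, submetacentric_min=0.3,
                          subtelocentric_min=0.15)
    assert classify_morphology(0.41, strict) is Morphology.SUBMETACENTRIC


@settings(derandomize=True, max_examples=100)
@given(
    p=st.floats(min_value=0.0, max_value=100.0),
    q=st.floats(min_value=1e-6, max_value=100.0),
    scale=st.floats(min_value=1e-3, max_value=1e3),
)
def test_classification_scale_invariance(p, q, scale):
    """classify(ci(p, q)) is invariant under (p, q) -> (c*p, c*q)."""
    if p > q:
        p, q = q, p
    base = classify_morphology(centromeric_index(p, q))
    scaled = classify_morphology(centromeric_index(p * scale, q * scale))
    assert base is scaled


def _uniform_karyotype(n_pairs, morph, ploidy=2):
    return Karyotype(
        species="toy",
        ploidy=ploidy,
        pairs=[
            ChromosomePair(pair_index=i, morphology=morph)
            for i in range(1, n_pairs + 1)
        ],
    )


def test_fundamental_number_all_telocentric_lower_bound():
    k = _uniform_karyotype(10, Morphology.TELOCENTRIC)
    assert fundamental_number(k) == 20  # FN = 2n when nothing is bi-armed


def test_fundamental_number_requires_morphology():
    k = Karyotype(species="toy", pairs=[ChromosomePair(pair_index=1)])
    with pytest.raises(IncompleteKaryotypeError):
        fundamental_number(k)


def test_fundamental_number_bounds_random():
    rng = random.Random(7)
    for _ in range(50):
        k = random_karyotype(rng)
        fn = fundamental_number(k)
        two_n = k.ploidy * k.basic_number_x
        assert two_n <= fn <= 2 * two_n
        all_biarmed = all(p.morphology.biarmed for p in k.pairs)
        assert (fn == 2 * two_n) == all_biarmed


def test_relative_length_uniform_and_single():
    pairs = [
        ChromosomePair(pair_index=i, p_len=1.0, q_len=2.0) for i in range(1, 13)
    ]
    k = Karyotype(species="toy", pairs=pairs)
    for p in pairs:
        assert relative_length(p, k) == pytest.approx(100.0 / 12.0)
    single = Karyotype(
        species="toy1", pairs=[ChromosomePair(pair_index=1, p_len=2.0, q_len=3.0)]
    )
    assert relative_length(single.pairs[0], single) == pytest.approx(100.0)


def test_relative_length_matches_hand_computation():
    # 11 pairs with known lengths; expectations computed independently
    # (plain spreadsheet-style arithmetic on the totals).
    totals = [20.0, 17.5, 15.0, 12.0, 9.5, 8.0, 6.5, 5.0, 4.0, 3.0, 2.5]
    hand = [100.0 * t / 103.0 for t in totals]  # sum(totals) == 103.0
    pairs = [
        ChromosomePair(pair_index=i, p_len=t * 0.4, q_len=t * 0.6)
        for i, t in enumerate(totals, start=1)
    ]
    k = Karyotype(species="toy", pairs=pairs)
    for p, expected in zip(pairs, hand):
        assert relative_length(p, k) == pytest.approx(expected, abs=1e-12)
    assert sum(relative_length(p, k) for p in pairs) == pytest.approx(100.0, abs=1e-9)


def test_validate_karyotype_passes_packaged_record(records_by_species):
    k = records_by_species["Boana raniceps"].karyotype
    assert validate_karyotype(k) == []


def test_validate_karyotype_flags_violations():
    k = _uniform_karyotype(10, Morphology.METACENTRIC)
    k.diploid_number_2n = 24  # contradicts ploidy * x = 20
    violations = validate_karyotype(k)
    assert len(violations) == 1 and "2n" in violations[0]

    pairs = [
        ChromosomePair(pair_index=i, morphology=Morphology.METACENTRIC,
                       rel_length=30.0)
        for i in range(1, 4)
    ]
    bad_rel = Karyotype(species="toy", pairs=pairs)  # sums to 90, not 100
    violations = validate_karyotype(bad_rel)
    assert len(violations) == 1 and "rel_length" in violations[0]


def test_idiogram_metacentric_and_telocentric_geometry():
    k = Karyotype(
        species="toy",
        pairs=[
            ChromosomePair(pair_index=1, ci=0.5, rel_length=10.0,
                           morphology=Morphology.METACENTRIC),
            ChromosomePair(pair_index=2, ci=0.0, rel_length=90.0,
                           morphology=Morphology.TELOCENTRIC),
        ],
    )
    coords = idiogram_coords(k)
    meta = coords[(coords.pair_index == 1) & coords.segment.isin(["p", "q"])]
    assert len(meta) == 2
    assert sorted((meta.y1 - meta.y0).tolist()) == pytest.approx([5.0, 5.0])
    telo = coords[(coords.pair_index == 2) & coords.segment.isin(["p", "q"])]
    assert telo.segment.tolist() == ["q"]  # single-armed: one segment


def test_idiogram_schematic_heights_sum_to_100(records_by_species):
    k = records_by_species["Hyloscirtus larinopygion"].karyotype
    coords = idiogram_coords(k, schematic=True)
    arms = coords[coords.segment.isin(["p", "q"])]
    assert coords.pair_index.nunique() == 12
    assert (arms.y1 - arms.y0).sum() == pytest.approx(100.0)


def test_idiogram_requires_rel_length_by_default(records_by_species):
    k = records_by_species["Hyloscirtus larinopygion"].karyotype
    with pytest.raises(IncompleteKaryotypeError):
        idiogram_coords(k)
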