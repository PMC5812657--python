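"""Packaged Cophomantini dataset: counts, printed values, consistency."""

import pytest

from karyoevo import fundamental_number, registry_counts, validate_karyotype
from karyoevo.errors import ConfigError


def test_studied_species_counts(dataset):
    studied = registry_counts(dataset.records, {"studied_here": True})
    assert studied["Boana"] == 25
    assert studied["Hyloscirtus"] == 3
    assert studied["total"] == 28


def test_taxonomy_registry_total(dataset):
    per_genus = dataset.taxonomy.per_genus
    assert per_genus == {
        "Aplastodiscus": 15,
        "Boana": 92,
        "Bokermannohyla": 32,
        "Hyloscirtus": 36,
        "Myersiohyla": 6,
    }
    assert dataset.taxonomy.total == 181


def test_c_band_registry(dataset):
    counts = registry_counts(dataset.records, "c_band_known")
    assert counts == {
        "Aplastodiscus": 8,
        "Boana": 33,
        "Bokermannohyla": 9,
        "Hyloscirtus": 3,
        "total": 53,
    }


def test_registry_counts_empty_and_bad_filter(dataset):
    zeros = registry_counts([], {})
    assert zeros["total"] == 0 and all(
        v == 0 for g, v in zeros.items() if g != "total"
    )
    with pytest.raises(ConfigError):
        registry_counts(dataset.records, {"bogus_key": 1})


def test_published_fundamental_numbers(records_by_species):
    expected = {
        "Hyloscirtus alytolylax": 38,
        "Hyloscirtus larinopygion": 46,
        "Hyloscirtus palmeri": 48,
    }
    for species, fn in expected.items():
        assert fundamental_number(records_by_species[species].karyotype) == fn


def test_alytolylax_record_details(records_by_species):
    r = records_by_species["Hyloscirtus alytolylax"]
    k = r.karyotype
    assert k.diploid_number_2n == 20
    assert k.basic_number_x == 10
    assert k.sex_system == "XY"
    (nor,) = k.nor_pairs()
    assert (nor.pair_index, nor.arm, nor.position) == (4, "p", "terminal")


def test_leucocheila_b_chromosome(records_by_species):
    (b,) = records_by_species["Boana leucocheila"].karyotype.b_chromosomes
    assert b.rel_length == pytest.approx(3.11)
    assert b.ci == pytest.approx(0.46)
    assert b.morphology.value == "m"
    assert b.mitotic_stability is True


def test_triploid_specimen_record(records_by_species):
    r = records_by_species["Boana pulchella (LGE 11504)"]
    assert r.specimen_level
    assert r.karyotype.ploidy == 3
    assert r.karyotype.diploid_number_2n == 36


def test_all_packaged_karyotypes_valid(dataset):
    for r in dataset.records:
        if r.karyotype is not None:
            assert validate_karyotype(r.karyotype) == [], r.species


def test_every_record_has_provenance(dataset):
    assert all(r.provenance for r in dataset.records)


def test_matrix_rows_match_tree_leaves(dataset):
    assert set(dataset.matrix.taxa) == set(dataset.tree.leaf_labels())


def test_shipped_matrix_regenerates_byte_identically(dataset):
    from importlib import resources

    from karyoevo.matrixio import write_matrix

    shipped = (resources.files("karyoevo") / "data" / "matrix.nex").read_text()
    assert write_matrix(dataset.matrix, "nexus") == shipped


def test_myersiohyla_is_missing_for_both_characters(dataset):
    assert dataset.matrix.cell("Myersiohyla", "x") is None
    assert dataset.matrix.cell("Myersiohyla", "nor_pair") is None
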