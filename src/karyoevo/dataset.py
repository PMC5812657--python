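"""The packaged Cophomantini cytogenetic dataset.

Cophomantini is a Neotropical treefrog tribe of five genera
(*Aplastodiscus*, *Boana*, *Bokermannohyla*, *Hyloscirtus*, *Myersiohyla*).
The dataset bundles, transcribed from the main text of the primary
cytogenetic literature on the tribe:

* per-pair karyotype records for the 28 newly studied species (morphology
  classes and every centromeric index printed in prose; raw arm-length
  measurements were published only as supplementary material and are not
  reproduced),
* literature records for taxa named in the text (basic number and/or
  NOR-bearing pair), each flagged by source,
* a condensed rooted phylogeny: the tribe's intergeneric backbone
  Myersiohyla,(Hyloscirtus,(Bokermannohyla,(Aplastodiscus,Boana))) with
  species groups as clades, embedded in Hylinae next to condensed terminals
  for the other hyline tribes and the two outgroup subfamilies,
* the coded two-character matrix (basic number x, NOR-bearing pair), and
* registry tables: described-species counts per genus (total 181) and the
  per-genus counts of species with known C-bands (total 53).

Every record carries a ``provenance`` tag naming the location in the source
text it was transcribed from.  Fields the text does not print are missing,
never inferred.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

from .characters import CharacterMatrix, build_matrix, default_nor_rules
from .errors import ConfigError
from .io import read_karyotypes_csv
from .karyotype import Karyotype, validate_karyotype
from .trees import Phylogeny, parse_newick

__all__ = [
    "GENERA",
    "SpeciesRecord",
    "CondensedTaxon",
    "TaxonomyRegistry",
    "Dataset",
    "load_dataset",
    "registry_counts",
]

GENERA = ("Aplastodiscus", "Boana", "Bokermannohyla", "Hyloscirtus", "Myersiohyla")


@dataclass(frozen=True)
class SpeciesRecord:
    """One Cophomantini species (or, for the triploid, one specimen)."""

    species: str
    genus: str
    species_group: str | None = None
    studied_here: bool = False
    specimen_level: bool = False
    n_specimens: str | None = None
    techniques: tuple[str, ...] = ()
    basic_number_x: int | None = None
    nor_pairs_raw: tuple[int, ...] = ()
    nor_position: str | None = None
    karyotype: Karyotype | None = None
    sex_system: str | None = None
    c_band_known: bool = False
    caution: bool = False
    source: str = "literature"
    provenance: str = ""

    def __post_init__(self):
        if self.genus not in GENERA:
            raise ValueError(f"{self.species}: unknown genus {self.genus!r}")
        if self.studied_here and not self.techniques:
            raise ValueError(f"{self.species}: studied here but no techniques listed")

    @property
    def taxon_label(self) -> str:
        return self.species


@dataclass(frozen=True)
class CondensedTaxon:
    """A terminal condensing a clade outside Cophomantini (or a genus rest)."""

    taxon_label: str
    genus: str | None = None
    basic_number_x: int | None = None
    nor_pairs_raw: tuple[int, ...] = ()
    provenance: str = ""


@dataclass(frozen=True)
class TaxonomyRegistry:
    """Described-species counts per genus; the total must equal their sum."""

    counts: tuple[tuple[str, int], ...]

    @property
    def per_genus(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def total(self) -> int:
        return sum(n for _, n in self.counts)


class Dataset(NamedTuple):
    records: list[SpeciesRecord]
    matrix: CharacterMatrix
    tree: Phylogeny
    taxonomy: TaxonomyRegistry
    condensed: list[CondensedTaxon]
    c_bands_known: dict[str, int]


def _data_text(name: str) -> str:
    return (resources.files("karyoevo") / "data" / name).read_text(encoding="utf-8")


def _parse_bool(s: str) -> bool:
    return s == "1"


def _parse_nor(s: str) -> tuple[int, ...]:
    return tuple(int(p) for p in s.split(";") if p)


def load_dataset(validate: bool = True) -> Dataset:
    """Load the packaged records, character matrix, tree and registries.

    With ``validate=True`` (the default) every packaged karyotype is checked
    against the karyotype invariants and any violation is a packaging error.
    """
    karyotypes = {
        k.species: k
        for k in read_karyotypes_csv(
            resources.files("karyoevo") / "data" / "karyotype_pairs.csv"
        )
    }
    records: list[SpeciesRecord] = []
    for row in csv.DictReader(_data_text("species.csv").splitlines()):
        k = karyotypes.get(row["species"])
        records.append(
            SpeciesRecord(
                species=row["species"],
                genus=row["genus"],
                species_group=row["species_group"] or None,
                studied_here=_parse_bool(row["studied_here"]),
                specimen_level=_parse_bool(row["specimen_level"]),
                n_specimens=row["n_specimens"] or None,
                techniques=tuple(t for t in row["techniques"].split(";") if t),
                basic_number_x=int(row["x"]) if row["x"] else (
                    k.basic_number_x if k else None
                ),
                nor_pairs_raw=_parse_nor(row["nor_pairs_raw"]),
                nor_position=row["nor_position"] or None,
                karyotype=k,
                sex_system=k.sex_system if k else None,
                c_band_known=_parse_bool(row["c_band_known"]),
                caution=_parse_bool(row["caution"]),
                source=row["source"],
                provenance=row["provenance"],
            )
        )
    condensed = [
        CondensedTaxon(
            taxon_label=row["taxon"],
            genus=row["genus"] or None,
            basic_number_x=int(row["x"]) if row["x"] else None,
            nor_pairs_raw=_parse_nor(row["nor_pairs_raw"]),
            provenance=row["provenance"],
        )
        for row in csv.DictReader(_data_text("condensed.csv").splitlines())
    ]
    tree = parse_newick(_data_text("tree.nwk"))
    registries = json.loads(_data_text("registries.json"))
    taxonomy = TaxonomyRegistry(counts=tuple(registries["taxonomy"].items()))

    matrix_records = [r for r in records if not r.specimen_level] + condensed
    matrix = build_matrix(matrix_records, default_nor_rules())

    if validate:
        problems: list[str] = []
        for r in records:
            if r.karyotype is not None:
                problems += [
                    f"{r.species}: {v}" for v in validate_karyotype(r.karyotype)
                ]
        missing = set(matrix.taxa) ^ set(tree.leaf_labels())
        if missing:
            problems.append(f"matrix/tree taxa mismatch: {sorted(missing)}")
        if problems:
            raise ValueError("packaged dataset inconsistent: " + "; ".join(problems))

    return Dataset(
        records=records,
        matrix=matrix,
        tree=tree,
        taxonomy=taxonomy,
        condensed=condensed,
        c_bands_known=dict(registries["c_bands_known"]),
    )


_RECORD_FILTER_KEYS = {"studied_here", "genus", "group", "technique", "caution"}


def registry_counts(
    records: Iterable[SpeciesRecord],
    filter: dict | str | None = None,
    c_bands_registry: dict[str, int] | None = None,
) -> dict[str, int]:
    """Per-genus counts (plus ``total``) of records matching a filter.

    ``filter`` is a dict over {studied_here, genus, group, technique,
    caution}, or the string ``"c_band_known"``.  The C-band filter returns
    the packaged per-genus literature registry (the species-level rows cover
    only taxa named in the main text, so the genus totals are registry data,
    not row counts); pass ``c_bands_registry`` to supply it explicitly,
    otherwise the packaged one is loaded.  Specimen-level records never
    count toward species tallies.
    """
    if filter == "c_band_known":
        if c_bands_registry is None:
            c_bands_registry = json.loads(_data_text("registries.json"))[
                "c_bands_known"
            ]
        out = dict(c_bands_registry)
        out["total"] = sum(c_bands_registry.values())
        return out

    if filter is None:
        filter = {}
    elif isinstance(filter, str):
        filter = {filter: True}
    unknown = set(filter) - _RECORD_FILTER_KEYS
    if unknown:
        raise ConfigError(
            f"unknown filter key(s) {sorted(unknown)}; "
            f"supported: {sorted(_RECORD_FILTER_KEYS)} or 'c_band_known'"
        )

    counts = {genus: 0 for genus in GENERA}
    for r in records:
        if r.specimen_level:
            continue
        if "studied_here" in filter and r.studied_here != filter["studied_here"]:
            continue
        if "genus" in filter and r.genus != filter["genus"]:
            continue
        if "group" in filter and r.species_group != filter["group"]:
            continue
        if "technique" in filter and filter["technique"] not in r.techniques:
            continue
        if "caution" in filter and r.caution != filter["caution"]:
            continue
        counts[r.genus] += 1
    counts["total"] = sum(counts.values())
    return counts
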