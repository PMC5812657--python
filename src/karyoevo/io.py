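"""Karyotype CSV dialect and idiogram TSV output.

One row per homologue record or B chromosome.  Columns::

    species, group, source, ploidy, pair_index, homologue, p_len, q_len,
    ci, morphology, rel_length, nor_arm, nor_position, bands, b_flag,
    sex_system

``homologue`` is A/B for heteromorphic half-records and "-" otherwise;
``bands`` is a semicolon-separated list of verbatim descriptors; B-chromosome
rows leave ``pair_index`` empty and set ``b_flag`` to ``stable``/``unstable``
(or ``1`` when stability is unrecorded).  Floats are written with Python's
shortest round-tripping representation, so write -> read is lossless.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Sequence, TextIO

from .errors import MatrixParseError
from .karyotype import (
    BChromosome,
    ChromosomePair,
    Karyotype,
    Morphology,
    NORAnnotation,
)

__all__ = [
    "KARYOTYPE_CSV_COLUMNS",
    "write_karyotypes_csv",
    "read_karyotypes_csv",
    "karyotypes_to_csv",
    "karyotypes_from_csv",
    "write_idiogram_tsv",
]

KARYOTYPE_CSV_COLUMNS = [
    "species",
    "group",
    "source",
    "ploidy",
    "pair_index",
    "homologue",
    "p_len",
    "q_len",
    "ci",
    "morphology",
    "rel_length",
    "nor_arm",
    "nor_position",
    "bands",
    "b_flag",
    "sex_system",
]


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _opt_float(s: str) -> float | None:
    return float(s) if s else None


def karyotypes_to_csv(karyotypes: Iterable[Karyotype]) -> str:
    """Serialize karyotypes to the CSV dialect (returned as a string)."""
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(KARYOTYPE_CSV_COLUMNS)
    for k in karyotypes:
        base = [k.species, k.group or "", k.source, str(k.ploidy)]
        for p in k.pairs:
            w.writerow(
                base
                + [
                    str(p.pair_index),
                    p.homologue or "-",
                    _fmt(p.p_len),
                    _fmt(p.q_len),
                    _fmt(p.ci),
                    p.morphology.value if p.morphology else "",
                    _fmt(p.rel_length),
                    (p.nor.arm or "") if p.nor else "",
                    (p.nor.position or "nor") if p.nor else "",
                    ";".join(p.bands),
                    "",
                    k.sex_system or "",
                ]
            )
        for b in k.b_chromosomes:
            flag = (
                "1"
                if b.mitotic_stability is None
                else ("stable" if b.mitotic_stability else "unstable")
            )
            w.writerow(
                base
                + [
                    "",
                    "-",
                    "",
                    "",
                    _fmt(b.ci),
                    b.morphology.value if b.morphology else "",
                    _fmt(b.rel_length),
                    "",
                    "",
                    "",
                    flag,
                    k.sex_system or "",
                ]
            )
    return buf.getvalue()


def write_karyotypes_csv(karyotypes: Iterable[Karyotype], path) -> None:
    Path(path).write_text(karyotypes_to_csv(karyotypes), encoding="utf-8")


def karyotypes_from_csv(text: str, derive: bool = False) -> list[Karyotype]:
    """Parse the CSV dialect back into karyotypes (inverse of the writer).

    With ``derive=True``, missing CI and morphology are filled from arm
    lengths after reading.
    """
    reader = csv.reader(_io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise MatrixParseError("empty karyotype CSV", line=1)
    if header[: len(KARYOTYPE_CSV_COLUMNS)] != KARYOTYPE_CSV_COLUMNS:
        raise MatrixParseError(
            f"unexpected header {header!r}; expected {KARYOTYPE_CSV_COLUMNS!r}",
            line=1,
        )
    order: list[str] = []
    rows_by_species: dict[str, list[dict]] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row or not any(row):
            continue
        if len(row) != len(KARYOTYPE_CSV_COLUMNS):
            raise MatrixParseError(
                f"expected {len(KARYOTYPE_CSV_COLUMNS)} fields, got {len(row)}",
                line=lineno,
            )
        rec = dict(zip(KARYOTYPE_CSV_COLUMNS, row))
        if rec["species"] not in rows_by_species:
            order.append(rec["species"])
            rows_by_species[rec["species"]] = []
        rows_by_species[rec["species"]].append(rec)

    karyotypes = []
    for species in order:
        rows = rows_by_species[species]
        first = rows[0]
        pairs: list[ChromosomePair] = []
        bs: list[BChromosome] = []
        sex = next((r["sex_system"] for r in rows if r["sex_system"]), None)
        for r in rows:
            morphology = Morphology(r["morphology"]) if r["morphology"] else None
            if r["b_flag"]:
                stability = {"stable": True, "unstable": False, "1": None}[r["b_flag"]]
                bs.append(
                    BChromosome(
                        rel_length=_opt_float(r["rel_length"]),
                        ci=_opt_float(r["ci"]),
                        morphology=morphology,
                        mitotic_stability=stability,
                    )
                )
                continue
            nor = None
            if r["nor_position"] or r["nor_arm"]:
                nor = NORAnnotation(
                    pair_index=int(r["pair_index"]),
                    arm=r["nor_arm"] or None,
                    position=r["nor_position"] if r["nor_position"] != "nor" else None,
                )
            pairs.append(
                ChromosomePair(
                    pair_index=int(r["pair_index"]),
                    morphology=morphology,
                    p_len=_opt_float(r["p_len"]),
                    q_len=_opt_float(r["q_len"]),
                    ci=_opt_float(r["ci"]),
                    rel_length=_opt_float(r["rel_length"]),
                    homologue=None if r["homologue"] in ("-", "") else r["homologue"],
                    nor=nor,
                    bands=tuple(b for b in r["bands"].split(";") if b),
                )
            )
        k = Karyotype(
            species=species,
            pairs=pairs,
            group=first["group"] or None,
            ploidy=int(first["ploidy"]),
            b_chromosomes=bs,
            sex_system=sex,
            source=first["source"],
        )
        karyotypes.append(k.derived() if derive else k)
    return karyotypes


def read_karyotypes_csv(path, derive: bool = False) -> list[Karyotype]:
    return karyotypes_from_csv(Path(path).read_text(encoding="utf-8"), derive=derive)


def write_idiogram_tsv(coords, path) -> None:
    """Write idiogram geometry (from :func:`karyotype.idiogram_coords`) as TSV."""
    coords.to_csv(path, sep="\t", index=False)
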