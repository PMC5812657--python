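"""Regenerate the packaged Cophomantini dataset under src/karyoevo/data/.

The dataset transcribes, record by record, the karyotype descriptions,
technique table, registry counts and condensed phylogeny printed in the main
text of the primary cytogenetic literature on Cophomantini.  Only values
printed in the text are packaged; where the text is silent a field is left
missing rather than inferred.  Run from the repository root:

    python scripts/build_data.py
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from karyoevo.characters import build_matrix, default_nor_rules
from karyoevo.io import write_karyotypes_csv
from karyoevo.karyotype import (
    BChromosome,
    ChromosomePair,
    Karyotype,
    Morphology,
    NORAnnotation,
)
from karyoevo.matrixio import write_matrix
from karyoevo.trees import parse_newick, write_newick

DATA = Path(__file__).resolve().parents[1] / "src" / "karyoevo" / "data"

M, SM, ST, T = "m", "sm", "st", "t"

# ---------------------------------------------------------------- karyotypes
# per species: group, pair morphologies (pair 1..x), printed CIs, NOR, extras.
# Heteromorphic pairs are (pair, [(homologue, morph, ci), ...]).

STUDIED = {
    # --- Hyloscirtus -------------------------------------------------------
    "Hyloscirtus alytolylax": dict(
        genus="Hyloscirtus", group="H. bogotensis", n="2F3M",
        tech="Ag-NORs;C-bands;DAPI/CMA3",
        morphs=[M, M, SM, SM, SM, M, T, M, M, M],
        nor=(4, "p", "terminal"), sex="XY",
        prov="results:hyloscirtus",
    ),
    "Hyloscirtus palmeri": dict(
        genus="Hyloscirtus", group="H. bogotensis", n="1F",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, SM, M, SM, M, M, M, M],
        nor=(4, "q", "terminal"),
        prov="results:hyloscirtus",
    ),
    "Hyloscirtus larinopygion": dict(
        genus="Hyloscirtus", group="H. larinopygion", n="2M",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, SM, SM, M, M, M, M, T],
        nor=(1, "p", "terminal"),
        prov="results:hyloscirtus",
    ),
    # --- Boana albopunctata group -----------------------------------------
    "Boana cf. alfaroi": dict(
        genus="Boana", group="B. albopunctata", n="1M1U", tech="rDNA-FISH",
        morphs=[M, M, SM, SM, SM, SM, SM, M, M, SM, M],
        nor=(8, "p", "terminal"),
        prov="results:albopunctata-group",
    ),
    "Boana leucocheila": dict(
        genus="Boana", group="B. albopunctata", n="3M",
        tech="Ag-NORs;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, SM, SM, SM, M, M, M, SM, M],
        nor=(8, "p", "terminal"),
        b=dict(rel=3.11, ci=0.46, morph=M, stable=True),
        prov="results:albopunctata-group",
    ),
    "Boana multifasciata": dict(
        genus="Boana", group="B. albopunctata", n="3M1U",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, ST, SM, M, M, SM, M],
        nor=(8, "p", "terminal"),
        bands={1: ("p:interstitial:C+",), 7: ("p:interstitial:C+", "q:interstitial:C+"),
               8: ("p:pericentromeric:C+",), 9: ("q:pericentromeric:C+",)},
        prov="results:albopunctata-group",
    ),
    "Boana almendarizae": dict(
        genus="Boana", group="B. albopunctata", n="2M",
        tech="Ag-NORs;C-bands;DAPI/CMA3",
        morphs=[M, M, SM, SM, SM, SM, SM, M, SM, M, M, M],
        nor=(12, None, "terminal"),
        prov="results:albopunctata-group",
    ),
    "Boana calcarata": dict(
        genus="Boana", group="B. albopunctata", n="1M", tech="C-bands",
        morphs=[M, M, SM, ST, SM, SM, M, M, M, M, M, M],
        prov="results:albopunctata-group",
    ),
    "Boana cf. lanciformis": dict(
        genus="Boana", group="B. albopunctata", n="1M", tech="Ag-NORs",
        morphs=[M, M, SM, ST, SM, ST, SM, M, M, SM, SM, M],
        nor=(11, "q", "terminal"),
        prov="results:albopunctata-group",
    ),
    "Boana heilprini": dict(
        genus="Boana", group="B. albopunctata", n="1F1M", tech="DAPI/CMA3",
        morphs=[M, M, SM, SM, M, SM, SM, M, SM, M, M, SM],
        prov="results:albopunctata-group",
    ),
    "Boana raniceps": dict(
        genus="Boana", group="B. albopunctata", n="1F14M1J2U",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, SM, M, M, SM, M, M, SM],
        nor=(11, "q", "terminal"),
        bands={7: ("p:pericentromeric:C+",), 11: ("q:interstitial:C+",)},
        prov="results:albopunctata-group",
    ),
    # --- Boana faber / pellucens groups -----------------------------------
    "Boana faber": dict(
        genus="Boana", group="B. faber", n="3M",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, ST, ST, M, SM, SM, M, M],
        nor=(11, "q", "terminal"),
        prov="results:faber-pellucens-groups",
    ),
    "Boana pellucens": dict(
        genus="Boana", group="B. pellucens", n="2M",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, SM, SM, SM, M, M, SM, M, SM, M],
        nor=(11, "q", "interstitial"),
        prov="results:faber-pellucens-groups",
    ),
    # --- Boana punctata group ---------------------------------------------
    "Boana cinerascens": dict(
        genus="Boana", group="B. punctata", n="7M1U",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, ST, SM, M, M, SM, M, M],
        nor=(11, "q", "interstitial"),
        prov="results:punctata-group",
    ),
    "Boana punctata": dict(
        genus="Boana", group="B. punctata", n="2F",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, SM, SM, ST, SM, M, M, SM, None, SM],
        hetero={11: [("A", M, None), ("B", SM, None)]},
        nor=(11, None, None),
        prov="results:punctata-group",
    ),
    # --- Boana semilineata group ------------------------------------------
    "Boana boans": dict(
        genus="Boana", group="B. semilineata", n="2M1U",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, SM, SM, None, M, M, M, M],
        ci={5: 0.35},
        hetero={8: [("A", SM, 0.34), ("B", M, 0.41)]},
        nor=(7, "q", "interstitial"),
        prov="results:semilineata-group",
    ),
    "Boana cf. semilineata": dict(
        genus="Boana", group="B. semilineata", n="1M1U",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, SM, SM, SM, SM, M, M, M],
        ci={5: 0.34},
        nor=(7, "q", "interstitial"),
        prov="results:semilineata-group",
    ),
    "Boana wavrini": dict(
        genus="Boana", group="B. semilineata", n="1M2U",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH",
        morphs=[M, M, SM, ST, SM, SM, SM, SM, M, M, M, M],
        ci={5: 0.25},
        nor=(11, "q", "interstitial"),
        prov="results:semilineata-group",
    ),
    # --- Boana pulchella group --------------------------------------------
    # shared morphology: 1,2,9-12 m; 3,5,7 sm; 4,6 st; pair 8 varies.
    "Boana albonigra": dict(
        genus="Boana", group="B. pulchella", n="1F2M",
        tech="Ag-NORs;C-bands;DAPI/CMA3", pair8=SM,
        nor=(11, "q", "interstitial"), prov="results:pulchella-group",
    ),
    "Boana bischoffi": dict(
        genus="Boana", group="B. pulchella", n="1M",
        tech="Ag-NORs;C-bands", pair8=SM,
        nor=(11, "q", "interstitial"), prov="results:pulchella-group",
    ),
    "Boana caingua": dict(
        genus="Boana", group="B. pulchella", n="1F12M",
        tech="Ag-NORs;C-bands;DAPI/CMA3", pair8=M,
        nor=(12, None, "interstitial"), prov="results:pulchella-group",
    ),
    "Boana cipoensis": dict(
        genus="Boana", group="B. pulchella", n="4M",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH", pair8=SM,
        nor=(1, "p", "terminal"), prov="results:pulchella-group",
    ),
    "Boana cordobae": dict(
        genus="Boana", group="B. pulchella", n="2F9M",
        tech="Ag-NORs;C-bands;DAPI/CMA3", pair8=M,
        nor=(11, "q", "terminal"), prov="results:pulchella-group",
    ),
    "Boana curupi": dict(
        genus="Boana", group="B. pulchella", n="6M",
        tech="Ag-NORs;C-bands;DAPI/CMA3", pair8=SM,
        nor=(1, "p", "terminal"), prov="results:pulchella-group",
    ),
    "Boana marianitae": dict(
        genus="Boana", group="B. pulchella", n="2M",
        tech="Ag-NORs;C-bands;DAPI/CMA3", pair8=SM,
        nor=(11, "q", "interstitial"), prov="results:pulchella-group",
    ),
    "Boana pulchella": dict(
        genus="Boana", group="B. pulchella", n="3F34M1J",
        tech="Ag-NORs;C-bands;DAPI/CMA3", pair8=M,
        nor=(12, None, "terminal"), prov="results:pulchella-group",
    ),
    "Boana riojana": dict(
        genus="Boana", group="B. pulchella", n="6F8M",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH", pair8=SM,
        nor=(11, "q", "interstitial"), prov="results:pulchella-group",
    ),
    "Boana stellae": dict(
        genus="Boana", group="B. pulchella", n="1F8M",
        tech="Ag-NORs;C-bands;DAPI/CMA3;rDNA-FISH", pair8=SM,
        nor=(1, "p", "terminal"), prov="results:pulchella-group",
    ),
}

PULCHELLA_BASE = [M, M, SM, ST, SM, ST, SM, None, M, M, M, M]


def build_karyotype(species: str, spec: dict, ploidy: int = 2) -> Karyotype:
    morphs = spec.get("morphs")
    if morphs is None:
        morphs = list(PULCHELLA_BASE)
        morphs[7] = spec["pair8"]
    cis = spec.get("ci", {})
    hetero = spec.get("hetero", {})
    bands = spec.get("bands", {})
    nor = spec.get("nor")
    pairs = []
    for i, morph in enumerate(morphs, start=1):
        annotation = None
        if nor is not None and nor[0] == i:
            annotation = NORAnnotation(pair_index=i, arm=nor[1], position=nor[2])
        if i in hetero:
            for hom, hmorph, hci in hetero[i]:
                pairs.append(
                    ChromosomePair(
                        pair_index=i,
                        morphology=Morphology(hmorph),
                        ci=hci,
                        homologue=hom,
                        nor=annotation,
                        bands=tuple(bands.get(i, ())),
                    )
                )
        else:
            pairs.append(
                ChromosomePair(
                    pair_index=i,
                    morphology=Morphology(morph),
                    ci=cis.get(i),
                    nor=annotation,
                    bands=tuple(bands.get(i, ())),
                )
            )
    b_list = []
    if "b" in spec:
        b = spec["b"]
        b_list.append(
            BChromosome(
                rel_length=b["rel"],
                ci=b["ci"],
                morphology=Morphology(b["morph"]),
                mitotic_stability=b["stable"],
            )
        )
    return Karyotype(
        species=species,
        pairs=pairs,
        group=spec["group"],
        ploidy=ploidy,
        b_chromosomes=b_list,
        sex_system=spec.get("sex"),
        source="this_study",
    )


# ------------------------------------------------------- literature records
# (species, genus, group, x, nor_pairs_raw, nor_position, c_band, caution, provenance)
LITERATURE = [
    ("Myersiohyla", "Myersiohyla", None, None, "", None, False, False,
     "discussion:basic-number"),
    ("Hyloscirtus armatus", "Hyloscirtus", "H. armatus", 12, "", None, False, False,
     "discussion:basic-number"),
    ("Bokermannohyla alvarengai", "Bokermannohyla", None, 12, "4", None, False, False,
     "discussion:nor-location"),
    ("Bokermannohyla ibitiguara", "Bokermannohyla", None, 12, "1", None, False, False,
     "discussion:nor-location"),
    ("Aplastodiscus perviridis", "Aplastodiscus", "A. perviridis", 12, "11", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus cochranae", "Aplastodiscus", "A. perviridis", 12, "11", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus albosignatus", "Aplastodiscus", "A. albosignatus", 10, "9", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus callipygius", "Aplastodiscus", "A. albosignatus", None, "9", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus leucopygius", "Aplastodiscus", "A. albosignatus", 9, "9", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus albofrenatus", "Aplastodiscus", "A. albofrenatus", 11, "6", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus arildae", "Aplastodiscus", "A. albofrenatus", 11, "11", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus ehrhardti", "Aplastodiscus", "A. albofrenatus", 11, "6", None,
     True, False, "discussion:nor-location"),
    ("Aplastodiscus eugenioi", "Aplastodiscus", "A. albofrenatus", 11, "6", None,
     True, False, "discussion:nor-location"),
    ("Boana albopunctata", "Boana", "B. albopunctata", 11, "8", None, True, False,
     "discussion:albopunctata-group"),
    ("Boana fasciata", "Boana", "B. albopunctata", 12, "", None, False, True,
     "discussion:albopunctata-group"),
    ("Boana prasina", "Boana", "B. pulchella", None, "9;12", None, True, False,
     "discussion:nor-location"),
    ("Boana joaquini", "Boana", "B. pulchella", None, "1", None, True, False,
     "discussion:nor-location"),
    ("Boana semiguttata", "Boana", "B. pulchella", None, "1", None, True, False,
     "discussion:nor-location"),
    ("Boana pombali", "Boana", "B. semilineata", None, "7", None, False, False,
     "discussion:nor-location"),
    ("Boana geographica", "Boana", "B. semilineata", None, "1", "centromeric",
     False, False, "discussion:nor-location"),
    ("Boana semilineata", "Boana", "B. semilineata", None, "7", None, True, False,
     "discussion:nor-location"),
]

# --------------------------------------------------------- condensed taxa
# Terminals condensing the non-Cophomantini context of the optimization:
# hyline tribes with the modal hyline condition, and the two outgroup
# subfamilies with x = 13.
CONDENSED = [
    ("Bokermannohyla spp.", "Bokermannohyla", 12, "11",
     "discussion:nor-location"),
    ("Dendropsophini", None, 12, "11", "discussion:basic-number"),
    ("Hylini", None, 12, "11", "discussion:basic-number"),
    ("Lophyohylini", None, 12, "11", "discussion:basic-number"),
    ("Pelodryadinae", None, 13, "", "discussion:basic-number"),
    ("Phyllomedusinae", None, 13, "", "discussion:basic-number"),
]

def _clade(label: str | None, *children: str) -> str:
    return "(" + ",".join(children) + ")" + (label or "")


TREE = (
    _clade(
        "Hylidae",
        _clade(None, "Phyllomedusinae", "Pelodryadinae"),
        _clade(
            "Hylinae",
            _clade(None, "Dendropsophini", "Hylini", "Lophyohylini"),
            _clade(
                "Cophomantini",
                "Myersiohyla",
                _clade(
                    None,
                    _clade(
                        "Hyloscirtus",
                        _clade("H._bogotensis_group",
                               "Hyloscirtus_alytolylax", "Hyloscirtus_palmeri"),
                        _clade(None,
                               "Hyloscirtus_armatus", "Hyloscirtus_larinopygion"),
                    ),
                    _clade(
                        None,
                        _clade("Bokermannohyla",
                               "Bokermannohyla_alvarengai",
                               "Bokermannohyla_ibitiguara",
                               "Bokermannohyla_spp."),
                        _clade(
                            None,
                            _clade(
                                "Aplastodiscus",
                                _clade("A._perviridis_group",
                                       "Aplastodiscus_perviridis",
                                       "Aplastodiscus_cochranae"),
                                _clade("A._albosignatus_group",
                                       "Aplastodiscus_albosignatus",
                                       "Aplastodiscus_callipygius",
                                       "Aplastodiscus_leucopygius"),
                                _clade("A._albofrenatus_group",
                                       "Aplastodiscus_albofrenatus",
                                       _clade(None,
                                              "Aplastodiscus_arildae",
                                              _clade(None,
                                                     "Aplastodiscus_ehrhardti",
                                                     "Aplastodiscus_eugenioi"))),
                            ),
                            _clade(
                                "Boana",
                                _clade(
                                    "B._albopunctata_group",
                                    _clade("B._albopunctata_2n22_clade",
                                           "Boana_albopunctata",
                                           "Boana_cf._alfaroi",
                                           "Boana_leucocheila",
                                           "Boana_multifasciata"),
                                    "Boana_almendarizae", "Boana_calcarata",
                                    "Boana_cf._lanciformis", "Boana_fasciata",
                                    "Boana_heilprini", "Boana_raniceps",
                                ),
                                "Boana_faber",
                                "Boana_pellucens",
                                _clade("B._punctata_group",
                                       "Boana_cinerascens", "Boana_punctata"),
                                _clade("B._semilineata_group",
                                       "Boana_boans", "Boana_cf._semilineata",
                                       "Boana_geographica", "Boana_pombali",
                                       "Boana_semilineata", "Boana_wavrini"),
                                _clade(
                                    "B._pulchella_group",
                                    _clade("B._polytaenia_semiguttata_clade",
                                           "Boana_cipoensis",
                                           _clade("B._semiguttata_clade",
                                                  "Boana_curupi",
                                                  "Boana_joaquini",
                                                  "Boana_semiguttata",
                                                  "Boana_stellae")),
                                    _clade("B._pulchella_12_clade",
                                           "Boana_caingua", "Boana_prasina",
                                           "Boana_pulchella"),
                                    "Boana_albonigra", "Boana_bischoffi",
                                    "Boana_cordobae", "Boana_marianitae",
                                    "Boana_riojana",
                                ),
                            ),
                        ),
                    ),
                ),
            ),
        ),
    )
    + ";"
)

TAXONOMY = {
    "Aplastodiscus": 15,
    "Boana": 92,
    "Bokermannohyla": 32,
    "Hyloscirtus": 36,
    "Myersiohyla": 6,
}
C_BANDS_KNOWN = {
    "Aplastodiscus": 8,
    "Boana": 33,
    "Bokermannohyla": 9,
    "Hyloscirtus": 3,
}


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)

    karyotypes = [build_karyotype(sp, spec) for sp, spec in STUDIED.items()]
    # the spontaneous triploid specimen: its own record, never merged
    triploid = build_karyotype(
        "Boana pulchella (LGE 11504)", STUDIED["Boana pulchella"], ploidy=3
    )
    write_karyotypes_csv(karyotypes + [triploid], DATA / "karyotype_pairs.csv")

    rows = [
        "species,genus,species_group,studied_here,specimen_level,n_specimens,"
        "techniques,x,nor_pairs_raw,nor_position,c_band_known,caution,source,"
        "provenance"
    ]
    for sp, spec in STUDIED.items():
        k = build_karyotype(sp, spec)
        nor = spec.get("nor")
        rows.append(
            ",".join(
                [
                    f'"{sp}"',
                    spec["genus"],
                    f'"{spec["group"]}"',
                    "1",
                    "0",
                    spec["n"],
                    f'"{spec["tech"]}"',
                    str(k.basic_number_x),
                    str(nor[0]) if nor else "",
                    (nor[2] or "") if nor else "",
                    "1" if "C-bands" in spec["tech"] else "0",
                    "0",
                    "this_study",
                    spec["prov"],
                ]
            )
        )
    rows.append(
        ",".join(
            [
                '"Boana pulchella (LGE 11504)"', "Boana", '"B. pulchella"',
                "1", "1", "1M", '"Ag-NORs;C-bands"', "12", "12", "terminal",
                "1", "0", "this_study", "results:pulchella-group",
            ]
        )
    )
    for sp, genus, group, x, nor_raw, nor_pos, cband, caution, prov in LITERATURE:
        rows.append(
            ",".join(
                [
                    f'"{sp}"', genus, f'"{group}"' if group else "",
                    "0", "0", "", "",
                    str(x) if x is not None else "",
                    nor_raw, nor_pos or "",
                    "1" if cband else "0",
                    "1" if caution else "0",
                    "literature", prov,
                ]
            )
        )
    (DATA / "species.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    rows = ["taxon,genus,x,nor_pairs_raw,provenance"]
    for taxon, genus, x, nor_raw, prov in CONDENSED:
        rows.append(
            ",".join([f'"{taxon}"', genus or "", str(x), nor_raw, prov])
        )
    (DATA / "condensed.csv").write_text("\n".join(rows) + "\n", encoding="utf-8")

    tree = parse_newick(TREE)
    (DATA / "tree.nwk").write_text(write_newick(tree) + "\n", encoding="utf-8")

    (DATA / "registries.json").write_text(
        json.dumps(
            {"taxonomy": TAXONOMY, "c_bands_known": C_BANDS_KNOWN}, indent=2
        )
        + "\n",
        encoding="utf-8",
    )

    # the shipped matrix is exactly what char coding regenerates from the
    # records (a packaging-time consistency guarantee)
    from karyoevo.dataset import load_dataset

    ds = load_dataset()
    write_matrix(ds.matrix, "nexus", DATA / "matrix.nex")
    print(f"wrote dataset: {len(ds.records)} records, "
          f"{len(ds.matrix.taxa)} matrix taxa, "
          f"{len(tree.leaf_labels())} tree leaves")


if __name__ == "__main__":
    main()
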