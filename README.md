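# karyoevo

Karyotype morphometrics and chromosome-character evolution for Neotropical
treefrogs (tribe Cophomantini, Hylidae: Hylinae).

Amphibian cytogenetics describes species by their karyotypes — the diploid
number `2n`, the basic number `x` (one haploid complement, `2n = ploidy·x`),
the fundamental number `FN` (chromosome arms: two per bi-armed chromosome,
one per telocentric), per-pair shape via the centromeric index
`CI = p/(p+q)`, and the chromosome pair bearing the nucleolar organizer
region (NOR). Changes in `x` and in the NOR-bearing pair are rare,
discrete events, which makes them usable as phylogenetic characters: coded
as unordered multistate characters and optimized by parsimony on an
independently estimated tree, they identify synapomorphies — derived
states originating on a clade's stem.

`karyoevo` provides that whole workflow as a tested library:

* **morphometrics** — CI, configurable CI→morphology classification
  (metacentric / submetacentric / subtelocentric / telocentric), relative
  lengths, `FN`, karyotype validation, renderer-agnostic idiogram
  coordinates; a lossless karyotype CSV dialect;
* **character coding** — basic number `x` (states 9–13) and NOR-bearing
  pair under explicit, swappable homology rules (homeologies, private
  states for independent transformations, genus-scoped medium-pair
  collapse, polymorphic multi-state cells); NEXUS / TNT / CSV matrix I/O
  with exact round-trips;
* **parsimony** — Fitch/Hartigan-style unordered parsimony on rooted,
  possibly multifurcating trees: tree length, per-node MPR (most
  parsimonious reconstruction) state sets, branch transformations,
  synapomorphy candidates and ambiguity flags; a brute-force oracle for
  verification;
* **data** — the packaged Cophomantini dataset (28 newly karyotyped
  species, literature records, registry tables, coded matrix, condensed
  tree), transcribed from the main text of the primary cytogenetic
  literature on the tribe;
* **synthetic** — seeded generators for noisy karyotype measurements and
  for character histories evolved on trees, with ground truth.

## Worked example

```python
from karyoevo import (load_dataset, reconstruct, synapomorphies,
                      fundamental_number, classify_morphology)

ds = load_dataset()
alytolylax = next(r for r in ds.records if r.species == "Hyloscirtus alytolylax")
k = alytolylax.karyotype
print(f"{k.species}: 2n = {k.diploid_number_2n}, x = {k.basic_number_x}, "
      f"FN = {fundamental_number(k)}, sex system = {k.sex_system}")
print("CI 0.25 classifies as:", classify_morphology(0.25).name.lower())

for char in ("x", "nor_pair"):
    result = reconstruct(ds.tree, ds.matrix, char)
    report = synapomorphies(result, ds.tree)
    print(f"\ncharacter {char}: tree length {result.length}")
    print("  Hylinae MPR set:", sorted(result.mpr["Hylinae"]))
    for t in report.synapomorphies:
        print(f"  synapomorphy: {t.child} <- state {next(iter(t.to_states))}")
```

prints

```
Hyloscirtus alytolylax: 2n = 20, x = 10, FN = 38, sex system = XY
CI 0.25 classifies as: submetacentric

character x: tree length 6
  Hylinae MPR set: ['12']
  synapomorphy: A. albofrenatus group <- state 11
  synapomorphy: B. albopunctata 2n22 clade <- state 11

character nor_pair: tree length 14
  Hylinae MPR set: ['11']
  synapomorphy: B. semilineata group <- state 7
  synapomorphy: B. albopunctata 2n22 clade <- state 8
  synapomorphy: B. polytaenia semiguttata clade <- state 1
  synapomorphy: B. pulchella 12 clade <- state 12
```

Reading the output: the dwarf-complement species *H. alytolylax*
(2n = 20, with one telocentric pair, hence FN = 38) carries an XX/XY
system; on the condensed tree, a basic number of x = 12 is fixed at the
Hylinae ancestor with reductions to x = 11 inside *Aplastodiscus* and
*Boana*, and the NOR sits ancestrally on pair 11 with clade-specific moves
to pairs 7, 8, 1 and 12. The base of the *A. albofrenatus* group is
flagged ambiguous for the NOR character (`report.ambiguous_nodes`).

## Command line

A thin CLI wraps the same functions:

```sh
karyoevo classify --input karyotypes.csv --out enriched.csv
karyoevo encode   --input karyotypes.csv --out matrix.nex --format nexus
karyoevo optimize --tree tree.nwk --matrix matrix.nex --char x --out report.json
karyoevo simulate --seed 7 --out sim/
karyoevo report
```

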