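# Methods

`karyoevo` implements the comparative-cytogenetics workflow used to study
chromosome evolution in the Neotropical treefrog tribe Cophomantini
(Hylidae: Hylinae): karyotype morphometrics, homology-explicit coding of
cytogenetic characters, and unordered-parsimony ancestral-state
reconstruction on a fixed phylogeny. This note records the models, the
parameters that matter, the numerical choices, and the places where the
design was genuinely open.

## Karyotype model and morphometrics

A karyotype is a list of homologous pairs, each with a short arm `p` and a
long arm `q` (`p <= q` by definition; the reader orients unsorted input and
an input with `p > q` is rejected as a probable transcription error).
Shape is summarized by the centromeric index

    CI = p / (p + q)  in [0, 0.5],

and mapped to the four standard morphology classes. The class bounds are
the CI equivalents of the classical arm-ratio cut-offs 1.7, 3.0 and 7.0
(`CI = 1 / (1 + r)`):

| class | CI range |
|---|---|
| metacentric (m) | [0.37, 0.50] |
| submetacentric (sm) | [0.25, 0.37) |
| subtelocentric (st) | [0.125, 0.25) |
| telocentric (t) | [0, 0.125) |

Boundary values belong to the more metacentric class, so CI 0.25 is
submetacentric ("almost subtelocentric") and 0.37 is metacentric. These
defaults reproduce every CI-to-class pairing printed in the source study
(0.41 and 0.46 metacentric; 0.34, 0.35 and 0.25 submetacentric) and are
configurable (`CIThresholds`).

Derived quantities: `2n = ploidy * x` (with `x` the haploid pair count);
the fundamental number `FN` counts chromosome arms over the somatic
complement, two per bi-armed chromosome and one per telocentric.
Subtelocentrics count as two-armed — the convention is calibrated against
the published values FN = 48 (twelve bi-armed pairs including a
subtelocentric pair 4) and FN = 46 (eleven bi-armed pairs plus a
telocentric pair 12). Relative length is a pair's percent of the haploid
A-complement total; B (supernumerary) chromosomes are excluded from `2n`,
`x`, `FN` and the 100 % normalization, and their size is expressed against
the A-complement total (matching the published "3.11 % of the haploid
set"). Heteromorphic pairs are stored as two half-records on one pair
index; FN counts each homologue separately, and size-based operations use
the homologue mean.

Idiogram output is pure geometry (one bar per pair, split at the
centromere, heights `rel * CI` upward and `rel * (1 - CI)` downward), with
no renderer. Because the packaged dataset carries morphology classes and
prose-printed CIs but not the raw arm measurements (published only as
supplementary material), `idiogram_coords(schematic=True)` fills missing
relative lengths uniformly and missing CIs with class midpoints — the way
published idiograms are drawn from class data; the default mode insists on
real measurements.

## Character coding

Two unordered characters are built:

* **Basic number `x`**, alphabet {9, 10, 11, 12, 13}. Treating `x` as a
  character is an explicit oversimplification (equal counts can arise from
  different rearrangements); it is the assumption that makes optimization
  possible at all, and it is confined to this one coding step.
* **NOR-bearing pair**, via an ordered rule set (`NorHomologyRules`) that
  is data, not code: species-scoped rules beat genus-scoped rules beat
  literal ones, and an observation with no rule is a coding error rather
  than a silent literal state. The default rule set encodes the source
  study's homology hypotheses: *Aplastodiscus* pair 9 is homeologous to the
  cophomantine pair 11; the three conspicuously different pair-4 NORs
  (*Bokermannohyla alvarengai*, *Hyloscirtus alytolylax*, *H. palmeri*) are
  three private states `4a/4b/4c` — on an unordered character, private
  states reproduce "independent transformations" exactly without a step
  matrix; medium-pair observations (6/7) collapse to one state per genus.
  The source is internally torn between listing pair 6 in its state
  alphabet and naming pair 7 in its results; the genus-scoped default
  preserves both readings and a literal reading is a one-rule swap
  (tested). Polymorphic NORs (e.g. pairs 9 and 12 in *Boana prasina*)
  become multi-state cells — cost-free ambiguity under parsimony.

Heterochromatin (C-band/DAPI/CMA3) descriptors are stored verbatim but are
deliberately **not** coded as characters: band homology across species
cannot be established from banding alone.

Matrices serialize to NEXUS, TNT `xread` and CSV. State labels are not
single symbols (`10`, `4a`), so the NEXUS/TNT writers emit a `STATEKEY`
legend mapping labels to symbols; the readers invert it, making every
writer/reader pair an exact round-trip (property-tested on random
matrices, and the NEXUS output is cross-checked as parseable by an
independent library).

## Parsimony reconstruction

The optimization is unordered (Fitch-style) parsimony on a rooted tree
taken as given — no tree search, no likelihood. The implementation is the
unit-cost dynamic program that generalizes the Fitch/Hartigan passes to
multifurcations, missing data and polymorphic tips:

* `down[v][s]`: minimum changes within the subtree of `v` given state `s`
  at `v` (tips: 0 if `s` is observed, else infinite — the change is
  charged to the terminal branch);
* `above[v][s]`: minimum changes outside the subtree given `s` at `v`;
* tree length `L = min_s down[root][s]`; the MPR set of a node is
  `{s : down[v][s] + above[v][s] = L}` — exactly the states attained in at
  least one minimum-change assignment.

Ambiguity is reported as `|MPR| > 1`; no ACCTRAN/DELTRAN choice is imposed
because the downstream claims (synapomorphies, ambiguous nodes) are made at
the MPR-set level. A candidate synapomorphy is a branch whose child MPR
set is a single state absent from the parent's MPR set — a derived state
originating on a clade's stem. Missing tips carry the whole alphabet at
zero cost and provably never increase tree length (property-tested).

Correctness is established against an independent brute-force oracle that
enumerates every internal-node assignment and accumulates minimum-cost
states per node. The oracle is exponential, so it is guarded by an
assignment-count budget (2,000,000); test instances are drawn with at most
6 internal nodes and 4 states, and the implementation/oracle agreement on
length *and* every MPR set is checked on 200+ seeded random instances,
together with state-relabelling invariance and the classical length
bounds.

## The packaged dataset

The dataset transcribes the main text of the primary cytogenetic study of
Cophomantini: per-pair morphology (and every CI printed in prose) for the
28 newly karyotyped species, literature records for taxa the text names,
the technique table, and the registry totals (181 described species;
C-bands known for 53 species: 8 + 33 + 9 + 3). Fields the text does not
print are missing, never inferred — notably raw arm lengths (supplementary
only) and basic numbers of several literature taxa. Where the text
contradicts itself (pair 5 of *Boana boans*: CI 0.35 in the results, 0.36
in the discussion) the results value is used. The triploid *B. pulchella*
specimen is a separate specimen-level record (ploidy 3) excluded from
species tallies. Two literature NOR observations are handled specially:
*B. prasina* is the polymorphic multi-state cell above, and *B. atlantica*
(NORs on pairs 10 and 12) is omitted because pair 10 has no homology rule
in the study's alphabet.

The condensed tree is reconstructed from textual statements only, since
the figure topology is not printed: the tribe backbone
`(Myersiohyla,(Hyloscirtus,(Bokermannohyla,(Aplastodiscus,Boana))))` with
species groups as clades (internally unresolved where the text is silent),
embedded in Hylinae next to condensed terminals for the three other hyline
tribes (modal condition x = 12, NOR pair 11) and the two outgroup
subfamilies (x = 13, NOR unknown). Two resolutions are deliberate package
choices: (i) the clade (*caingua*, *prasina*, *pulchella*) and the
(*polytaenia* + *semiguttata*) clade are resolved inside the
*B. pulchella* group, because the text names them as the bearers of the
NOR-12 and NOR-1 synapomorphies; (ii) within the *A. albofrenatus* group,
*A. arildae* is nested among the medium-pair species,
`(albofrenatus,(arildae,(ehrhardti,eugenioi)))`, which is the published
arrangement that produces the reported ambiguity at the group's base.
Ancestral-state claims are therefore only made (and tested) at nodes the
text itself names.

Registry counts by genus come from the study's own registry sentence; they
are packaged as totals because the species-level registry behind them is
not reproduced in the main text and the dataset does not invent rows.

## Synthetic generators

`simulate_karyotype` draws true pair totals from a log-normal (positive,
right-skewed, like real chromosome size series; defaults: median 5 units,
sigma 0.5, 12 pairs — the modal complement), a true CI uniform on
[0, 0.5] so every morphology class occurs, and applies independent
multiplicative log-normal noise per arm (default sd 0.05, i.e. ~5 %
measurement error, of the order of the arm-measurement scatter reported as
standard deviations in karyotype tables). Pairs are re-ranked by measured
size, as in a real karyogram. At noise 0 the classifier recovers the truth
exactly; with noise, misclassification concentrates where the true CI lies
within about two CI-scale standard deviations
(`sd_CI ≈ sqrt(2) * sd * CI * (1 - CI)`) of a class boundary — both are
tested.

`simulate_character` evolves a state down the tree with a per-branch jump
probability (uniform different state on change). A per-branch probability
is used instead of rate × branch length because condensed cladograms carry
no meaningful branch lengths. The full change history is recorded;
parsimony length can never exceed the realized number of changes, and
`recovery_experiment` summarizes root-state recovery (true root in the
root MPR set), root ambiguity, and mean length against the change
probability. What these simulations do *not* emulate: correlated
rearrangements (fusions changing `x` and NOR position together),
heterochromatin dynamics, or B-chromosome inheritance — conclusions about
those features of real data are outside what a passing test establishes.

## Problem sizes and determinism

Every stochastic component is seeded (`numpy.random.default_rng` /
`random.Random`), and regenerating with the same seed is bit-identical.
The validation suite uses 200 oracle instances (≤ 6 internal nodes, ≤ 4
states), 50 random instances per serialization format, and 60 replicates
per point of the recovery grid — sizes chosen so the whole suite runs in
seconds while the oracle comparisons remain exhaustive.

## Known limitations

* The packaged karyotypes lack arm lengths, so relative-length and
  measurement-based operations can only be exercised on synthetic data.
* The condensed tree is a textual reconstruction; claims at unnamed nodes
  are not meaningful and are not made.
* NOR homology rules are hypotheses; alternative rule files change the
  character and hence the optimization (by design).
* Parsimony is the only reconstruction criterion offered, matching the
  source analysis; no model-based (Mk) estimation is included.
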