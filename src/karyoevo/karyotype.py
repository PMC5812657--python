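"""Karyotype data model and morphometric operations.

A karyotype is described pair by pair: each homologous pair carries a short
arm (p) and a long arm (q), and chromosome shape is summarized by the
centromeric index CI = p / (p + q), which runs from 0 (telocentric, no short
arm) to 0.5 (perfectly metacentric, arms equal).  Derived quantities follow
the conventions of amphibian cytogenetics:

* ``2n``   somatic (diploid) chromosome number,
* ``x``    basic chromosome number, one haploid complement (2n = ploidy * x),
* ``FN``   fundamental number, the count of chromosome arms in the somatic
           complement (bi-armed chromosomes contribute two arms, telocentrics
           one),
* relative length, a pair's share (percent) of the total haploid complement
  length.

Supernumerary (B) chromosomes are dispensable elements outside the standard
A complement; they are excluded from 2n, x, FN, and the 100 % relative-length
normalization, and their size is expressed against the A haploid total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

from .errors import (
    DegenerateInputError,
    IncompleteKaryotypeError,
    InvalidMeasurementError,
)

__all__ = [
    "Morphology",
    "CIThresholds",
    "DEFAULT_THRESHOLDS",
    "NORAnnotation",
    "ChromosomePair",
    "BChromosome",
    "Karyotype",
    "centromeric_index",
    "classify_morphology",
    "fundamental_number",
    "relative_length",
    "validate_karyotype",
    "idiogram_coords",
]


class Morphology(str, Enum):
    """Chromosome morphology classes, from median to terminal centromere."""

    METACENTRIC = "m"
    SUBMETACENTRIC = "sm"
    SUBTELOCENTRIC = "st"
    TELOCENTRIC = "t"

    @property
    def biarmed(self) -> bool:
        """Whether the class contributes two arms to the fundamental number.

        Subtelocentric chromosomes have a short but real p arm and count as
        two-armed; only telocentrics are single-armed.
        """
        return self is not Morphology.TELOCENTRIC


@dataclass(frozen=True)
class CIThresholds:
    """Lower CI bounds of the morphology classes.

    The defaults are the centromeric-index equivalents of the classical
    arm-ratio cut-offs 1.7, 3.0 and 7.0 (CI = 1 / (1 + arm ratio)):
    metacentric CI in [0.37, 0.5], submetacentric [0.25, 0.37),
    subtelocentric [0.125, 0.25), telocentric [0, 0.125).  Boundary values
    belong to the higher (more metacentric) class, so CI 0.25 is
    submetacentric ("almost subtelocentric") and CI 0.37 is metacentric.
    """

    metacentric_min: float = 0.37
    submetacentric_min: float = 0.25
    subtelocentric_min: float = 0.125

    def classify(self, ci: float) -> Morphology:
        if not 0.0 <= ci <= 0.5:
            raise InvalidMeasurementError(
                f"centromeric index {ci!r} outside [0, 0.5]"
            )
        if ci >= self.metacentric_min:
            return Morphology.METACENTRIC
        if ci >= self.submetacentric_min:
            return Morphology.SUBMETACENTRIC
        if ci >= self.subtelocentric_min:
            return Morphology.SUBTELOCENTRIC
        return Morphology.TELOCENTRIC

    def representative_ci(self, morphology: Morphology) -> float:
        """Class midpoint, used for schematic idiograms when no CI is known."""
        bands = {
            Morphology.METACENTRIC: (self.metacentric_min, 0.5),
            Morphology.SUBMETACENTRIC: (self.submetacentric_min, self.metacentric_min),
            Morphology.SUBTELOCENTRIC: (self.subtelocentric_min, self.submetacentric_min),
            Morphology.TELOCENTRIC: (0.0, self.subtelocentric_min),
        }
        lo, hi = bands[morphology]
        return (lo + hi) / 2.0


DEFAULT_THRESHOLDS = CIThresholds()


def centromeric_index(p_len: float, q_len: float) -> float:
    """Centromeric index CI = p / (p + q) of an oriented arm pair.

    The caller must orient arms so that p is the short arm (p <= q);
    unoriented input is an error rather than silently swapped, because a
    p > q measurement usually indicates a transcription mistake.
    """
    if p_len < 0 or q_len <= 0:
        raise InvalidMeasurementError(
            f"arm lengths must satisfy p >= 0 and q > 0, got p={p_len!r}, q={q_len!r}"
        )
    if p_len > q_len:
        raise InvalidMeasurementError(
            f"p must be the short arm (p <= q), got p={p_len!r} > q={q_len!r}"
        )
    return p_len / (p_len + q_len)


def classify_morphology(
    ci: float, thresholds: CIThresholds = DEFAULT_THRESHOLDS
) -> Morphology:
    """Map a centromeric index to its morphology class."""
    return thresholds.classify(ci)


@dataclass(frozen=True)
class NORAnnotation:
    """Location of a nucleolar organizer region on a chromosome pair.

    ``arm`` is "p", "q" or None (unassigned / centromeric); ``position`` is
    "terminal", "interstitial", "centromeric" or None when the source does
    not state it.
    """

    pair_index: int
    arm: str | None = None
    position: str | None = None

    _ARMS = (None, "p", "q")
    _POSITIONS = (None, "terminal", "interstitial", "centromeric")

    def __post_init__(self):
        if self.arm not in self._ARMS:
            raise ValueError(f"NOR arm must be one of {self._ARMS}, got {self.arm!r}")
        if self.position not in self._POSITIONS:
            raise ValueError(
                f"NOR position must be one of {self._POSITIONS}, got {self.position!r}"
            )


@dataclass(frozen=True)
class ChromosomePair:
    """One homologous pair (or, for heteromorphic pairs, one homologue).

    Heteromorphic pairs — e.g. a pair whose two homologues differ in shape —
    are stored as two half-records sharing ``pair_index`` with distinct
    ``homologue`` labels ("A"/"B").  Band annotations are verbatim categorical
    descriptors (arm, position class, stain sign), e.g. ``"q:interstitial:C+"``;
    no cross-species homology of heterochromatic bands is implied.
    """

    pair_index: int
    morphology: Morphology | None = None
    p_len: float | None = None
    q_len: float | None = None
    ci: float | None = None
    rel_length: float | None = None
    homologue: str | None = None
    nor: NORAnnotation | None = None
    bands: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pair_index < 1:
            raise ValueError("pair_index must be >= 1")
        if self.p_len is not None and self.q_len is not None:
            if self.p_len > self.q_len:
                raise InvalidMeasurementError(
                    f"pair {self.pair_index}: p_len {self.p_len} > q_len {self.q_len}"
                )
        if self.ci is not None and not 0.0 <= self.ci <= 0.5:
            raise InvalidMeasurementError(
                f"pair {self.pair_index}: ci {self.ci} outside [0, 0.5]"
            )

    @property
    def total_length(self) -> float | None:
        if self.p_len is None or self.q_len is None:
            return None
        return self.p_len + self.q_len

    def derived(self, thresholds: CIThresholds = DEFAULT_THRESHOLDS) -> "ChromosomePair":
        """Copy with CI (from arm lengths) and morphology (from CI) filled in."""
        ci = self.ci
        if ci is None and self.p_len is not None and self.q_len is not None:
            ci = centromeric_index(self.p_len, self.q_len)
        morphology = self.morphology
        if morphology is None and ci is not None:
            morphology = thresholds.classify(ci)
        return replace(self, ci=ci, morphology=morphology)


@dataclass(frozen=True)
class BChromosome:
    """A supernumerary (B) chromosome, outside the A complement.

    ``rel_length`` is percent of the A-complement haploid length.
    """

    rel_length: float | None = None
    ci: float | None = None
    morphology: Morphology | None = None
    mitotic_stability: bool | None = None

    def __post_init__(self):
        if self.ci is not None and not 0.0 <= self.ci <= 0.5:
            raise InvalidMeasurementError(f"B chromosome ci {self.ci} outside [0, 0.5]")


@dataclass
class Karyotype:
    """A species' (or specimen's) full chromosome complement."""

    species: str
    pairs: list[ChromosomePair]
    group: str | None = None
    ploidy: int = 2
    b_chromosomes: list[BChromosome] = field(default_factory=list)
    sex_system: str | None = None
    source: str = "this_study"
    basic_number_x: int | None = None
    diploid_number_2n: int | None = None

    def __post_init__(self):
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.basic_number_x is None:
            self.basic_number_x = len(self.pair_groups())
        if self.diploid_number_2n is None:
            self.diploid_number_2n = self.ploidy * self.basic_number_x

    def pair_groups(self) -> dict[int, list[ChromosomePair]]:
        """Pairs grouped by pair index, preserving homologue order."""
        groups: dict[int, list[ChromosomePair]] = {}
        for p in self.pairs:
            groups.setdefault(p.pair_index, []).append(p)
        return groups

    def derived(self, thresholds: CIThresholds = DEFAULT_THRESHOLDS) -> "Karyotype":
        """Copy with per-pair CI and morphology derived where absent."""
        return replace(
            self, pairs=[p.derived(thresholds) for p in self.pairs]
        )

    def nor_pairs(self) -> list[NORAnnotation]:
        return [p.nor for p in self.pairs if p.nor is not None]


def fundamental_number(karyotype: Karyotype) -> int:
    """Fundamental number FN: total chromosome arms in the somatic complement.

    Bi-armed chromosomes (metacentric, submetacentric, subtelocentric) count
    two arms, telocentrics one.  Counts run over chromosomes, i.e. pairs
    multiplied by ploidy; B chromosomes are excluded.  Heteromorphic pairs
    stored as half-records contribute per homologue.
    """
    fn = 0
    for idx, recs in karyotype.pair_groups().items():
        if karyotype.ploidy % len(recs) != 0:
            raise IncompleteKaryotypeError(
                f"{karyotype.species}: pair {idx} has {len(recs)} homologue records, "
                f"incompatible with ploidy {karyotype.ploidy}"
            )
        copies = karyotype.ploidy // len(recs)
        for rec in recs:
            if rec.morphology is None:
                raise IncompleteKaryotypeError(
                    f"{karyotype.species}: pair {idx} lacks a morphology class"
                )
            fn += copies * (2 if rec.morphology.biarmed else 1)
    return fn


def _haploid_total_length(karyotype: Karyotype) -> float:
    total = 0.0
    for idx, recs in karyotype.pair_groups().items():
        lengths = [r.total_length for r in recs]
        if any(l is None for l in lengths):
            raise IncompleteKaryotypeError(
                f"{karyotype.species}: pair {idx} lacks arm lengths"
            )
        total += sum(lengths) / len(lengths)  # heteromorphic pairs: mean of homologues
    return total


def relative_length(pair, karyotype: Karyotype) -> float:
    """Percent of the haploid A-complement length taken by ``pair``.

    ``pair`` may be a :class:`ChromosomePair` or any object with ``p_len`` and
    ``q_len``; the denominator is always the A-complement haploid sum, so a
    B chromosome's size is expressed against the A total.
    """
    if pair.p_len is None or pair.q_len is None:
        raise IncompleteKaryotypeError("pair lacks arm lengths")
    denom = _haploid_total_length(karyotype)
    if denom <= 0:
        raise DegenerateInputError(
            f"{karyotype.species}: zero-length haploid complement"
        )
    return 100.0 * (pair.p_len + pair.q_len) / denom


REL_LENGTH_TOL = 1e-9


def validate_karyotype(
    karyotype: Karyotype, thresholds: CIThresholds = DEFAULT_THRESHOLDS
) -> list[str]:
    """Check every karyotype invariant; return violations (empty iff valid).

    Reports, never raises: each violation names the field and the invariant
    it breaks.  Fields that are absent (None) are not violations — only
    inconsistent present values are.
    """
    v: list[str] = []
    k = karyotype
    groups = k.pair_groups()

    if k.basic_number_x != len(groups):
        v.append(
            f"basic_number_x: declared x={k.basic_number_x} but karyotype has "
            f"{len(groups)} pairs"
        )
    if k.diploid_number_2n != k.ploidy * k.basic_number_x:
        v.append(
            f"diploid_number_2n: 2n={k.diploid_number_2n} != ploidy*x="
            f"{k.ploidy * k.basic_number_x}"
        )
    for idx, recs in groups.items():
        for rec in recs:
            if rec.ci is not None and rec.morphology is not None:
                expected = thresholds.classify(rec.ci)
                if expected is not rec.morphology:
                    v.append(
                        f"pairs[{idx}].morphology: {rec.morphology.value} inconsistent "
                        f"with ci={rec.ci} (classifier says {expected.value})"
                    )
            if (
                rec.ci is not None
                and rec.p_len is not None
                and rec.q_len is not None
            ):
                ci = centromeric_index(rec.p_len, rec.q_len)
                if not math.isclose(ci, rec.ci, abs_tol=1e-9):
                    v.append(
                        f"pairs[{idx}].ci: stored ci={rec.ci} != p/(p+q)={ci}"
                    )
            if rec.rel_length is not None and rec.rel_length <= 0:
                v.append(f"pairs[{idx}].rel_length: must be > 0")
    rels = [
        sum(r.rel_length for r in recs) / len(recs)
        for recs in groups.values()
        if all(r.rel_length is not None for r in recs)
    ]
    if len(rels) == len(groups) and groups:
        total = sum(rels)
        if not math.isclose(total, 100.0, abs_tol=1e-6):
            v.append(
                f"pairs.rel_length: haploid complement sums to {total}, expected 100"
            )
    try:
        fn = fundamental_number(k)
        two_n = k.ploidy * len(groups)
        if not two_n <= fn <= 2 * two_n:
            v.append(f"fundamental_number: FN={fn} outside [2n, 2*2n]=[{two_n}, {2*two_n}]")
    except IncompleteKaryotypeError:
        pass  # missing morphologies are not a violation, just incomplete
    return v


def idiogram_coords(
    karyotype: Karyotype,
    thresholds: CIThresholds = DEFAULT_THRESHOLDS,
    schematic: bool = False,
    width: float = 0.6,
    spacing: float = 1.0,
):
    """Renderer-agnostic idiogram geometry for one haploid set.

    Each pair becomes a vertical bar split at the centromere (y = 0): the p
    arm extends upward with height ``rel_length * ci`` and the q arm downward
    with height ``rel_length * (1 - ci)``, so the two segment heights sum to
    the pair's relative length and a haploid set sums to 100.  Telocentric
    pairs (ci = 0) yield a single q segment.  NOR and band annotations are
    emitted as overlay rows sharing the arm's rectangle.

    With ``schematic=True``, missing relative lengths are filled uniformly
    (100 / x) and missing CIs with the class-representative midpoint, which
    is how published idiograms are drawn when only morphology classes are
    known.  Otherwise missing values raise an incomplete-karyotype error.

    Returns a :class:`pandas.DataFrame` with columns
    ``pair_index, segment, x0, y0, x1, y1, annotation``.
    """
    import pandas as pd

    groups = karyotype.pair_groups()
    n = len(groups)
    rows = []
    for col, (idx, recs) in enumerate(sorted(groups.items())):
        rec = recs[0].derived(thresholds)  # draw the first (modal) homologue
        rel = rec.rel_length
        ci = rec.ci
        if rel is None:
            if not schematic:
                raise IncompleteKaryotypeError(
                    f"{karyotype.species}: pair {idx} lacks rel_length "
                    "(use schematic=True for a uniform layout)"
                )
            rel = 100.0 / n
        if ci is None:
            if rec.morphology is None or not schematic:
                raise IncompleteKaryotypeError(
                    f"{karyotype.species}: pair {idx} lacks ci"
                )
            ci = thresholds.representative_ci(rec.morphology)
        x0 = col * spacing
        x1 = x0 + width
        p_h = rel * ci
        q_h = rel * (1.0 - ci)
        if p_h > 0:
            rows.append((idx, "p", x0, 0.0, x1, p_h, ""))
        rows.append((idx, "q", x0, -q_h, x1, 0.0, ""))
        if rec.nor is not None:
            arm = rec.nor.arm or "q"
            y0, y1 = (0.0, p_h) if arm == "p" else (-q_h, 0.0)
            rows.append(
                (idx, f"nor:{arm}", x0, y0, x1, y1, rec.nor.position or "nor")
            )
        for band in rec.bands:
            arm = band.split(":", 1)[0] if ":" in band else "q"
            y0, y1 = (0.0, p_h) if arm == "p" else (-q_h, 0.0)
            rows.append((idx, f"band:{arm}", x0, y0, x1, y1, band))
    return pd.DataFrame(
        rows,
        columns=["pair_index", "segment", "x0", "y0", "x1", "y1", "annotation"],
    )
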