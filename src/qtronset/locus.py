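"""Model of the TCERG1 exon-4 hexanucleotide repeat locus.

The locus is a 38-unit quasi-tandem repeat (QTR) of hexamers on chr5
(hg19 145,838,546-145,838,773) whose central portion is a perfect short
tandem repeat (STR) of (CAGGCC)_n.  Each hexamer encodes a
glutamine/alanine (QA) dipeptide, with occasional valine interruptions.
This module declares the locus, the eight-allele inventory observed in
sequenced Huntington's disease cohorts, and sequence constructors shared
by the genotype caller (as reference/truth) and the read simulator.

External genomic coordinates are 1-based inclusive; everything internal
is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq

UNIT = "CAGGCC"
UNIT_LEN = 6

#: hg19 coordinates of the reference QTR tract (1-based inclusive).
TCERG1_CHROM = "chr5"
TCERG1_START = 145_838_546
TCERG1_END = 145_838_773
GENOME_BUILD = "hg19"

REF_QTR_UNITS = 38
REF_STR_UNITS = 6
#: unit index (0-based) of the first pure-STR unit within the tract
STR_OFFSET = 16

# Non-STR units are imperfect QA-coding hexamers; two valine units mimic
# the interruptions seen in the translated repeat.  The exact variant-unit
# layout of the genomic tract is not machine-readable, so this synthetic
# layout is a documented stand-in with the correct unit-level structure.
# The variant units are drawn aperiodically (fixed seed) from the twelve
# QA/VA-coding hexamers: a periodic layout would make the tract
# self-similar under unit shifts, which a real quasi-tandem repeat is not.
_VALINE_POSITIONS = (5, 30)
_A6_UNIT_INDEX = 2
#: variant unit used when an allele gains a non-STR unit (A8-type)
_VARIANT_INSERT = "CAGGCT"


def reference_unit_count(start: int, end: int, unit_length: int = UNIT_LEN) -> int:
    """Number of repeat units in a 1-based inclusive coordinate span.

    Raises ``ValueError`` when the span is empty or not a whole number
    of units (a malformed locus definition).
    """
    if end < start:
        raise ValueError(f"empty span: end {end} < start {start}")
    if unit_length < 1:
        raise ValueError("unit_length must be >= 1")
    span = end - start + 1
    if span % unit_length:
        raise ValueError(
            f"span of {span} bp is not divisible by unit length {unit_length}; "
            "malformed locus definition"
        )
    return span // unit_length


def _make_reference_units() -> tuple[str, ...]:
    rng = np.random.default_rng(20220905)
    gln = ("CAG", "CAA")
    ala = ("GCC", "GCT", "GCA", "GCG")
    units = []
    for i in range(REF_QTR_UNITS):
        if STR_OFFSET <= i < STR_OFFSET + REF_STR_UNITS:
            units.append(UNIT)
            continue
        first = "GTG" if i in _VALINE_POSITIONS else gln[rng.integers(2)]
        second = ala[rng.integers(4)]
        while first + second == UNIT:
            second = ala[rng.integers(4)]
        units.append(first + second)
    # pin the unit carrying the default A6 synonymous SNV (GCA -> GCG)
    units[_A6_UNIT_INDEX] = "CAGGCA"
    return tuple(units)


_REFERENCE_UNITS = _make_reference_units()


def reference_units() -> list[str]:
    """The 38 hexamer units of the reference (A1) tract."""
    return list(_REFERENCE_UNITS)


def _synthetic_flank(length: int, seed: int) -> str:
    """Deterministic non-repetitive flank free of the repeat unit."""
    rng = np.random.default_rng(seed)
    while True:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if UNIT not in seq:
            return seq


@dataclass(frozen=True)
class RepeatLocus:
    """A declared repeat locus with its reference tract structure."""

    chromosome: str = TCERG1_CHROM
    start: int = TCERG1_START  # 1-based inclusive
    end: int = TCERG1_END
    build: str = GENOME_BUILD
    unit: str = UNIT
    qtr_units: int = REF_QTR_UNITS
    str_units: int = REF_STR_UNITS
    str_offset: int = STR_OFFSET
    left_flank: str = field(default_factory=lambda: _synthetic_flank(150, 145838546))
    right_flank: str = field(default_factory=lambda: _synthetic_flank(150, 145838773))

    def __post_init__(self) -> None:
        if set(self.unit) - set("ACGT"):
            raise ValueError(f"unit {self.unit!r} contains non-ACGT bases")
        if reference_unit_count(self.start, self.end, len(self.unit)) != self.qtr_units:
            raise ValueError(
                "coordinate span does not match qtr_units x unit length"
            )
        if self.str_units > self.qtr_units:
            raise ValueError("str_units cannot exceed qtr_units")
        if not 0 <= self.str_offset <= self.qtr_units - self.str_units:
            raise ValueError("pure-STR run must lie inside the QTR tract")

    @property
    def tract_length(self) -> int:
        return self.qtr_units * len(self.unit)

    def reference_tract(self) -> str:
        return "".join(reference_units())

    def reference_window(self) -> str:
        """flank + tract + flank, the frame all alignment happens in."""
        return self.left_flank + self.reference_tract() + self.right_flank

    @property
    def tract_start(self) -> int:
        """0-based start of the tract within the reference window."""
        return len(self.left_flank)

    @property
    def tract_end(self) -> int:
        return len(self.left_flank) + self.tract_length


@dataclass(frozen=True)
class AlleleSpec:
    """One allele of the repeat inventory, described at unit resolution.

    ``substitutions`` lists (offset-within-tract, alternate base) pairs for
    same-length sequence variants (e.g. the synonymous SNV of allele A6).
    """

    name: str
    qtr_units: int
    str_units: int
    substitutions: tuple[tuple[int, str], ...] = ()

    @property
    def delta_qtr(self) -> int:
        return self.qtr_units - REF_QTR_UNITS

    @property
    def delta_str(self) -> int:
        return self.str_units - REF_STR_UNITS


#: Built-in eight-allele inventory.  QTR/STR unit counts and population
#: frequencies follow the sequenced HD cohort inventory; A6 differs from
#: the reference only by a synonymous third-codon-position SNV whose
#: default placement (tract offset 17, A->G in unit 2, GCA->GCG, both Ala)
#: is a configurable stand-in.
ALLELES: dict[str, AlleleSpec] = {
    "A1": AlleleSpec("A1", 38, 6),
    "A2": AlleleSpec("A2", 35, 3),
    "A3": AlleleSpec("A3", 36, 4),
    "A4": AlleleSpec("A4", 40, 8),
    "A5": AlleleSpec("A5", 34, 4),
    "A6": AlleleSpec("A6", 38, 6, substitutions=((17, "G"),)),
    "A7": AlleleSpec("A7", 39, 7),
    "A8": AlleleSpec("A8", 39, 6),
}

#: Allele frequencies (%) from the sequenced cohort, renormalised on use.
ALLELE_FREQ_PCT: dict[str, float] = {
    "A1": 91.31,
    "A2": 4.10,
    "A3": 2.30,
    "A4": 1.97,
    "A5": 0.08,
    "A6": 0.08,
    "A7": 0.08,
    "A8": 0.08,
}


def allele_frequencies() -> dict[str, float]:
    """Inventory frequencies renormalised to sum to one."""
    total = sum(ALLELE_FREQ_PCT.values())
    return {k: v / total for k, v in ALLELE_FREQ_PCT.items()}


def build_allele_tract(spec: AlleleSpec, locus: RepeatLocus | None = None) -> str:
    """Construct the tract sequence of an allele.

    STR-length changes add or remove copies of the pure unit at the left
    edge of the central run (the leftmost equivalent placement of a repeat
    indel).  QTR-length changes beyond the STR change add or remove
    variant units immediately 3' of the run, so the pure-run length is
    unaffected.  Substitutions are applied last, at tract offsets.
    """
    locus = locus or RepeatLocus()
    units = reference_units()
    d_str = spec.str_units - locus.str_units
    d_var = spec.delta_qtr - d_str
    run_start = locus.str_offset
    run_end = locus.str_offset + locus.str_units
    if d_str >= 0:
        units[run_start:run_start] = [UNIT] * d_str
    else:
        if -d_str > locus.str_units:
            raise ValueError(f"{spec.name}: cannot delete more STR units than exist")
        del units[run_start : run_start - d_str]
    run_end += d_str
    if d_var >= 0:
        units[run_end:run_end] = [_VARIANT_INSERT] * d_var
    else:
        after_run = len(units) - run_end
        if -d_var > after_run:
            raise ValueError(f"{spec.name}: cannot delete {-d_var} variant units")
        del units[run_end : run_end - d_var]
    tract = list("".join(units))
    for offset, base in spec.substitutions:
        if not 0 <= offset < len(tract):
            raise ValueError(
                f"{spec.name}: substitution offset {offset} outside tract "
                f"of length {len(tract)}"
            )
        if base not in "ACGT":
            raise ValueError(f"{spec.name}: invalid substitution base {base!r}")
        tract[offset] = base
    out = "".join(tract)
    if len(out) != spec.qtr_units * UNIT_LEN:
        raise AssertionError("tract length inconsistent with allele spec")
    return out


def build_allele_sequence(spec: AlleleSpec, locus: RepeatLocus | None = None) -> str:
    """flank + allele tract + flank (the allele's locus window)."""
    locus = locus or RepeatLocus()
    return locus.left_flank + build_allele_tract(spec, locus) + locus.right_flank


def longest_pure_run_units(tract: str, unit: str = UNIT) -> int:
    """Length (in units) of the longest perfect run of ``unit`` in ``tract``."""
    best = run = 0
    pos = 0
    k = len(unit)
    while pos + k <= len(tract):
        if tract[pos : pos + k] == unit:
            run += 1
            best = max(best, run)
            pos += k
        else:
            run = 0
            pos += 1
    return best


@dataclass(frozen=True)
class TractProtein:
    protein: str
    dipeptide_units: int


def translate_tract(tract: str, frame_offset: int = 0) -> TractProtein:
    """Translate the in-frame tract; hexamers encode QA-type dipeptides.

    A stop codon inside the tract raises ``ValueError`` (flagged, never
    silently dropped).
    """
    if len(tract) - frame_offset < 3:
        raise ValueError("tract too short to translate at this frame offset")
    inframe = tract[frame_offset:]
    inframe = inframe[: len(inframe) - len(inframe) % 3]
    protein = str(Seq(inframe).translate())
    if "*" in protein:
        raise ValueError(
            f"stop codon at residue {protein.index('*')} inside repeat tract"
        )
    return TractProtein(protein, len(inframe) // UNIT_LEN)
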