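"""Diploid QTR/STR genotype calling from locus-localised short reads.

The caller runs the enumerate-then-realign procedure:

1.  align every read to the reference window and drop reads with a bad
    mismatch error;
2.  collect the left-normalised indel signatures observed in single-read
    alignments and enumerate candidate haplotypes (reference plus every
    observed signature and their compatible combinations);
3.  realign each read to all candidates and keep the one with the
    smallest mismatch error (ties resolve to the reference, then to the
    smaller indel);
4.  resolve remaining ties using the read's mate;
5.  build an asterisk-padded multiple alignment in a single expanded
    reference frame, so indels become substitutions;
6.  split reads into two groups that agree at every discordant column,
    and call one allele per group (two groups: heterozygote; otherwise
    homozygote);
7.  optionally re-call each sample with candidate haplotypes confirmed
    in other samples.

Because a 75 bp read cannot span the 228 bp tract, repeat-length
evidence comes entirely from flank-anchored indel signatures; reads
without a unique flank anchor count towards depth but never towards
length calling.
"""

from __future__ import annotations

import itertools
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field

from . import align as _al
from . import locus as _loc
from .align import AlignmentPath, MatchPiece, find_min_error_path
from .locus import ALLELES, RepeatLocus, build_allele_tract, longest_pure_run_units

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "LocusRead",
    "CandidateHaplotype",
    "PaddedAlignment",
    "AlleleCall",
    "Genotype",
    "LowDepthError",
    "MultiallelicError",
    "enumerate_candidates",
    "realign_and_select",
    "mate_pair_correct",
    "build_padded_alignment",
    "separate_alleles",
    "call_genotype",
    "call_cohort",
    "cross_sample_correct",
]


class LowDepthError(RuntimeError):
    """Raised when informative depth is below the callable minimum."""


class MultiallelicError(RuntimeError):
    """Raised when three or more well-supported incompatible read classes exist."""


@dataclass(frozen=True)
class CallerConfig:
    seed_len: int = _al.DEFAULT_SEED_LEN
    max_gaps: int = 2
    m_max: float = 5.0          # step-(ii) alignment-score filter
    min_anchor: int = 20        # bp of unique flank needed to be informative
    min_support: int = 3        # reads per allele group
    min_depth: int = 10         # mean fold-coverage over the tract
    two_gap_trigger: float = 1.25
    max_gap_penalty: float = 1e-4
    max_candidates: int = 64


@dataclass(frozen=True)
class LocusRead:
    """A read localised to the locus window (forward-strand sequence).

    ``pos`` is an optional 0-based position hint within the source
    haplotype/window (used for SAM export; the caller realigns anyway).
    """

    name: str
    seq: str
    mate: int = 1
    sample: str = ""
    pos: int = -1


@dataclass(frozen=True)
class CandidateHaplotype:
    name: str
    sequence: str
    signature: tuple  # ((ref_pos, signed_delta, inserted_seq), ...)
    source: tuple[str, ...] = ()

    @property
    def indel_magnitude(self) -> int:
        return sum(abs(d) for _, d, _ in self.signature)


@dataclass
class ReadAssignment:
    read: LocusRead
    candidate: int                  # index into the candidate list
    path: AlignmentPath
    ties: tuple[int, ...]           # all candidates achieving the minimal M
    anchored: bool
    tie_paths: dict = field(default_factory=dict)  # candidate -> path, for ties
    conflict: bool = False
    resolved_by_mate: bool = False
    equivalent_ties: bool = False   # tied placements project identically

    @property
    def informative(self) -> bool:
        # uniquely placed among candidates: the imperfect (variant) units of
        # the QTR anchor mid-tract reads just as well as the flanks do, so
        # uniqueness of the minimal-M candidate is the informativeness test.
        # Ties between candidates that are identical over the read's span
        # (detected at padding time) are not real ambiguity.
        return not self.conflict and (
            len(self.ties) == 1 or self.equivalent_ties
        )


@dataclass
class PaddedAlignment:
    """Multiple alignment in a single expanded-reference frame.

    Insertion columns carry ``*`` in the expanded reference; reads show
    ``*`` where they lack a base within their aligned span and ``.``
    outside it.  Removing ``*``/``.`` from any row reproduces the read.
    """

    columns: list[tuple[str, int, int]]   # (kind "R"|"I", ref_pos, slot)
    expanded_reference: str
    rows: list[tuple[str, str]]           # (read name, row string)
    row_assignments: list[ReadAssignment]

    def depad_row(self, i: int) -> str:
        return self.rows[i][1].replace("*", "").replace(".", "")


@dataclass(frozen=True)
class AlleleCall:
    sequence: str       # tract sequence
    qtr_units: int
    str_units: int
    support: int
    matched_spec: str | None
    signature: tuple = ()


@dataclass(frozen=True)
class Genotype:
    allele_a: AlleleCall    # shorter-or-equal QTR
    allele_b: AlleleCall
    zygosity: str           # "hom" | "het"
    depth: int
    qc_flags: tuple[str, ...] = ()

    @property
    def n_min(self) -> int:
        return self.allele_a.qtr_units

    @property
    def n_max(self) -> int:
        return self.allele_b.qtr_units

    @property
    def n_sum(self) -> int:
        return self.n_min + self.n_max

    @property
    def n_diff(self) -> int:
        return self.n_max - self.n_min


# ----------------------------------------------------------------------
# candidate enumeration
# ----------------------------------------------------------------------

def apply_signature(window: str, signature: tuple) -> str:
    """Apply indel events (sorted, non-overlapping) to the window."""
    seq = window
    for pos, delta, ins in sorted(signature, reverse=True):
        if delta < 0:
            seq = seq[:pos] + seq[pos - delta :]
        else:
            seq = seq[:pos] + ins + seq[pos:]
    return seq


def _events_compatible(sig: tuple) -> bool:
    spans = []
    for pos, delta, _ in sig:
        spans.append((pos, pos - delta) if delta < 0 else (pos, pos))
    spans.sort()
    for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
        if b0 < a1 or (b0 == a0):
            return False
    return True


def enumerate_candidates(
    read_paths: list[tuple[LocusRead, AlignmentPath]],
    locus: RepeatLocus,
    config: CallerConfig = CallerConfig(),
    extra_signatures: tuple = (),
) -> list[CandidateHaplotype]:
    """Reference plus haplotypes from observed indel-signature combinations."""
    window = locus.reference_window()
    sources: dict[tuple, set[str]] = defaultdict(set)
    for read, path in read_paths:
        sig = path.indel_signature(window, read.seq)
        if sig:
            sources[sig].add(read.name)
    for sig in extra_signatures:
        if sig:
            sources[tuple(sig)].add("<cross-sample>")
    if not sources and not extra_signatures:
        logger.warning("no indel signatures observed; reference-only candidate set")
    # atomic events observed anywhere, for building combinations
    events = sorted({ev for sig in sources for ev in sig})
    combos: set[tuple] = set(sources)
    for r in range(2, len(events) + 1):
        if len(combos) >= config.max_candidates:
            break
        for combo in itertools.combinations(events, r):
            if _events_compatible(combo):
                combos.add(tuple(sorted(combo)))
            if len(combos) >= config.max_candidates:
                break
    candidates = [CandidateHaplotype("REF", window, ())]
    seen = {window}
    for sig in sorted(combos, key=lambda s: (sum(abs(d) for _, d, _ in s), s)):
        seq = apply_signature(window, sig)
        if seq in seen:
            continue
        seen.add(seq)
        candidates.append(
            CandidateHaplotype(
                f"H{len(candidates)}", seq, tuple(sorted(sig)),
                tuple(sorted(sources.get(sig, ()))),
            )
        )
    return candidates


# ----------------------------------------------------------------------
# realignment and mate correction
# ----------------------------------------------------------------------

def _flank_anchor(path: AlignmentPath, cand_len: int, locus: RepeatLocus) -> int:
    """bp of unique flank covered by the aligned pieces (max of the two sides)."""
    left_end = len(locus.left_flank)
    right_start = cand_len - len(locus.right_flank)
    left = right = 0
    for p in path.pieces:
        left += max(0, min(p.ref_end, left_end) - max(p.ref_start, 0))
        right += max(0, min(p.ref_end, cand_len) - max(p.ref_start, right_start))
    return max(left, right)


def _shifted_reuse(
    refp: AlignmentPath, signature: tuple
) -> AlignmentPath | None:
    """Reuse a perfect reference path on a candidate the read never touches.

    Valid only for M == 0 paths whose reference span avoids every indel
    event of the candidate; the pieces are then identical up to the
    cumulative coordinate shift of events lying left of the span.
    """
    if refp.M != 0 or not refp.pieces:
        return None
    s = min(p.ref_start for p in refp.pieces)
    e = max(p.ref_end for p in refp.pieces)
    shift = 0
    for pos, d, _ in signature:
        if d < 0:
            if not (e <= pos or s >= pos - d):
                return None
            if pos - d <= s:
                shift += d
        else:
            if not (e <= pos or s >= pos):
                return None
            if pos <= s:
                shift += d
    pieces = tuple(
        MatchPiece(p.read_start, p.read_end, p.ref_start + shift)
        for p in refp.pieces
    )
    return AlignmentPath(pieces, refp.gaps, refp.m)


def realign_and_select(
    reads: list[LocusRead],
    candidates: list[CandidateHaplotype],
    locus: RepeatLocus,
    config: CallerConfig = CallerConfig(),
    reference_paths: dict[tuple[str, int], AlignmentPath] | None = None,
) -> list[ReadAssignment]:
    """Assign each read to the candidate minimising its mismatch error.

    Ties resolve to the reference, then to the smaller indel signature;
    the full tie set is kept so mates and grouping can use it.
    ``reference_paths`` (keyed by (read name, mate)) lets perfect
    reference alignments be reused on candidates whose indels the read
    never overlaps.
    """
    if not candidates:
        raise ValueError("need at least one candidate haplotype")
    order = sorted(
        range(len(candidates)),
        key=lambda i: (i != 0, candidates[i].indel_magnitude, i),
    )
    out = []
    for read in reads:
        refp = (
            reference_paths.get((read.name, read.mate))
            if reference_paths
            else None
        )
        best: dict[int, AlignmentPath] = {}
        for i, cand in enumerate(candidates):
            path = None
            if refp is not None:
                if i == 0:
                    path = refp
                else:
                    path = _shifted_reuse(refp, cand.signature)
            if path is None:
                path = find_min_error_path(
                    read.seq, cand.sequence, config.max_gaps,
                    seed_len=config.seed_len,
                    two_gap_trigger=config.two_gap_trigger,
                    max_gap_penalty=config.max_gap_penalty,
                )
            if path is not None:
                best[i] = path
        if not best:
            logger.debug("read %s unalignable against all candidates", read.name)
            continue
        # exact comparison: a well-anchored repeat indel penalises the wrong
        # haplotype by only ~1e-13, which must still break the tie
        min_m = min(p.M for p in best.values())
        ties = tuple(i for i in sorted(best) if best[i].M == min_m)
        chosen = next(i for i in order if i in ties)
        path = best[chosen]
        anchored = _flank_anchor(
            path, len(candidates[chosen].sequence), locus
        ) >= config.min_anchor
        out.append(
            ReadAssignment(
                read, chosen, path, ties, anchored,
                tie_paths={i: best[i] for i in ties},
            )
        )
    return out


def mate_pair_correct(assignments: list[ReadAssignment]) -> list[ReadAssignment]:
    """Resolve tied reads using their informative mates; flag conflicts."""
    by_name: dict[str, list[ReadAssignment]] = defaultdict(list)
    for a in assignments:
        by_name[a.read.name].append(a)
    for pair in by_name.values():
        if len(pair) != 2:
            continue
        a, b = pair
        if a.informative and b.informative:
            if a.candidate != b.candidate:
                a.conflict = b.conflict = True
        else:
            for inf, tied in ((a, b), (b, a)):
                if inf.informative and len(tied.ties) > 1 and inf.candidate in tied.ties:
                    tied.candidate = inf.candidate
                    tied.path = tied.tie_paths[inf.candidate]
                    tied.ties = (inf.candidate,)
                    tied.resolved_by_mate = True
    return assignments


# ----------------------------------------------------------------------
# padded multiple alignment
# ----------------------------------------------------------------------

def _candidate_col_map(
    columns: list[tuple[str, int, int]], signature: tuple
) -> list[int]:
    """Column index of every candidate-haplotype position."""
    deleted = []
    ins_at: dict[int, int] = {}
    for pos, delta, ins in signature:
        if delta < 0:
            deleted.append((pos, pos - delta))
        else:
            ins_at[pos] = len(ins)
    cmap = []
    for ci, (kind, pos, slot) in enumerate(columns):
        if kind == "R":
            if not any(a <= pos < b for a, b in deleted):
                cmap.append(ci)
        elif slot < ins_at.get(pos, 0):
            cmap.append(ci)
    return cmap


def build_padded_alignment(
    assignments: list[ReadAssignment],
    candidates: list[CandidateHaplotype],
    locus: RepeatLocus,
) -> PaddedAlignment:
    """Project all realigned reads into one asterisk-expanded frame."""
    window = locus.reference_window()
    ins_cols: dict[int, int] = defaultdict(int)
    for cand in candidates:
        for pos, delta, ins in cand.signature:
            if delta > 0:
                ins_cols[pos] = max(ins_cols[pos], len(ins))
    columns: list[tuple[str, int, int]] = []
    for pos in range(len(window) + 1):
        for slot in range(ins_cols.get(pos, 0)):
            columns.append(("I", pos, slot))
        if pos < len(window):
            columns.append(("R", pos, 0))
    expanded_ref = "".join(
        "*" if kind == "I" else window[pos] for kind, pos, _ in columns
    )
    cmaps = {
        i: _candidate_col_map(columns, cand.signature)
        for i, cand in enumerate(candidates)
    }
    for i, cand in enumerate(candidates):
        if len(cmaps[i]) != len(cand.sequence):
            raise RuntimeError(
                f"inconsistent insertion columns for candidate {cand.name}"
            )
    rows, row_assignments = [], []
    for a in assignments:
        if a.conflict:
            continue
        row = _project_row(a.path, cmaps[a.candidate], a.read.seq, len(columns))
        if row is None:
            continue
        if len(a.ties) > 1:
            # a tie is harmless when every tied candidate projects the read
            # onto exactly the same columns (the candidates only differ
            # outside the read's span)
            proj = {
                _project_row(p, cmaps[i], a.read.seq, len(columns))
                for i, p in a.tie_paths.items()
            }
            if len(proj) == 1 and None not in proj:
                a.equivalent_ties = True
        rows.append((a.read.name, row))
        row_assignments.append(a)
    return PaddedAlignment(columns, expanded_ref, rows, row_assignments)


def _project_row(
    path: AlignmentPath, cmap: list[int], read_seq: str, ncols: int
) -> str | None:
    """Project one read's alignment into the expanded-column frame."""
    if any(g.kind == "insertion" for g in path.gaps):
        return None  # residual insertion vs its candidate: not representable
    row = ["."] * ncols
    cols_used = []
    for piece in path.pieces:
        for k in range(piece.length):
            cpos = piece.ref_start + k
            if not 0 <= cpos < len(cmap):
                return None
            col = cmap[cpos]
            row[col] = read_seq[piece.read_start + k]
            cols_used.append(col)
    if not cols_used:
        return None
    lo, hi = min(cols_used), max(cols_used)
    for c in range(lo, hi + 1):
        if row[c] == ".":
            row[c] = "*"
    return "".join(row)


# ----------------------------------------------------------------------
# allele separation and consensus
# ----------------------------------------------------------------------

def discordant_columns(
    padded: PaddedAlignment, eligible: list[int], min_support: int = 1
) -> list[int]:
    """Columns where reads disagree with the expanded reference.

    With ``min_support`` > 1, a column only counts when at least that
    many reads share the *same* alternative character there; isolated
    sequencing errors are thereby excluded from allele separation.
    """
    alt: dict[tuple[int, str], int] = defaultdict(int)
    for i in eligible:
        row = padded.rows[i][1]
        for c, ch in enumerate(row):
            if ch not in (".", padded.expanded_reference[c]):
                alt[(c, ch)] += 1
    return sorted({c for (c, _), k in alt.items() if k >= min_support})


def separate_alleles(
    padded: PaddedAlignment,
    min_support: int,
    return_groups: bool = False,
):
    """Greedy bipartition of informative reads over discordant columns.

    Reads within a group agree at every discordant column both cover.
    Returns one or two read-index groups (homozygote / heterozygote);
    three or more groups above ``min_support`` raise
    ``MultiallelicError``.
    """
    eligible = [
        i for i, a in enumerate(padded.row_assignments)
        if a.informative or a.resolved_by_mate
    ]
    cols = discordant_columns(padded, eligible, min_support)
    row_profiles = {}
    for i in eligible:
        row = padded.rows[i][1]
        row_profiles[i] = {c: row[c] for c in cols if row[c] != "."}
    # grouping operates on fragments: a mate pair is one molecule, and it is
    # what links discordant regions further apart than a read length
    frag_rows: dict[str, list[int]] = defaultdict(list)
    for i in eligible:
        frag_rows[padded.rows[i][0]].append(i)
    fragments = []
    for name, idxs in frag_rows.items():
        prof: dict[int, str] = {}
        ok = True
        for i in idxs:
            for c, ch in row_profiles[i].items():
                if prof.get(c, ch) != ch:
                    ok = False  # mates disagree: drop the fragment
                    break
                prof[c] = ch
            if not ok:
                break
        if ok and prof:
            fragments.append({"cons": prof, "members": idxs})
    # reads agreeing with the reference at every covered column still carry
    # signal: they form the reference-like group.
    groups: list[dict] = []   # each: {"cons": {col: ch}, "members": [i]}
    for frag in sorted(fragments, key=lambda f: -len(f["cons"])):
        prof = frag["cons"]
        compatible = []
        for g in groups:
            if all(g["cons"].get(c, ch) == ch for c, ch in prof.items()):
                compatible.append(g)
        if compatible:
            g = max(compatible, key=lambda g: len(g["members"]))
            g["members"].extend(frag["members"])
            g["cons"].update(prof)
        else:
            groups.append({"cons": dict(prof), "members": list(frag["members"])})
    # merge groups that remained mutually compatible
    merged = True
    while merged:
        merged = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                a, b = groups[gi], groups[gj]
                if all(a["cons"].get(c, ch) == ch for c, ch in b["cons"].items()):
                    a["members"] += b["members"]
                    a["cons"].update(b["cons"])
                    del groups[gj]
                    merged = True
                    break
            if merged:
                break
    supported = [g for g in groups if len(g["members"]) >= min_support]
    supported.sort(key=lambda g: -len(g["members"]))
    if len(supported) > 2:
        raise MultiallelicError(
            f"{len(supported)} incompatible read classes with support >= "
            f"{min_support}: multiallelic call or contamination"
        )
    if not supported:
        out = [eligible]  # homozygous-reference fallback
    else:
        out = [g["members"] for g in supported]
    return (out, groups) if return_groups else out


def _consensus_allele(
    members: list[int],
    padded: PaddedAlignment,
    candidates: list[CandidateHaplotype],
    locus: RepeatLocus,
    vote_cols: list[int] | None = None,
) -> AlleleCall:
    """Consensus of a read group: its modal candidate haplotype, overridden
    by the group's column-wise majority at the separation columns.

    Restricting the vote to the supported discordant columns keeps
    isolated sequencing errors out of the allele sequence; everywhere
    else the best-fit candidate already carries the evidence.
    """
    # the seed candidate comes from reads assigned uniquely: equivalent-tie
    # reads carry an arbitrary (reference-preferred) candidate label
    unique = [
        i for i in members if len(padded.row_assignments[i].ties) == 1
    ]
    modal_cand = 0
    if unique or members:
        modal_cand = Counter(
            padded.row_assignments[i].candidate for i in (unique or members)
        ).most_common(1)[0][0]
    cand = candidates[modal_cand]
    cmap = _candidate_col_map(padded.columns, cand.signature)
    col_char = ["*"] * len(padded.columns)
    for cpos, col in enumerate(cmap):
        col_char[col] = cand.sequence[cpos]
    # override with the group's majority at separation columns (ties -> ref)
    for c in (vote_cols if vote_cols is not None else range(len(padded.columns))):
        votes = Counter()
        for i in members:
            ch = padded.rows[i][1][c]
            if ch != ".":
                votes[ch] += 1
        if votes:
            top = votes.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                col_char[c] = padded.expanded_reference[c]
            else:
                col_char[c] = top[0][0]
    t0, t1 = locus.tract_start, locus.tract_end
    tract_chars = []
    for (kind, pos, _), ch in zip(padded.columns, col_char):
        in_tract = (t0 <= pos < t1) if kind == "R" else (t0 < pos <= t1)
        if in_tract and ch != "*":
            tract_chars.append(ch)
    tract = "".join(tract_chars)
    qtr = len(tract) // _loc.UNIT_LEN
    matched = next(
        (n for n, s in ALLELES.items() if build_allele_tract(s, locus) == tract),
        None,
    )
    return AlleleCall(
        tract,
        qtr,
        longest_pure_run_units(tract, locus.unit),
        len(members),
        matched,
        cand.signature,
    )


# ----------------------------------------------------------------------
# full pipeline
# ----------------------------------------------------------------------

def _tract_coverage(
    assignments: list[ReadAssignment],
    candidates: list[CandidateHaplotype],
    locus: RepeatLocus,
) -> float:
    """Mean fold-coverage of the repeat tract by non-conflicted reads."""
    total = 0
    t0 = locus.tract_start
    for a in assignments:
        if a.conflict:
            continue
        t1 = len(candidates[a.candidate].sequence) - len(locus.right_flank)
        for p in a.path.pieces:
            total += max(0, min(p.ref_end, t1) - max(p.ref_start, t0))
    return total / locus.tract_length


def call_genotype(
    locus: RepeatLocus,
    reads: list[LocusRead],
    config: CallerConfig = CallerConfig(),
    extra_signatures: tuple = (),
) -> Genotype:
    """Run the full calling pipeline on one sample's localised reads."""
    window = locus.reference_window()
    qc: list[str] = []
    ref_paths: list[tuple[LocusRead, AlignmentPath]] = []
    dropped = 0
    for read in reads:
        path = find_min_error_path(
            read.seq, window, config.max_gaps,
            seed_len=config.seed_len, two_gap_trigger=config.two_gap_trigger,
            max_gap_penalty=config.max_gap_penalty,
        )
        if path is None or path.M > config.m_max:
            dropped += 1
            continue
        ref_paths.append((read, path))
    if dropped:
        logger.info("dropped %d reads with bad alignment score", dropped)
    candidates = enumerate_candidates(
        ref_paths, locus, config, extra_signatures=extra_signatures
    )
    refp_map = {(r.name, r.mate): p for r, p in ref_paths}
    assignments = realign_and_select(
        [r for r, _ in ref_paths], candidates, locus, config,
        reference_paths=refp_map,
    )
    assignments = mate_pair_correct(assignments)
    depth = sum(1 for a in assignments if not a.conflict)
    # the gate is mean fold-coverage over the repeat tract itself: read
    # counts overstate usable depth because flank-only reads carry no
    # length information
    tract_cov = _tract_coverage(assignments, candidates, locus)
    if tract_cov < config.min_depth:
        raise LowDepthError(
            f"mean tract coverage {tract_cov:.1f}x is below "
            f"{config.min_depth}x: locus uncallable at this depth"
        )
    padded = build_padded_alignment(assignments, candidates, locus)
    groups = separate_alleles(padded, config.min_support)
    eligible = [
        i for i, a in enumerate(padded.row_assignments)
        if a.informative or a.resolved_by_mate
    ]
    vote_cols = discordant_columns(padded, eligible, config.min_support)
    alleles = [
        _consensus_allele(g, padded, candidates, locus, vote_cols)
        for g in groups
    ]
    if len(alleles) == 1:
        a = b = alleles[0]
        zyg = "hom"
    else:
        a, b = sorted(alleles, key=lambda c: (c.qtr_units, c.sequence))
        zyg = "het"
    if any(len(c.sequence) % _loc.UNIT_LEN for c in (a, b)):
        qc.append("off-frame-tract")
    conflicts = sum(1 for x in assignments if x.conflict)
    if conflicts:
        qc.append(f"mate-conflicts:{conflicts}")
    return Genotype(a, b, zyg, depth, tuple(qc))


def cross_sample_correct(
    locus: RepeatLocus,
    sample_reads: dict[str, list[LocusRead]],
    first_pass: dict[str, Genotype],
    config: CallerConfig = CallerConfig(),
) -> dict[str, Genotype]:
    """One re-calling round with candidates confirmed in other samples.

    A sample's call is replaced only when the new call has at least the
    old supporting-read total (calls move toward higher support only).
    A no-op on single-sample input.
    """
    if len(sample_reads) < 2:
        return dict(first_pass)
    confirmed: set[tuple] = set()
    for g in first_pass.values():
        for allele in (g.allele_a, g.allele_b):
            if allele.support >= config.min_support and allele.signature:
                confirmed.add(allele.signature)
    out = {}
    for sample, reads in sample_reads.items():
        extra = tuple(confirmed)
        try:
            second = call_genotype(locus, reads, config, extra_signatures=extra)
        except (LowDepthError, MultiallelicError):
            out[sample] = first_pass[sample]
            continue
        old = first_pass[sample]
        old_support = old.allele_a.support + old.allele_b.support
        new_support = second.allele_a.support + second.allele_b.support
        out[sample] = second if new_support >= old_support else old
    return out


def call_cohort(
    locus: RepeatLocus,
    sample_reads: dict[str, list[LocusRead]],
    config: CallerConfig = CallerConfig(),
    cross_correct: bool = True,
) -> dict[str, Genotype | None]:
    """Call every sample, then run one cross-sample correction round.

    Samples failing the depth gate are reported as ``None``.
    """
    first: dict[str, Genotype] = {}
    failed: dict[str, None] = {}
    for sample, reads in sample_reads.items():
        try:
            first[sample] = call_genotype(locus, reads, config)
        except LowDepthError:
            logger.warning("sample %s uncallable: low depth", sample)
            failed[sample] = None
    if cross_correct and len(first) > 1:
        first = cross_sample_correct(
            locus, {s: sample_reads[s] for s in first}, first, config
        )
    return {**first, **failed}
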