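"""Match-matrix alignment of single reads against a locus window.

A read is aligned by partitioning it into contiguous segments, each
placed on one diagonal of the read-vs-reference match matrix.  Segments
are the "match pieces"; a change of diagonal between consecutive pieces
is a "gap" whose height Delta is the absolute diagonal jump (deletion
when the reference offset increases, insertion when it decreases).  The
path score is the mismatch error

    M = m + sum_i Delta_i * exp(5 - l_i)

where m counts mismatching bases inside pieces and l_i is the smaller
length of the two pieces adjoining gap i.  The exponential discount
means a long, well-anchored repeat-unit jump costs almost nothing while
a poorly anchored jump is heavily penalised, which is what lets a single
75 bp read report a multi-unit repeat contraction or expansion.

The search below is exact over this path space for up to two gaps
(vectorised enumeration of diagonals and breakpoints); candidate
haplotype realignment upstream absorbs more complex indel combinations,
so deeper gap chains are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MatchPiece",
    "Gap",
    "AlignmentPath",
    "mismatch_error",
    "classify_gap",
    "build_match_matrix",
    "diagonal_runs",
    "find_min_error_path",
    "normalize_indel",
]

#: default minimal exact-run length for a diagonal to become a candidate
DEFAULT_SEED_LEN = 8
#: default shortest read considered alignable
MIN_READ_LEN = 16
#: diagonals retained for the (expensive) two-gap search
TWO_GAP_DIAGONALS = 8


@dataclass(frozen=True)
class MatchPiece:
    """A contiguous read segment aligned on a single diagonal."""

    read_start: int
    read_end: int
    ref_start: int

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def length(self) -> int:
        return self.read_end - self.read_start

    @property
    def offset(self) -> int:
        """Diagonal index: reference offset minus read offset."""
        return self.ref_start - self.read_start


@dataclass(frozen=True)
class Gap:
    delta: int
    flank_min: int
    kind: str  # "deletion" | "insertion"

    def __post_init__(self) -> None:
        if self.delta < 1 or self.flank_min < 1:
            raise ValueError("gap height and flank length must be >= 1")
        if self.kind not in ("deletion", "insertion"):
            raise ValueError(f"unknown gap kind {self.kind!r}")


@dataclass(frozen=True)
class AlignmentPath:
    pieces: tuple[MatchPiece, ...]
    gaps: tuple[Gap, ...]
    m: int
    M: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "M", mismatch_error(self.m, [(g.delta, g.flank_min) for g in self.gaps])
        )

    @property
    def read_span(self) -> tuple[int, int]:
        return self.pieces[0].read_start, self.pieces[-1].read_end

    def indel_signature(self, ref_window: str, read: str) -> tuple:
        """Left-normalised indel events relative to the reference window.

        Returns a tuple of events ``(ref_pos, signed_delta, inserted_seq)``:
        a deletion removes ``delta`` reference bases starting at
        ``ref_pos``; an insertion places ``inserted_seq`` before
        ``ref_pos``.
        """
        events = []
        for left, right, gap in zip(self.pieces, self.pieces[1:], self.gaps):
            if gap.kind == "deletion":
                pos = left.ref_end
                pos = normalize_indel(ref_window, pos, -gap.delta, None)[0]
                events.append((pos, -gap.delta, None))
            else:
                # the read bases skipped between the two pieces are the
                # inserted block, placed where the left piece ended on the
                # reference
                ins = read[left.read_end : right.read_start]
                if len(ins) != gap.delta:
                    continue
                pos, ins = normalize_indel(ref_window, left.ref_end, gap.delta, ins)
                events.append((pos, gap.delta, ins))
        return tuple(events)


def mismatch_error(m: int, gaps: list[tuple[int, int]]) -> float:
    """M = m + sum Delta_i * exp(5 - l_i), exactly as defined."""
    if m < 0:
        raise ValueError("mismatch count m must be >= 0")
    total = float(m)
    for delta, flank in gaps:
        if delta < 1 or flank < 1:
            raise ValueError("each gap needs Delta >= 1 and l >= 1")
        total += delta * math.exp(5.0 - flank)
    return total


def classify_gap(left: MatchPiece, right: MatchPiece) -> Gap:
    """Classify the discontinuity between two ordered match pieces.

    A rising diagonal offset skips reference bases (deletion in the
    read's source relative to the reference); a falling offset means the
    read carries extra bases (insertion).
    """
    if right.read_start < left.read_end:
        raise ValueError("pieces must be ordered and non-overlapping in the read")
    jump = right.offset - left.offset
    if jump == 0:
        raise ValueError("adjoining pieces share a diagonal: no gap to classify")
    kind = "deletion" if jump > 0 else "insertion"
    return Gap(abs(jump), min(left.length, right.length), kind)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def build_match_matrix(read: str, ref_window: str) -> np.ndarray:
    """Boolean matrix: cell (i, j) is True iff read[i] == ref_window[j]."""
    if not read or not ref_window:
        raise ValueError("read and reference window must be nonempty")
    return _encode(read)[:, None] == _encode(ref_window)[None, :]


def diagonal_runs(read: str, ref_window: str, min_len: int = 1) -> list[MatchPiece]:
    """Maximal exact diagonal runs of length >= min_len (candidate pieces)."""
    mat = build_match_matrix(read, ref_window)
    L, W = mat.shape
    out = []
    for d in range(-L + 1, W):
        i0, i1 = max(0, -d), min(L, W - d)
        if i1 - i0 < min_len:
            continue
        diag = mat[np.arange(i0, i1), np.arange(i0 + d, i1 + d)]
        run = 0
        for idx, hit in enumerate(diag):
            if hit:
                run += 1
            else:
                if run >= min_len:
                    out.append(MatchPiece(i0 + idx - run, i0 + idx, i0 + idx - run + d))
                run = 0
        if run >= min_len:
            out.append(MatchPiece(i1 - run, i1, i1 - run + d))
    out.sort(key=lambda p: (p.read_start, p.ref_start))
    return out


#: cap on candidate diagonals (memory guard for the vectorised stages)
MAX_DIAGONALS = 64


def _max_run_per_diagonal(read: str, ref_window: str) -> np.ndarray:
    """Longest exact diagonal run for every diagonal, vectorised.

    Returns an array of length L+W-1 indexed by diagonal d + (L-1),
    d = j - i in [-(L-1), W-1].
    """
    mat = build_match_matrix(read, ref_window)
    L, W = mat.shape
    runs = np.zeros((L, W), dtype=np.int32)
    runs[0] = mat[0]
    for i in range(1, L):
        runs[i, 0] = mat[i, 0]
        runs[i, 1:] = np.where(mat[i, 1:], runs[i - 1, :-1] + 1, 0)
    out = np.zeros(L + W - 1, dtype=np.int32)
    i_idx, j_idx = np.nonzero(runs)
    if len(i_idx):
        np.maximum.at(out, j_idx - i_idx + (L - 1), runs[i_idx, j_idx])
    return out


def _candidate_diagonals(
    read: str, ref_window: str, seed_len: int, all_diagonals: bool
) -> np.ndarray:
    L, W = len(read), len(ref_window)
    if all_diagonals or seed_len <= 1:
        return np.arange(-L + 1, W)
    best_run = _max_run_per_diagonal(read, ref_window)
    thr = seed_len
    while thr >= 2 and not np.any(best_run >= thr):
        thr //= 2
    hits = np.nonzero(best_run >= max(thr, 2))[0]
    if not len(hits):
        # hopeless read: coarse gapless placements only
        return np.arange(0, max(1, W - L + 1), max(1, L // 2))
    diags = hits - (L - 1)
    if len(diags) > MAX_DIAGONALS:
        order = np.argsort(-best_run[hits], kind="stable")[:MAX_DIAGONALS]
        diags = np.sort(diags[order])
    return diags


def _mismatch_prefix(read: str, ref_window: str, diags: np.ndarray) -> np.ndarray:
    """Per-diagonal cumulative mismatch counts along the read.

    Off-window positions count as mismatches, so partially overlapping
    reads are scored rather than rejected.
    """
    r = _encode(read)
    w = _encode(ref_window)
    L, W = len(r), len(w)
    j = diags[:, None] + np.arange(L)[None, :]
    inside = (j >= 0) & (j < W)
    ref_at = np.where(inside, w[np.clip(j, 0, W - 1)], 0)
    mm = (~inside) | (ref_at != r[None, :])
    pref = np.zeros((len(diags), L + 1), dtype=np.int64)
    np.cumsum(mm, axis=1, out=pref[:, 1:])
    return pref


def find_min_error_path(
    read: str,
    ref_window: str,
    max_gaps: int = 2,
    *,
    seed_len: int = DEFAULT_SEED_LEN,
    min_read_len: int = MIN_READ_LEN,
    all_diagonals: bool = False,
    two_gap_trigger: float = 1.25,
    max_gap_penalty: float = 1e-4,
) -> AlignmentPath | None:
    """Minimum mismatch-error path of a read through the reference window.

    Exact over paths with up to ``min(max_gaps, 2)`` gaps.  Ties are
    broken deterministically: fewer gaps first, then leftmost reference
    placement.  The two-gap stage runs only when the best one-gap score
    still exceeds ``two_gap_trigger`` (set it to 0 with
    ``all_diagonals=True`` for a fully exhaustive search).  Returns
    ``None`` for reads shorter than ``min_read_len`` (unalignable).

    ``max_gap_penalty`` caps the penalty term Delta*exp(5-l) a single
    gap may contribute: a gap is only a credible indel when its
    adjoining pieces anchor it almost certainly (l >= 5 + ln(Delta/cap)).
    Within a quasi-repeat of near-identical units, short coincidental
    anchors are frequent, and without this gate a tall gap over a
    14-bp anchor (penalty ~5e-3) would outscore a single honest
    mismatch.  Set it to ``inf`` to search the unrestricted path space.
    """
    if max_gaps < 0:
        raise ValueError("max_gaps must be >= 0")
    L = len(read)
    if L < min_read_len:
        return None
    diags = _candidate_diagonals(read, ref_window, seed_len, all_diagonals)
    pref = _mismatch_prefix(read, ref_window, diags)
    nd = len(diags)

    # --- gapless stage -------------------------------------------------
    total = pref[:, L]
    best_i = int(np.argmin(total))
    best = (float(total[best_i]), [(0, L, int(diags[best_i]))])

    if max_gaps >= 1 and best[0] > 0 and nd > 1 and L >= 2:
        # --- one-gap stage ---------------------------------------------
        # deletion (diagonal offset rises): read stays contiguous,
        #   pieces [0,b) and [b,L)
        b = np.arange(1, L)
        pen_l = np.exp(5.0 - np.minimum(b, L - b))  # (L-1,)
        left = pref[:, 1:L]                          # (nd, L-1) cost of [0, b)
        right = pref[:, L][:, None] - pref[:, 1:L]   # (nd, L-1) cost of [b, L)
        dd = (diags[None, :] - diags[:, None]).astype(float)  # d2 - d1
        pen_term = dd[:, :, None] * pen_l[None, None, :]
        cost = left[:, None, :] + right[None, :, :] + pen_term
        cost[dd <= 0, :] = np.inf  # insertions handled below
        cost[pen_term > max_gap_penalty] = np.inf
        flat = int(np.argmin(cost))
        i1, i2, ib = np.unravel_index(flat, cost.shape)
        c1 = float(cost[i1, i2, ib])
        if c1 < best[0]:
            bp = int(ib) + 1
            best = (c1, [(0, bp, int(diags[i1])), (bp, L, int(diags[i2]))])
        # insertion (offset falls by Delta): the read skips Delta bases,
        #   pieces [0,b) and [b+Delta, L); skipped bases cost only the
        #   gap penalty
        pair_i1, pair_i2 = np.nonzero(dd < 0)
        deltas = -dd[pair_i1, pair_i2].astype(int)
        for delta in np.unique(deltas):
            if delta >= L - 1:
                continue
            sel = deltas == delta
            rows1, rows2 = pair_i1[sel], pair_i2[sel]
            bi = np.arange(1, L - delta)
            pen = delta * np.exp(5.0 - np.minimum(bi, L - delta - bi))
            pen = np.where(pen > max_gap_penalty, np.inf, pen)
            ci = (
                pref[rows1][:, bi]
                + pref[rows2][:, L][:, None]
                - pref[rows2][:, bi + delta]
                + pen[None, :]
            )
            fl = int(np.argmin(ci))
            r, jb = np.unravel_index(fl, ci.shape)
            v = float(ci[r, jb])
            if v < best[0]:
                bp = int(bi[jb])
                best = (
                    v,
                    [(0, bp, int(diags[rows1[r]])),
                     (bp + int(delta), L, int(diags[rows2[r]]))],
                )

        if max_gaps >= 2 and best[0] > two_gap_trigger and nd > 1 and L >= 3:
            # --- two-gap stage on a pruned diagonal set ----------------
            if all_diagonals or nd <= TWO_GAP_DIAGONALS:
                keep = np.arange(nd)
            else:
                keep = np.argsort(total, kind="stable")[:TWO_GAP_DIAGONALS]
                keep = np.union1d(keep, [i1, i2])
            kd = diags[keep]
            kp = pref[keep]
            nk = len(kd)
            e1 = np.arange(1, L)                      # end of piece 1
            e2 = np.arange(1, L)                      # end of piece 2
            best2 = None
            for a in range(nk):
                for mi in range(nk):
                    if mi == a:
                        continue
                    d12 = int(kd[mi] - kd[a])
                    skip1 = -d12 if d12 < 0 else 0
                    for c in range(nk):
                        if c == mi:
                            continue
                        d23 = int(kd[c] - kd[mi])
                        skip2 = -d23 if d23 < 0 else 0
                        s2 = e1 + skip1               # start of piece 2
                        s3 = e2 + skip2               # start of piece 3
                        l2 = e2[None, :] - s2[:, None]
                        l3 = L - s3
                        ok = (l2 >= 1) & (l3[None, :] >= 1)
                        if not ok.any():
                            continue
                        pen12 = abs(d12) * np.exp(
                            5.0 - np.minimum(e1[:, None], l2)
                        )
                        pen23 = abs(d23) * np.exp(
                            5.0 - np.minimum(l2, l3[None, :])
                        )
                        pen = np.where(
                            (pen12 > max_gap_penalty)
                            | (pen23 > max_gap_penalty),
                            np.inf, pen12 + pen23,
                        )
                        s2c = np.minimum(s2, L)
                        s3c = np.minimum(s3, L)
                        mcost = (
                            kp[a][e1][:, None]
                            + kp[mi][e2][None, :] - kp[mi][s2c][:, None]
                            + kp[c][L] - kp[c][s3c][None, :]
                        )
                        tot2 = np.where(ok, mcost + pen, np.inf)
                        fl = int(np.argmin(tot2))
                        v = float(tot2.flat[fl])
                        if best2 is None or v < best2[0]:
                            j1, j2 = np.unravel_index(fl, tot2.shape)
                            best2 = (
                                v,
                                [
                                    (0, int(e1[j1]), int(kd[a])),
                                    (int(e1[j1]) + skip1, int(e2[j2]), int(kd[mi])),
                                    (int(e2[j2]) + skip2, L, int(kd[c])),
                                ],
                            )
            if best2 is not None and best2[0] < best[0]:
                best = (best2[0], best2[1])

    pieces = tuple(
        MatchPiece(s, e, s + d) for s, e, d in best[1]
    )
    gaps = tuple(classify_gap(a, b) for a, b in zip(pieces, pieces[1:]))
    diag_list = diags.tolist()
    m = 0
    for s, e, d in best[1]:
        i0 = diag_list.index(d)
        m += int(pref[i0, e] - pref[i0, s])
    return AlignmentPath(pieces, gaps, m)


def normalize_indel(
    ref: str, pos: int, delta: int, inserted: str | None
) -> tuple[int, str | None]:
    """Left-align an indel event inside repetitive sequence.

    ``delta`` < 0 deletes reference bases [pos, pos - delta); ``delta`` > 0
    inserts ``inserted`` before reference position ``pos``.  The event is
    shifted left while the flanking base equals the last base of the
    deleted/inserted block (the standard left-normalisation used for
    repeat indels, making calls positionally comparable).
    """
    if delta < 0:
        k = -delta
        while pos > 0 and ref[pos - 1] == ref[pos + k - 1]:
            pos -= 1
        return pos, None
    if inserted is None or len(inserted) != delta:
        raise ValueError("insertion requires the inserted sequence of length delta")
    ins = inserted
    while pos > 0 and ref[pos - 1] == ins[-1]:
        ins = ref[pos - 1] + ins[:-1]
        pos -= 1
    return pos, ins
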