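"""Inverted-repeat discovery, candidate assembly, TSD detection, nesting.

The search aligns each genome segment against its own reverse complement
with a seed-and-extend strategy: exact k-mer seeds (default k=8) anchor a
banded, X-drop gapped extension (match +1, mismatch -1, gap -2, X-drop 6),
so terminal inverted repeats (TIRs) may contain mismatches and gaps.  A
match between segment position i and reverse-complement position j is by
construction a reverse-complementary match between two genome loci; mapping
the subject interval back through the reverse complement yields the two TIR
arm coordinates.  Each biological arm pair would be seen twice (once per
orientation); only the canonical orientation is extended, so every pair is
reported exactly once and the full-length self-alignment never appears.

Assembled candidates must pass, in order: element length bounds, a GC
bound on the terminal (TIR) sequences, a compositional-complexity bound on
the element, and a target-site-duplication (TSD) check.  Because local
extension can overshoot the true element boundary — most prominently when
the TSD is its own reverse complement (TA, the canonical Tourist TSD) and
therefore aligns as part of the TIR — the TSD check scans a small window of
inward trims of the outer TIR ends and adopts the outermost boundary pair
flanked by an exact direct repeat.  Finally, candidates whose TIR arms
overlap another candidate's arms are the same locus; only the longest
element per such conflict is kept.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

from .segmentation import GenomeSegment
from .sequence_core import gc_content, lcc_score, reverse_complement

# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class InvertedRepeatHit:
    """One gapped local alignment between two TIR arms, in genome coordinates.

    ``aln_len`` counts alignment columns (including gap columns); the two
    arm intervals are 0-based half-open and ordered left < right.
    """

    chrom: str
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    aln_len: int
    matches: int
    gaps: int
    score: int

    @property
    def identity(self) -> float:
        return self.matches / self.aln_len

    @property
    def span(self) -> int:
        return self.right_end - self.left_start


@dataclass
class MiteCandidate:
    """A putative element: span excludes the TSD; flanks sit outside it."""

    chrom: str
    start: int
    end: int
    seq: str
    tir_len: int
    left_tir: Tuple[int, int]
    right_tir: Tuple[int, int]
    tsd: Optional[str]
    flank_left: str
    flank_right: str

    @property
    def candidate_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def tsd_len(self) -> int:
        return len(self.tsd) if self.tsd else 0

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# banded X-drop extension


def _extend(
    q: str,
    s: str,
    match: int,
    mismatch: int,
    gap: int,
    band: int,
    xdrop: int,
) -> List[Tuple[int, int, int, int, int, int]]:
    """Extend an alignment anchored immediately before ``q[0]``/``s[0]``.

    Banded Needleman–Wunsch-style extension with linear gap cost and X-drop
    termination: cells scoring more than ``xdrop`` below the running best
    are pruned, and the extension stops when a whole row dies.  Returns the
    score-record endpoints — every endpoint that improved on all previous
    scores — as ``(score, q_len, s_len, matches, gap_cols, columns)``
    tuples in increasing score order, starting with the empty extension
    ``(0, 0, 0, 0, 0, 0)``.  Keeping the whole record ladder (rather than
    only the maximum) lets the caller back off to a shorter endpoint when
    the marginal tail of a maximal extension would drag identity below the
    reporting threshold.  Ties prefer the earlier (shorter) endpoint.
    """
    nq, ns = len(q), len(s)
    records = [(0, 0, 0, 0, 0, 0)]
    best = 0
    # row 0: leading gaps in q
    prev: Dict[int, Tuple[int, int, int, int]] = {0: (0, 0, 0, 0)}
    for j in range(1, min(ns, band) + 1):
        sc = gap * j
        if sc <= best - xdrop:
            break
        prev[j] = (sc, 0, j, j)
    for i in range(1, nq + 1):
        lo, hi = max(0, i - band), min(ns, i + band)
        cur: Dict[int, Tuple[int, int, int, int]] = {}
        qc = q[i - 1]
        row_record = None
        for j in range(lo, hi + 1):
            cell = None
            if j > 0:
                p = prev.get(j - 1)
                if p is not None:
                    hit = qc == s[j - 1] and qc != "N"
                    cell = (
                        p[0] + (match if hit else mismatch),
                        p[1] + (1 if hit else 0),
                        p[2],
                        p[3] + 1,
                    )
            p = prev.get(j)
            if p is not None:
                cand = (p[0] + gap, p[1], p[2] + 1, p[3] + 1)
                if cell is None or cand[0] > cell[0]:
                    cell = cand
            p = cur.get(j - 1)
            if p is not None:
                cand = (p[0] + gap, p[1], p[2] + 1, p[3] + 1)
                if cell is None or cand[0] > cell[0]:
                    cell = cand
            if cell is None or cell[0] <= best - xdrop:
                continue
            cur[j] = cell
            if cell[0] > best and (
                row_record is None or cell[0] > row_record[0]
            ):
                row_record = (cell[0], i, j, cell[1], cell[2], cell[3])
        if row_record is not None:
            best = row_record[0]
            records.append(row_record)
        if not cur:
            break
        prev = cur
    return records


def _overlaps(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# inverted-repeat search


def find_inverted_repeats(
    segment: GenomeSegment,
    tir_min_len: int = 10,
    min_identity: float = 0.8,
    mite_max_len: int = 800,
    seed_len: int = 8,
    band: int = 5,
    xdrop: int = 6,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    max_kmer_hits: int = 50,
) -> List[InvertedRepeatHit]:
    """All maximal inverted-repeat arm pairs inside one segment.

    Returns hits with alignment length >= ``tir_min_len`` and identity >=
    ``min_identity`` whose arms do not overlap each other and whose span
    (left arm start to right arm end) is at most ``mite_max_len``.  Seeds
    occurring more than ``max_kmer_hits`` times in the segment are skipped
    (low-complexity guard), as are seeds already covered by an extended
    alignment.  Output is sorted by genome coordinates.
    """
    seq = segment.seq
    n = len(seq)
    if n < 2 * tir_min_len:
        return []
    rc = reverse_complement(seq)

    index: Dict[str, List[int]] = {}
    for j in range(n - seed_len + 1):
        kmer = rc[j : j + seed_len]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(j)

    raw: Dict[Tuple[int, int, int, int], Tuple[int, int, int, int]] = {}
    boxes: List[Tuple[int, int, int, int]] = []
    cap = mite_max_len

    for a in range(n - seed_len + 1):
        kmer = seq[a : a + seed_len]
        positions = index.get(kmer)
        if not positions or len(positions) > max_kmer_hits:
            continue
        for b in positions:
            # canonical orientation only: the mirror seed satisfies the
            # complementary inequality, so each arm pair is extended once.
            if a + b + seed_len > n:
                continue
            # outer span can only grow during extension; prune early.
            if (n - b) - a > mite_max_len:
                continue
            covered = False
            for qs0, qe0, ss0, se0 in boxes:
                if qs0 <= a and a + seed_len <= qe0 and ss0 <= b and b + seed_len <= se0:
                    covered = True
                    break
            if covered:
                continue
            r_recs = _extend(
                seq[a + seed_len : a + seed_len + cap],
                rc[b + seed_len : b + seed_len + cap],
                match, mismatch, gap, band, xdrop,
            )
            l_recs = _extend(
                seq[max(0, a - cap) : a][::-1],
                rc[max(0, b - cap) : b][::-1],
                match, mismatch, gap, band, xdrop,
            )
            # rectangle covered by the maximal extension, for seed skipping
            boxes.append(
                (
                    a - l_recs[-1][1],
                    a + seed_len + r_recs[-1][1],
                    b - l_recs[-1][2],
                    b + seed_len + r_recs[-1][2],
                )
            )
            # best-scoring endpoint pair that satisfies the reporting
            # contract; backing off the record ladder discards marginal
            # extension tails that would sink identity below threshold.
            pairs = sorted(
                ((lr, rr) for lr in l_recs for rr in r_recs),
                key=lambda p: (
                    -(p[0][0] + p[1][0]),
                    p[0][5] + p[1][5],
                    p[0][5],
                ),
            )
            for l_rec, r_rec in pairs:
                matches = seed_len + l_rec[3] + r_rec[3]
                cols = seed_len + l_rec[5] + r_rec[5]
                if cols < tir_min_len or matches / cols < min_identity:
                    continue
                qs, qe = a - l_rec[1], a + seed_len + r_rec[1]
                ss, se = b - l_rec[2], b + seed_len + r_rec[2]
                arm1 = (qs, qe)
                arm2 = (n - se, n - ss)
                if arm2[0] < arm1[0]:
                    arm1, arm2 = arm2, arm1
                if arm1[1] > arm2[0]:  # overlapping arms: palindrome center
                    continue
                if arm2[1] - arm1[0] > mite_max_len:
                    continue
                gapcols = l_rec[4] + r_rec[4]
                score = seed_len * match + l_rec[0] + r_rec[0]
                key = (arm1[0], arm1[1], arm2[0], arm2[1])
                stats = (score, cols, matches, gapcols)
                if key not in raw or stats[0] > raw[key][0]:
                    raw[key] = stats
                break

    # suppress near-duplicate reports of the same arm pair (different seeds
    # that converged to slightly different endpoints): keep best score.
    order = sorted(
        raw.items(), key=lambda kv: (-kv[1][0], -kv[1][1], kv[0])
    )
    kept: List[Tuple[Tuple[int, int, int, int], Tuple[int, int, int, int]]] = []
    for key, stats in order:
        l_int, r_int = (key[0], key[1]), (key[2], key[3])
        dup = any(
            _overlaps(l_int, (k[0], k[1])) and _overlaps(r_int, (k[2], k[3]))
            for k, _ in kept
        )
        if not dup:
            kept.append((key, stats))

    hits = [
        InvertedRepeatHit(
            chrom=segment.chrom,
            left_start=segment.start + ls,
            left_end=segment.start + le,
            right_start=segment.start + rs,
            right_end=segment.start + re,
            aln_len=cols,
            matches=matches,
            gaps=gapcols,
            score=score,
        )
        for (ls, le, rs, re), (score, cols, matches, gapcols) in kept
    ]
    hits.sort(key=lambda h: (h.left_start, h.left_end, h.right_start, h.right_end))
    return hits


# ---------------------------------------------------------------------------
# TSD detection and candidate assembly


def detect_tsd(
    chrom_seq: str,
    start: int,
    end: int,
    tsd_min_len: int = 2,
    tsd_max_len: int = 10,
) -> Optional[str]:
    """Longest exact direct repeat flanking [start, end), or None.

    Scans lengths from ``tsd_max_len`` down to ``tsd_min_len`` and returns
    the first (longest) k with chrom_seq[start-k:start] == chrom_seq[end:end+k].
    Repeats containing N never qualify.
    """
    if not (0 <= start < end <= len(chrom_seq)):
        raise ValueError("detect_tsd interval outside chromosome")
    kmax = min(tsd_max_len, start, len(chrom_seq) - end)
    for k in range(kmax, tsd_min_len - 1, -1):
        left = chrom_seq[start - k : start]
        if "N" in left:
            continue
        if left == chrom_seq[end : end + k]:
            return left
    return None


_COMPLEMENT_BASE = {"A": "T", "C": "G", "G": "C", "T": "A"}


def terminal_arm_length(
    chrom_seq: str,
    start: int,
    end: int,
    tir_min_len: int,
    min_arm_identity: float = 0.8,
) -> Optional[Tuple[int, int]]:
    """Terminal inverted-repeat run anchored at [start, end).

    Pairs the i-th base after ``start`` with the i-th base before ``end``
    and returns ``(u, matches)`` for the qualifying arm length u (at least
    ``tir_min_len``, up to half the span, complement identity at least
    ``min_arm_identity``) with the highest identity, ties going to the
    longer arm; ``None`` when no u qualifies.  A terminal inverted repeat by
    definition starts at the element boundary, so the outermost two base
    pairs must complement-match exactly; this anchors the measure to the
    boundary and keeps a symmetric shift of both ends (which preserves the
    arm-pairing diagonal) from faking the structure at a wrong boundary.
    Ungapped by construction, and deliberately independent of the seeded
    alignment that proposed the span, so alignment overshoot cannot fake
    it either.
    """
    half = (end - start) // 2
    if half < tir_min_len:
        return None
    matches = 0
    best = None
    for i in range(half):
        a = chrom_seq[start + i]
        b = chrom_seq[end - 1 - i]
        if a != "N" and _COMPLEMENT_BASE.get(a) == b:
            matches += 1
        elif i < 2:
            return None
        u = i + 1
        if u >= tir_min_len and matches >= math.ceil(min_arm_identity * u):
            # prefer the highest-fidelity qualifying arm, longest on ties
            if best is None or matches * best[0] >= best[1] * u:
                best = (u, matches)
    return best


def assemble_candidate(
    hit: InvertedRepeatHit,
    chrom_seq: str,
    mite_min_len: int = 50,
    mite_max_len: int = 800,
    gc_min: float = 0.15,
    gc_max: float = 0.95,
    gc_on_element: bool = False,
    lcc_threshold: float = 1.0,
    tsd_min_len: int = 2,
    tsd_max_len: int = 10,
    require_tsd: bool = True,
    boundary_trim_window: int = 60,
    tir_min_len: int = 10,
    flank_len: int = 50,
) -> Tuple[Optional[MiteCandidate], Optional[str]]:
    """Build a candidate from an arm-pair hit, or reject it with a reason.

    Filters run in order: length, GC (on the terminal/TIR sequences unless
    ``gc_on_element``), complexity, boundary structure.  Because local
    extension overshoots the true element boundary whenever flanking bases
    happen to align (most systematically when the TSD is its own reverse
    complement, like TA), the boundary step scans inward trims of the
    outer hit ends — up to ``boundary_trim_window`` bp per side, smallest
    total trim first — and adopts the outermost boundary pair that carries
    *both* defining structures: an exact target-site duplication and a
    terminal inverted-repeat run of at least ``tir_min_len`` bp (see
    :func:`terminal_arm_length`).  Requiring the arm structure at the
    boundary stops chance direct repeats inside an over-extended alignment
    from fixing a wrong boundary.  Returns ``(candidate, None)`` or
    ``(None, reason)`` with reason in ``{"length", "gc", "complexity",
    "tsd"}``.
    """
    L = len(chrom_seq)
    if not (0 <= hit.left_start < hit.right_end <= L):
        raise ValueError("hit coordinates outside chromosome")
    start0, end0 = hit.left_start, hit.right_end
    if not (mite_min_len <= end0 - start0 <= mite_max_len + 2 * boundary_trim_window):
        return None, "length"

    if gc_on_element:
        gc_targets = [chrom_seq[start0:end0]]
    else:
        gc_targets = [
            chrom_seq[hit.left_start : hit.left_end],
            chrom_seq[hit.right_start : hit.right_end],
        ]
    for t in gc_targets:
        if not t:
            return None, "gc"
        g = gc_content(t)
        if not (gc_min <= g <= gc_max):
            return None, "gc"

    if lcc_score(chrom_seq[start0:end0]) < lcc_threshold:
        return None, "complexity"

    # trims on the two sides track each other up to alignment gap skew;
    # among all boundary pairs carrying both structures, the one whose
    # terminal repeat has the highest complement identity wins (an exact
    # arm at the true boundary beats the diluted arm a shifted boundary
    # inherits), with the outermost boundary breaking ties.  Because a
    # maximal alignment always covers the true arm, the true boundary lies
    # within (arm length - tir_min_len) of the hit end on each side: that
    # per-hit bound reaches deep overshoot on long noisy arms while giving
    # short (junk) arms almost no room for chance direct repeats.
    max_skew = hit.gaps + 2
    found = None
    found_key = None
    W = boundary_trim_window
    max_tl = min(W, max(0, (hit.left_end - hit.left_start) - tir_min_len + 2))
    max_tr = min(W, max(0, (hit.right_end - hit.right_start) - tir_min_len + 2))
    for total in range(0, max_tl + max_tr + 1):
        for tl in range(max(0, total - max_tr), min(max_tl, total) + 1):
            tr = total - tl
            if abs(tl - tr) > max_skew:
                continue
            s2, e2 = start0 + tl, end0 - tr
            if not (mite_min_len <= e2 - s2 <= mite_max_len):
                continue
            tsd = detect_tsd(chrom_seq, s2, e2, tsd_min_len, tsd_max_len)
            if tsd is None:
                continue
            arm = terminal_arm_length(chrom_seq, s2, e2, tir_min_len)
            if arm is None:
                continue
            u, matches = arm
            # identity as a cross-multiplied fraction; larger is better,
            # then smaller total trim, then smaller left trim.
            key = (-matches / u, total, tl)
            if found_key is None or key < found_key:
                found = (s2, e2, tsd, u)
                found_key = key

    if found is None:
        if require_tsd:
            return None, "tsd"
        s2, e2, tsd = start0, end0, None
        if not (mite_min_len <= e2 - s2 <= mite_max_len):
            return None, "length"
        arm = terminal_arm_length(chrom_seq, s2, e2, tir_min_len)
        u = arm[0] if arm is not None else min(hit.aln_len, (e2 - s2) // 2)
    else:
        s2, e2, tsd, u = found

    seq = chrom_seq[s2:e2]
    if lcc_score(seq) < lcc_threshold:
        return None, "complexity"
    k = len(tsd) if tsd else 0
    flank_left = chrom_seq[max(0, s2 - k - flank_len) : s2 - k]
    flank_right = chrom_seq[e2 + k : e2 + k + flank_len]
    cand = MiteCandidate(
        chrom=hit.chrom,
        start=s2,
        end=e2,
        seq=seq,
        tir_len=u,
        left_tir=(s2, s2 + u),
        right_tir=(e2 - u, e2),
        tsd=tsd,
        flank_left=flank_left,
        flank_right=flank_right,
    )
    return cand, None


# ---------------------------------------------------------------------------
# nesting resolution


def _arms_shared(a: Tuple[int, int], b: Tuple[int, int]) -> bool:
    """Substantial arm overlap: at least half the shorter arm interval.

    A 1-2 bp coincidental touch between unrelated arm calls must not make
    two candidates "the same element", so the overlap is required to cover
    >= 50% of the shorter of the two arms.
    """
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov * 2 >= min(a[1] - a[0], b[1] - b[0])


def same_locus(a: MiteCandidate, b: MiteCandidate) -> bool:
    """True when two candidates describe the same element locus.

    Two candidates are the same element when their TIR structure
    coincides: the left arms overlap each other and the right arms overlap
    each other (each substantially).  This captures boundary variants of
    one element — the duplicate calls that nesting resolution exists to
    collapse, which differ by a few bases at either end.  A candidate that
    merely shares one arm region with a longer overlapping call (typically
    a chance alignment seeded by a real arm) is a different locus, as is a
    genuinely nested element whose arms are disjoint from its host's.
    """
    if a.chrom != b.chrom:
        return False
    return _arms_shared(a.left_tir, b.left_tir) and _arms_shared(
        a.right_tir, b.right_tir
    )


def resolve_nested(candidates: Iterable[MiteCandidate]) -> List[MiteCandidate]:
    """Collapse duplicates and nested candidates, keeping the longer element.

    Exact duplicates (same chrom/start/end) collapse to one.  Whenever two
    candidates describe the same locus (see :func:`same_locus`) the longer
    element wins, with ties broken by (chrom, start, end).  The result is
    independent of input order and sorted by genome coordinates.
    """
    uniq: Dict[Tuple[str, int, int], MiteCandidate] = {}
    for c in sorted(
        candidates, key=lambda c: (c.chrom, c.start, c.end, c.tir_len)
    ):
        uniq.setdefault((c.chrom, c.start, c.end), c)
    order = sorted(
        uniq.values(), key=lambda c: (-(c.end - c.start), c.chrom, c.start, c.end)
    )
    kept: Dict[str, List[MiteCandidate]] = {}
    out: List[MiteCandidate] = []
    for c in order:
        bucket = kept.setdefault(c.chrom, [])
        if any(same_locus(c, k) for k in bucket):
            continue
        bucket.append(c)
        out.append(c)
    out.sort(key=lambda c: (c.chrom, c.start, c.end))
    return out
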