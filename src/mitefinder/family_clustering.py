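"""Greedy centroid clustering of candidate elements into families.

Candidates are compared by global pairwise alignment identity — matching
columns over total alignment columns, gap columns included in the
denominator — on the better of the two strands, and clustered greedily:
processed in decreasing length order, each candidate joins the first
existing centroid it matches at or above the identity threshold, otherwise
it founds a new family with itself as centroid.  Element sequences exclude
the target-site duplication by construction, so clustering compares
internal sequences only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import edlib
from Bio import Align

from .sequence_core import reverse_complement
from .tir_search import MiteCandidate


@dataclass
class Family:
    family_id: int
    centroid_id: str
    member_ids: List[str] = field(default_factory=list)
    representative_id: Optional[str] = None
    common_tsd: Optional[str] = None
    distinct_count: Optional[int] = None
    distinct_ids: Optional[List[str]] = None

    def __len__(self) -> int:
        return len(self.member_ids)


_ALIGNER_CACHE: Dict[tuple, Align.PairwiseAligner] = {}


def _global_aligner(
    match: float, mismatch: float, gap_open: float, gap_extend: float
) -> Align.PairwiseAligner:
    key = (match, mismatch, gap_open, gap_extend)
    aligner = _ALIGNER_CACHE.get(key)
    if aligner is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap_open
        aligner.extend_gap_score = gap_extend
        _ALIGNER_CACHE[key] = aligner
    return aligner


def pairwise_identity(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -10.0,
    gap_extend: float = -1.0,
) -> float:
    """Global-alignment identity between two sequences, best strand.

    End gaps are penalized (true global alignment with affine gaps), so two
    sequences of very different length cannot reach high identity through
    dangling ends.  Returns matching columns / total alignment columns.
    """
    if not a or not b:
        raise ValueError("pairwise_identity of empty sequence")
    aligner = _global_aligner(match, mismatch, gap_open, gap_extend)
    best = 0.0
    for subject in (b, reverse_complement(b)):
        aln = aligner.align(a, subject)[0]
        counts = aln.counts()
        cols = counts.gaps + counts.identities + counts.mismatches
        if cols:
            best = max(best, counts.identities / cols)
    return best


def _composition(seq: str) -> Tuple[int, int, int, int]:
    return (seq.count("A"), seq.count("C"), seq.count("G"), seq.count("T"))


def _identity_upper_bound(
    len_a: int, comp_a: Tuple[int, ...], len_b: int, comp_b: Tuple[int, ...]
) -> float:
    """Cheap, provable cap on global-alignment identity.

    A global alignment has at least max(len_a, len_b) columns, and matching
    columns cannot exceed the smaller length nor the shared base
    composition (a match consumes one identical base from each side; the
    reverse complement permutes the composition).  Used to skip alignments
    that cannot reach the clustering threshold.
    """
    longest = max(len_a, len_b)
    shared_fwd = sum(min(x, y) for x, y in zip(comp_a, comp_b))
    shared_rc = sum(min(x, y) for x, y in zip(comp_a, comp_b[::-1]))
    return min(len_a, len_b, max(shared_fwd, shared_rc)) / longest


def _edit_distance_screen(
    a: str, b: str, b_rc: str, threshold: float
) -> bool:
    """Can identity(a, b on either strand) possibly reach ``threshold``?

    Any alignment with identity >= t has at most (1-t) * columns non-match
    columns, and columns <= |a| + |b|, so its unit-cost edit distance is at
    most (1-t) * (|a| + |b|).  A banded edit-distance computation with that
    cap is therefore an exact screen: if both orientations exceed the cap,
    no alignment can qualify and the expensive scored alignment is skipped.
    """
    cap = int((1.0 - threshold) * (len(a) + len(b)))
    for subject in (b, b_rc):
        if edlib.align(a, subject, mode="NW", task="distance",
                       k=cap)["editDistance"] != -1:
            return True
    return False


def greedy_cluster(
    candidates: Sequence[MiteCandidate],
    cluster_identity: float = 0.80,
    best_match: bool = False,
) -> List[Family]:
    """Cluster candidates into families at the given identity threshold.

    Input order never matters: candidates are sorted by decreasing sequence
    length with candidate_id as tiebreak, the classic greedy-centroid
    ordering.  With ``best_match`` a candidate joins the highest-identity
    qualifying centroid instead of the first.
    """
    if not (0.0 < cluster_identity <= 1.0):
        raise ValueError("cluster_identity must be in (0, 1]")
    ordered = sorted(
        candidates, key=lambda c: (-len(c.seq), c.candidate_id)
    )
    families: List[Family] = []
    centroid_seq: Dict[int, str] = {}
    centroid_rc: Dict[int, str] = {}
    centroid_comp: Dict[int, Tuple[int, ...]] = {}
    for cand in ordered:
        chosen = None
        best_ident = 0.0
        comp = _composition(cand.seq)
        for fam in families:
            cseq = centroid_seq[fam.family_id]
            bound = _identity_upper_bound(
                len(cand.seq), comp, len(cseq), centroid_comp[fam.family_id]
            )
            if bound < cluster_identity:
                continue
            if not _edit_distance_screen(
                cand.seq, cseq, centroid_rc[fam.family_id], cluster_identity
            ):
                continue
            ident = pairwise_identity(cand.seq, cseq)
            if ident >= cluster_identity:
                if not best_match:
                    chosen = fam
                    break
                if ident > best_ident:
                    chosen, best_ident = fam, ident
        if chosen is None:
            fam = Family(
                family_id=len(families) + 1, centroid_id=cand.candidate_id
            )
            fam.member_ids.append(cand.candidate_id)
            centroid_seq[fam.family_id] = cand.seq
            centroid_rc[fam.family_id] = reverse_complement(cand.seq)
            centroid_comp[fam.family_id] = comp
            families.append(fam)
        else:
            chosen.member_ids.append(cand.candidate_id)
    return families
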