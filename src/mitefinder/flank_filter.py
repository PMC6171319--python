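"""Flanking-sequence divergence filter.

A genuine transposition deposits the element into a new genomic context,
so two independent insertions of the same family should have unrelated
flanking sequences, whereas a segmental or tandem duplication carries the
flanks along.  For every pair of same-family members the filter runs eight
local alignments (left/right flank against the partner's flanks in both
orientations, plus the four "flank against flank-plus-element" variants
that catch members whose annotated boundaries sit slightly inside the
partner).  A pair is *shared* if any normalized score reaches the cutoff;
a member is a *distinct individual* only if it is non-shared against every
other member, and a family survives only if its distinct-individual count
reaches the minimum copy number.

The local-alignment scoring is match +1 / mismatch -1 / gap -2, and the
score is normalized by the attainable self-score min(len(query),
flank_len), so 1.0 means a perfect full-length flank match; unrelated
random 50-mers score ~0.2-0.3 and conserved flanks score near 1, with the
default cutoff at 0.5.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .family_clustering import Family
from .sequence_core import reverse_complement
from .tir_search import MiteCandidate, terminal_arm_length

_alignment_calls = 0


def alignment_call_count() -> int:
    """Number of local-alignment invocations since the last reset."""
    return _alignment_calls


def reset_alignment_call_count() -> None:
    global _alignment_calls
    _alignment_calls = 0


_LOCAL_ALIGNER: Optional[Align.PairwiseAligner] = None


def _local_aligner() -> Align.PairwiseAligner:
    global _LOCAL_ALIGNER
    if _LOCAL_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -2
        aligner.extend_gap_score = -2
        _LOCAL_ALIGNER = aligner
    return _LOCAL_ALIGNER


def _local_score(query: str, subject: str) -> float:
    global _alignment_calls
    _alignment_calls += 1
    if not query or not subject:
        return 0.0
    return float(_local_aligner().score(query, subject))


def _normalized(query: str, subject: str, flank_len: int) -> float:
    denom = min(len(query), flank_len)
    if denom == 0:
        # zero-length flank at a chromosome edge scores 0 by contract
        _local_score(query, subject)
        return 0.0
    return _local_score(query, subject) / denom


@dataclass(frozen=True)
class FlankComparisonResult:
    pair: Tuple[str, str]
    scores: Tuple[float, ...]
    verdict: str  # "shared" | "distinct"


def compare_flanks(
    a: MiteCandidate,
    b: MiteCandidate,
    flank_len: int = 50,
    cutoff: float = 0.5,
) -> FlankComparisonResult:
    """The eight-way flank comparison of candidate ``a`` against ``b``.

    Rows 1-4 compare flank against flank (both orientations); rows 5-8
    compare ``a``'s flanks against ``b``'s flank extended with the full
    element, covering boundaries annotated slightly inside the partner.
    Verdict is "shared" iff any normalized score >= ``cutoff``.
    """
    ext_right = b.seq + b.flank_right
    ext_left = b.flank_left + b.seq
    pairs = (
        (a.flank_right, b.flank_right),
        (a.flank_left, b.flank_left),
        (reverse_complement(a.flank_left), b.flank_right),
        (reverse_complement(a.flank_right), b.flank_left),
        (a.flank_right, ext_right),
        (a.flank_left, ext_left),
        (reverse_complement(a.flank_left), ext_right),
        (reverse_complement(a.flank_right), ext_left),
    )
    scores = tuple(_normalized(q, s, flank_len) for q, s in pairs)
    verdict = "shared" if any(sc >= cutoff for sc in scores) else "distinct"
    return FlankComparisonResult(
        pair=(a.candidate_id, b.candidate_id), scores=scores, verdict=verdict
    )


def pair_is_shared(
    a: MiteCandidate,
    b: MiteCandidate,
    flank_len: int = 50,
    cutoff: float = 0.5,
    audit: Optional[List[FlankComparisonResult]] = None,
) -> bool:
    """Order-independent shared-flank verdict for a member pair.

    Rows 1-4 are symmetric; the extended rows 5-8 are evaluated in both
    directions so that swapping ``a`` and ``b`` cannot change the verdict.
    """
    fwd = compare_flanks(a, b, flank_len, cutoff)
    rev_pairs = (
        (b.flank_right, a.seq + a.flank_right),
        (b.flank_left, a.flank_left + a.seq),
        (reverse_complement(b.flank_left), a.seq + a.flank_right),
        (reverse_complement(b.flank_right), a.flank_left + a.seq),
    )
    rev_scores = tuple(_normalized(q, s, flank_len) for q, s in rev_pairs)
    shared = fwd.verdict == "shared" or any(sc >= cutoff for sc in rev_scores)
    if audit is not None:
        audit.append(
            FlankComparisonResult(
                pair=fwd.pair,
                scores=fwd.scores + rev_scores,
                verdict="shared" if shared else "distinct",
            )
        )
    return shared


def count_distinct_individuals(
    family: Family,
    candidates_by_id: Dict[str, MiteCandidate],
    flank_len: int = 50,
    cutoff: float = 0.5,
    max_members: int = 2000,
    subsample: int = 200,
    seed: int = 0,
    audit: Optional[List[FlankComparisonResult]] = None,
) -> int:
    """Count members whose flanks diverge from *every* other member.

    Families larger than ``max_members`` compare each member against a
    seeded random subsample of ``subsample`` others instead of all-vs-all
    (a deliberate approximation for huge families).  Sets
    ``family.distinct_count`` and ``family.distinct_ids``.
    """
    members = [candidates_by_id[mid] for mid in family.member_ids]
    # Same-family members with overlapping spans are redundant calls of a
    # single locus (they sit at the same coordinates *and* cluster at the
    # identity threshold): keep the best-supported call per locus — highest
    # terminal-arm fidelity first (an exact TIR at the true boundary beats
    # the diluted arm a shifted call inherits), then longest verified TIR,
    # TSD and element — and flag the rest as non-distinct up front, so a
    # redundant call cannot drag every genuine member below the "differs
    # completely from all others" bar.
    def _arm_fidelity(c: MiteCandidate) -> float:
        floor = max(1, min(c.tir_len, len(c.seq) // 2))
        arm = terminal_arm_length(c.seq, 0, len(c.seq), floor)
        if arm is None:
            return 0.0
        u, matches = arm
        return matches / u

    order = sorted(
        range(len(members)),
        key=lambda i: (
            -_arm_fidelity(members[i]),
            -members[i].tir_len,
            -members[i].tsd_len,
            -(members[i].length),
            members[i].candidate_id,
        ),
    )
    redundant = set()
    accepted: List[MiteCandidate] = []
    for i in order:
        c = members[i]
        if any(
            c.chrom == k.chrom and c.start < k.end and k.start < c.end
            for k in accepted
        ):
            redundant.add(i)
        else:
            accepted.append(c)
    m = len(members)
    distinct_flags = [i not in redundant for i in range(m)]
    live = [i for i in range(m) if i not in redundant]
    if len(live) > max_members:
        rng = random.Random(seed * 1_000_003 + family.family_id)
        for i in live:
            others = [j for j in live if j != i]
            sample = rng.sample(others, min(subsample, len(others)))
            for j in sample:
                if pair_is_shared(
                    members[i], members[j], flank_len, cutoff, audit
                ):
                    distinct_flags[i] = False
                    break
    else:
        for ii, i in enumerate(live):
            for j in live[ii + 1 :]:
                if not (distinct_flags[i] or distinct_flags[j]):
                    continue
                if pair_is_shared(
                    members[i], members[j], flank_len, cutoff, audit
                ):
                    distinct_flags[i] = False
                    distinct_flags[j] = False
    family.distinct_ids = [
        members[i].candidate_id for i in range(m) if distinct_flags[i]
    ]
    family.distinct_count = len(family.distinct_ids)
    return family.distinct_count


def filter_families(
    families: Sequence[Family], min_copy_number: int = 3
) -> List[Family]:
    """Families whose distinct-individual count meets the copy threshold."""
    out = []
    for fam in families:
        if fam.distinct_count is None:
            raise ValueError(
                f"family {fam.family_id}: distinct_count not computed"
            )
        if fam.distinct_count >= min_copy_number:
            out.append(fam)
    return out
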