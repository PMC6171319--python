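"""Shared fixtures: brute-force oracles and sequence fixture builders."""

from __future__ import annotations

import random
from typing import List, Tuple

import numpy as np
import pytest

from mitefinder import MiteCandidate, reverse_complement


def brute_force_exact_inverted_repeats(
    seq: str, min_len: int, max_span: int
) -> List[Tuple[int, int, int, int]]:
    """All maximal exact inverted repeats in ``seq``, by diagonal scan.

    Returns canonical (left_start, left_end, right_start, right_end)
    tuples with non-overlapping arms and span <= ``max_span``.  O(n^2)
    over all diagonals of seq x reverse_complement(seq); independent of
    the seed-and-extend search it serves as an oracle for.
    """
    n = len(seq)
    if n == 0:
        return []
    S = np.frombuffer(seq.encode(), dtype=np.uint8)
    R = np.frombuffer(reverse_complement(seq).encode(), dtype=np.uint8)
    hits = set()
    for off in range(-(n - 1), n):
        if off >= 0:
            a0, b0, L = 0, off, n - off
        else:
            a0, b0, L = -off, 0, n + off
        if L < min_len:
            continue
        eq = (S[a0 : a0 + L] == R[b0 : b0 + L]).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], eq, [0]))))
        for st, en in zip(edges[::2], edges[1::2]):
            if en - st < min_len:
                continue
            qs, qe = a0 + int(st), a0 + int(en)
            ss, se = b0 + int(st), b0 + int(en)
            arm1, arm2 = (qs, qe), (n - se, n - ss)
            if arm2[0] < arm1[0]:
                arm1, arm2 = arm2, arm1
            if arm1[1] > arm2[0]:
                continue
            if arm2[1] - arm1[0] > max_span:
                continue
            hits.add(arm1 + arm2)
    return sorted(hits)


@pytest.fixture
def exact_ir_oracle():
    return brute_force_exact_inverted_repeats


def random_dna(rng: random.Random, n: int, gc: float = 0.5) -> str:
    w = ((1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2)
    return "".join(rng.choices("ACGT", weights=w, k=n))


@pytest.fixture
def dna():
    return random_dna


def make_candidate(
    chrom: str = "chr1",
    start: int = 1000,
    end: int = 1300,
    seq: str | None = None,
    tir_len: int = 12,
    tsd: str | None = "TA",
    flank_left: str | None = None,
    flank_right: str | None = None,
    rng_seed: int = 0,
) -> MiteCandidate:
    """Candidate factory with plausible defaults for unit tests."""
    rng = random.Random(rng_seed)
    if seq is None:
        arm = random_dna(rng, tir_len)
        internal = random_dna(rng, (end - start) - 2 * tir_len)
        seq = arm + internal + reverse_complement(arm)
    if flank_left is None:
        flank_left = random_dna(rng, 50)
    if flank_right is None:
        flank_right = random_dna(rng, 50)
    return MiteCandidate(
        chrom=chrom,
        start=start,
        end=end,
        seq=seq,
        tir_len=tir_len,
        left_tir=(start, start + tir_len),
        right_tir=(end - tir_len, end),
        tsd=tsd,
        flank_left=flank_left,
        flank_right=flank_right,
    )


@pytest.fixture
def candidate_factory():
    return make_candidate
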