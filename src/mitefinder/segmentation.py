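"""Chromosome segmentation into overlapping search windows.

The inverted-repeat search never needs to compare positions farther apart
than the maximum element length M, so each chromosome is cut into windows
of length 2M whose starts advance by M (50% overlap between consecutive
full windows).  Every genomic interval of length <= M is then wholly
contained in at least one window, which makes the windows independent,
embarrassingly-parallel work units: an element found in two overlapping
windows yields identical genome coordinates and is de-duplicated
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List


@dataclass(frozen=True)
class GenomeSegment:
    """A window of one chromosome. Coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad segment interval [{self.start}, {self.end})")
        if len(self.seq) != self.end - self.start:
            raise ValueError("segment sequence length does not match interval")


def make_segments(
    chrom: str, seq: str, mite_max_len: int, mite_min_len: int = 1
) -> List[GenomeSegment]:
    """Split a chromosome into windows of length 2*mite_max_len, step mite_max_len.

    Window i covers [i*M, min(i*M + 2M, L)).  A tail start s > 0 is emitted
    only while L - s >= M; shorter tails are already fully covered by the
    previous window (which ends at min(s + M, L) = L), so every interval of
    length <= M remains contained in some emitted window.  A chromosome
    shorter than ``mite_min_len`` cannot host a candidate and yields no
    segments; an empty chromosome yields an empty list.
    """
    if mite_min_len < 1 or mite_max_len < mite_min_len:
        raise ValueError("require 1 <= mite_min_len <= mite_max_len")
    L = len(seq)
    if L < mite_min_len:
        return []
    M = mite_max_len
    segments = []
    for s in range(0, L, M):
        if s > 0 and L - s < M:
            break
        e = min(s + 2 * M, L)
        segments.append(GenomeSegment(chrom, s, e, seq[s:e]))
    return segments
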