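"""Nucleotide-sequence primitives shared by every pipeline stage.

Sequences are handled as plain uppercase strings over the IUPAC nucleotide
alphabet.  FASTA input/output goes through Biopython's SeqIO and yields
``(name, sequence)`` pairs; reading is streaming (one record in memory at a
time), so whole-genome files never need to fit in memory twice.

Two small statistics defined here drive candidate filtering downstream:

* :func:`gc_content` — fraction of G/C bases, used to reject inverted
  repeats arising purely from extreme base composition.
* :func:`lcc_score` — local compositional complexity, the base-2 Shannon
  entropy of the mononucleotide composition (0 for a homopolymer, 2 for a
  perfectly uniform sequence).  Low-complexity DNA aligns promiscuously to
  its own reverse complement and is a classic source of false inverted
  repeats, so both whole segments and assembled elements are required to
  clear a complexity threshold.
"""

from __future__ import annotations

import math
import os
from typing import Iterable, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide one-letter codes accepted on input (after uppercasing).
IUPAC_NUCLEOTIDES = frozenset("ACGTNRYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def _validate(seq: str) -> str:
    """Uppercase ``seq`` and reject characters outside the IUPAC alphabet."""
    s = seq.upper()
    bad = set(s) - IUPAC_NUCLEOTIDES
    if bad:
        raise ValueError(
            "non-nucleotide characters in sequence: %r" % sorted(bad)
        )
    return s


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement.

    Ambiguity codes map to their IUPAC complements; ``N`` maps to ``N``.
    Applying the function twice returns the input (involution).
    """
    return _validate(seq).translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """Fraction of G and C bases, case-insensitive.

    ``N`` (and other ambiguity codes) count toward the denominator only,
    which is the conservative choice for assembly gaps.  Raises
    ``ValueError`` on an empty sequence.
    """
    s = _validate(seq)
    if not s:
        raise ValueError("gc_content of empty sequence")
    return (s.count("G") + s.count("C")) / len(s)


def lcc_score(seq: str) -> float:
    """Local compositional complexity: base-2 entropy of A/C/G/T frequencies.

    Frequencies are counts over the full sequence length, so ``N`` dilutes
    the score without contributing a term.  Range is [0, 2]: 0 for a
    homopolymer, 1 for a two-letter repeat such as (AT)n, 2 for a uniform
    composition.  Permutation-invariant by construction.
    """
    s = _validate(seq)
    if not s:
        raise ValueError("lcc_score of empty sequence")
    n = len(s)
    h = 0.0
    for base in "ACGT":
        f = s.count(base) / n
        if f > 0.0:
            h -= f * math.log2(f)
    return h


def read_fasta(path: str) -> Iterator[Tuple[str, str]]:
    """Stream ``(name, sequence)`` pairs from a FASTA file.

    Sequences are uppercased and validated against the IUPAC alphabet.
    Arbitrary line wrapping is accepted.  A missing file raises
    ``FileNotFoundError``; a file whose first record lacks a ``>`` header
    raises ``ValueError`` before any record is yielded.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with open(path) as fh:
        ch = fh.read(1)
        while ch and ch.isspace():
            ch = fh.read(1)
        if ch and ch != ">":
            raise ValueError(f"{path}: malformed FASTA (missing '>' header)")
    for rec in SeqIO.parse(path, "fasta"):
        yield rec.id, _validate(str(rec.seq))


def write_fasta(records: Iterable[Tuple[str, str]], path: str) -> None:
    """Write ``(name, sequence)`` pairs as FASTA, 60-column wrapped."""
    seq_records = (
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    )
    SeqIO.write(seq_records, path, "fasta")
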