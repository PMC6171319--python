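"""Synthetic test genomes with planted MITE families and decoys.

The generator writes an i.i.d. random background at a chosen GC content
and plants element families with the full structural signature the
pipeline looks for: a random terminal inverted-repeat (TIR) arm pair, a
random internal sequence (complexity >= 1 enforced at generation), an
exact target-site duplication (TSD) wrapped around every insertion, and —
because each insertion lands at an independently drawn position — flanking
context that is unrelated between copies.  Optional per-copy point
mutations hit the internal sequence only, so structural detection stays
exact while family identity degrades realistically.

Three decoy kinds probe the false-positive filters:

* ``low_complexity_ir`` — homopolymer or dinucleotide-repeat interiors
  between real arms (complexity / GC filters);
* ``shared_flank_duplication`` — one family copy duplicated *with* its
  flanks and TSD, emulating a segmental duplication (flank filter);
* ``lone_ir`` — a structurally perfect element with a single copy
  (minimum-copy-number filter).

Ground truth is machine-readable, and ``score_detection`` turns a
pipeline report into recall / precision / family purity at 90% reciprocal
overlap.
"""

from __future__ import annotations

import dataclasses
import json
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .sequence_core import gc_content, lcc_score, reverse_complement

_BASES = "ACGT"


@dataclass(frozen=True)
class FamilySpec:
    """One planted family: element length includes both TIR arms."""

    length: int = 300
    tir_len: int = 12
    copies: int = 4
    tsd: Optional[str] = None  # None: drawn per copy from tsd_choices
    mutation_rate: Optional[float] = None  # None: config default


@dataclass(frozen=True)
class SyntheticConfig:
    n_families: int = 5
    copies_per_family: int = 4
    element_len_range: Tuple[int, int] = (150, 400)
    tir_len_range: Tuple[int, int] = (10, 15)
    tsd_choices: Tuple[str, ...] = ("TA", "CTA", "GAT")
    genome_len: int = 200_000
    n_chroms: int = 1
    gc: float = 0.5
    mutation_rate: float = 0.0
    families: Optional[Tuple[FamilySpec, ...]] = None
    n_low_complexity: int = 0
    n_shared_flank_dups: int = 0
    n_lone_ir: int = 0
    margin: int = 80  # clear background kept around every insertion
    seed: int = 0


@dataclass(frozen=True)
class TruthElement:
    chrom: str
    start: int
    end: int
    family: str
    tir_len: int
    tsd: str
    provenance: str  # "independent" | "duplicated"


@dataclass(frozen=True)
class TruthDecoy:
    kind: str  # "low_complexity_ir" | "shared_flank_duplication" | "lone_ir"
    chrom: str
    start: int
    end: int


@dataclass
class SyntheticTruth:
    elements: List[TruthElement] = field(default_factory=list)
    decoys: List[TruthDecoy] = field(default_factory=list)
    config: Dict = field(default_factory=dict)

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(
                "record\tchrom\tstart\tend\tfamily\ttir_len\ttsd\tprovenance\n"
            )
            for e in self.elements:
                fh.write(
                    f"element\t{e.chrom}\t{e.start}\t{e.end}\t{e.family}\t"
                    f"{e.tir_len}\t{e.tsd}\t{e.provenance}\n"
                )
            for d in self.decoys:
                fh.write(
                    f"decoy\t{d.chrom}\t{d.start}\t{d.end}\t{d.kind}\t.\t.\t.\n"
                )

    @staticmethod
    def from_tsv(path: str) -> "SyntheticTruth":
        truth = SyntheticTruth()
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("record\t"):
                raise ValueError(f"{path}: not a truth TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if parts[0] == "element":
                    truth.elements.append(
                        TruthElement(
                            parts[1], int(parts[2]), int(parts[3]), parts[4],
                            int(parts[5]), parts[6], parts[7],
                        )
                    )
                else:
                    truth.decoys.append(
                        TruthDecoy(parts[4], parts[1], int(parts[2]),
                                   int(parts[3]))
                    )
        return truth


def _random_seq(rng: random.Random, n: int, gc: float) -> str:
    w_at, w_gc = (1.0 - gc) / 2.0, gc / 2.0
    return "".join(
        rng.choices(_BASES, weights=(w_at, w_gc, w_gc, w_at), k=n)
    )


def _mutate(seq: str, rate: float, rng: random.Random) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in _BASES if b != base])
    return "".join(out)


def _build_element(
    rng: random.Random, length: int, tir_len: int, gc: float
) -> Tuple[str, str, str]:
    """Return (arm, internal, element).

    Planted elements must satisfy every structural candidate filter by
    construction, so the draw is rejected until the element complexity is
    comfortably above 1 and the arm GC sits well inside the terminal-GC
    acceptance band (a short random arm can otherwise land outside it).
    """
    internal_len = length - 2 * tir_len
    if internal_len < 1:
        raise ValueError("element length must exceed twice the TIR length")
    for _ in range(1000):
        arm = _random_seq(rng, tir_len, gc)
        if not (0.2 <= gc_content(arm) <= 0.9):
            continue
        internal = _random_seq(rng, internal_len, gc)
        element = arm + internal + reverse_complement(arm)
        if lcc_score(element) >= 1.05:
            return arm, internal, element
    raise RuntimeError("could not draw a complex element; check GC setting")


class _Placer:
    """Non-overlapping insertion sites, margin-separated, bounded retries."""

    def __init__(
        self, rng: random.Random, chroms: List[List[str]], margin: int
    ) -> None:
        self.rng = rng
        self.chroms = chroms
        self.margin = margin
        self.occupied: List[List[Tuple[int, int]]] = [[] for _ in chroms]

    def place(self, insert: str) -> Tuple[int, int]:
        n = len(insert)
        for _ in range(2000):
            ci = self.rng.randrange(len(self.chroms))
            clen = len(self.chroms[ci])
            if clen < n + 2 * self.margin + 2:
                continue
            pos = self.rng.randrange(self.margin, clen - n - self.margin)
            lo, hi = pos - self.margin, pos + n + self.margin
            if any(s < hi and lo < e for s, e in self.occupied[ci]):
                continue
            self.chroms[ci][pos : pos + n] = list(insert)
            self.occupied[ci].append((pos, pos + n))
            return ci, pos
        raise RuntimeError(
            "could not place insertion without overlap; genome too crowded"
        )


def generate_genome(
    config: SyntheticConfig,
) -> Tuple[List[Tuple[str, str]], SyntheticTruth]:
    """Build a synthetic genome and its ground truth, deterministic per seed.

    Returns ``(records, truth)`` where records are ``(chrom_name, seq)``
    pairs.  Insertions overwrite background (genome length is fixed), so
    truth coordinates are final genome coordinates.
    """
    rng = random.Random(config.seed)
    per_chrom = config.genome_len // config.n_chroms
    chroms = [
        list(_random_seq(rng, per_chrom, config.gc))
        for _ in range(config.n_chroms)
    ]
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    placer = _Placer(rng, chroms, config.margin)
    truth = SyntheticTruth(config=dataclasses.asdict(config))

    specs = config.families
    if specs is None:
        specs = tuple(
            FamilySpec(
                length=rng.randint(*config.element_len_range),
                tir_len=rng.randint(*config.tir_len_range),
                copies=config.copies_per_family,
            )
            for _ in range(config.n_families)
        )
    total_planted = sum(s.length * s.copies for s in specs)
    if total_planted >= config.genome_len / 2:
        raise ValueError("total planted length must stay below genome_len/2")

    for fi, spec in enumerate(specs):
        arm, internal, _ = _build_element(
            rng, spec.length, spec.tir_len, config.gc
        )
        rate = (
            spec.mutation_rate
            if spec.mutation_rate is not None
            else config.mutation_rate
        )
        for _copy in range(spec.copies):
            body = _mutate(internal, rate, rng)
            element = arm + body + reverse_complement(arm)
            tsd = spec.tsd or rng.choice(config.tsd_choices)
            ci, pos = placer.place(tsd + element + tsd)
            start = pos + len(tsd)
            truth.elements.append(
                TruthElement(
                    chrom=names[ci],
                    start=start,
                    end=start + len(element),
                    family=f"fam{fi + 1}",
                    tir_len=spec.tir_len,
                    tsd=tsd,
                    provenance="independent",
                )
            )

    # segmental-duplication decoys: copy an element together with its TSDs
    # and 50 bp of flanking context to a fresh locus.
    flank = 50
    independents = list(truth.elements)
    for d in range(config.n_shared_flank_dups):
        src = independents[d % len(independents)]
        ci_src = names.index(src.chrom)
        k = len(src.tsd)
        lo = max(0, src.start - k - flank)
        hi = min(len(chroms[ci_src]), src.end + k + flank)
        block = "".join(chroms[ci_src][lo:hi])
        ci, pos = placer.place(block)
        start = pos + (src.start - lo)
        end = start + (src.end - src.start)
        truth.elements.append(
            TruthElement(
                chrom=names[ci],
                start=start,
                end=end,
                family=src.family,
                tir_len=src.tir_len,
                tsd=src.tsd,
                provenance="duplicated",
            )
        )
        truth.decoys.append(
            TruthDecoy("shared_flank_duplication", names[ci], start, end)
        )

    for d in range(config.n_low_complexity):
        arm = _random_seq(rng, 12, 0.5)
        body = "A" * 240 if d % 2 == 0 else "AT" * 120
        element = arm + body + reverse_complement(arm)
        tsd = rng.choice(config.tsd_choices)
        ci, pos = placer.place(tsd + element + tsd)
        start = pos + len(tsd)
        truth.decoys.append(
            TruthDecoy(
                "low_complexity_ir", names[ci], start, start + len(element)
            )
        )

    for _d in range(config.n_lone_ir):
        _, _, element = _build_element(rng, 250, 12, config.gc)
        tsd = rng.choice(config.tsd_choices)
        ci, pos = placer.place(tsd + element + tsd)
        start = pos + len(tsd)
        truth.decoys.append(
            TruthDecoy("lone_ir", names[ci], start, start + len(element))
        )

    records = [(names[i], "".join(chroms[i])) for i in range(config.n_chroms)]
    return records, truth


def write_config_echo(config: SyntheticConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=str)
        fh.write("\n")


@dataclass(frozen=True)
class DetectionScore:
    recall: float
    precision: float
    family_purity: float
    n_truth: int
    n_reported: int
    n_matched: int


def score_detection(
    truth: SyntheticTruth,
    reported: Sequence[Tuple[str, int, int, str]],
    min_reciprocal_overlap: float = 0.9,
) -> DetectionScore:
    """Match reported elements to planted truth at reciprocal overlap.

    ``reported`` holds ``(chrom, start, end, family_label)`` rows.  A
    reported element matches a truth element when their overlap covers at
    least ``min_reciprocal_overlap`` of both; matching is one-to-one,
    resolved greedily in coordinate order.  Purity is the fraction of
    reported families whose members all match, and match a single truth
    family.
    """
    unmatched = list(range(len(truth.elements)))
    assignments: List[Optional[int]] = []
    for chrom, start, end, _label in sorted(reported):
        best_ti, best_ov = None, 0.0
        for ti in unmatched:
            t = truth.elements[ti]
            if t.chrom != chrom:
                continue
            ov = min(end, t.end) - max(start, t.start)
            if ov <= 0:
                continue
            frac = min(ov / (end - start), ov / (t.end - t.start))
            if frac >= min_reciprocal_overlap and frac > best_ov:
                best_ti, best_ov = ti, frac
        assignments.append(best_ti)
        if best_ti is not None:
            unmatched.remove(best_ti)

    ordered = sorted(reported)
    n_truth = len(truth.elements)
    n_reported = len(ordered)
    n_matched = sum(1 for a in assignments if a is not None)
    recall = n_matched / n_truth if n_truth else 1.0
    precision = n_matched / n_reported if n_reported else 1.0

    by_family: Dict[str, List[Optional[int]]] = {}
    for (_c, _s, _e, label), ti in zip(ordered, assignments):
        by_family.setdefault(label, []).append(ti)
    pure = 0
    for tis in by_family.values():
        labels = {
            truth.elements[ti].family for ti in tis if ti is not None
        }
        if len(labels) == 1 and all(ti is not None for ti in tis):
            pure += 1
    purity = pure / len(by_family) if by_family else 1.0
    return DetectionScore(
        recall=recall,
        precision=precision,
        family_purity=purity,
        n_truth=n_truth,
        n_reported=n_reported,
        n_matched=n_matched,
    )
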