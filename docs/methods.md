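# Methods

## The detection model

`mitefinder` is a structure-based detector: it never consults a repeat
library, but searches for loci carrying the two defining signatures of a
miniature inverted-repeat transposable element (MITE) — terminal inverted
repeats (TIRs) and a target-site duplication (TSD) — and then requires
population-level evidence (several copies in divergent genomic contexts)
before calling a family. The underlying assumptions are:

* a MITE is 50–800 bp long, begins and ends with a TIR of at least 10 bp
  whose two arms align at ≥ 80% identity (mismatches and gaps allowed);
* insertion created an exact direct repeat of 2–10 bp immediately outside
  both ends (the TSD); elements whose TSD has decayed beyond recognition
  are out of reach by design (a `--no-require-tsd` switch exists but is
  not the tested operating point);
* copies of one family share ≥ 80% global sequence identity;
* true transposition places copies into unrelated flanking sequence,
  whereas segmental/tandem duplication carries flanks along — so flank
  divergence across ≥ 3 copies is demanded as evidence of mobility.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `mite_max_len` (M) | 800 | bp | window size 2M, window step M; span ceiling |
| `mite_min_len` | 50 | bp | element length floor |
| `tir_min_len` | 10 | nt | minimum TIR alignment length |
| `tir_min_identity` | 0.8 | — | minimum TIR alignment identity |
| `seed_len` | 8 | nt | exact seed for the inverted-repeat search |
| `xdrop` / `band` | 6 / 5 | score / cells | extension termination and gap band |
| `lcc_threshold` | 1.0 | bits/position | complexity floor (segments and elements) |
| `gc_min`, `gc_max` | 0.15, 0.95 | fraction | terminal-sequence GC band |
| `tsd_min_len`, `tsd_max_len` | 2, 10 | bp | TSD search range |
| `boundary_trim_window` | 60 | bp | cap on boundary refinement per side |
| `cluster_identity` | 0.80 | — | greedy clustering threshold |
| `flank_len` | 50 | bp | flank length for the divergence test |
| `flank_similarity_cutoff` | 0.5 | — | normalized local score above which flanks are "shared" |
| `min_copy_number` | 3 | copies | distinct individuals required per family |

**Segmentation.** Windows `[iM, iM+2M)` guarantee that every interval of
length ≤ M is wholly inside at least one window; consecutive full windows
overlap by exactly 50%. A tail start `s > 0` is emitted only while
`L − s ≥ M` — shorter tails are already covered by the previous window,
so the containment guarantee is preserved (proof: an interval `[a, b)`
with `b − a ≤ M` has `i = ⌊a/M⌋`; if window `iM` was dropped then
`L − iM < M`, and window `(i−1)M` ends at `min((i+1)M, L) = L ≥ b`).
Windows are independent work units; results are re-sorted after parallel
collection, so worker count never affects output.

**TIR search.** Each window is aligned against its own reverse complement
by seed-and-extend: exact 8-mer seeds, banded gapped X-drop extension
(match +1, mismatch −1, gap −2, X-drop 6, band ±5). Only the canonical
orientation of each seed is extended (`a + b + k ≤ n`), so every
biological arm pair is reported once and the trivial full self-alignment
never forms. Two engineering details matter in practice:

* *Record-ladder back-off.* The extension keeps every score-record
  endpoint, not only the maximum. A maximal extension sometimes gains a
  few points from a noisy tail whose mismatches sink the overall identity
  below 0.8; backing off to the best endpoint pair that satisfies the
  length and identity contract recovers the clean core alignment instead
  of discarding the hit.
* *Seed-frequency cap and rectangle skip.* k-mers occurring more than
  `max_kmer_hits` (50) times in a window are not used as seeds, and seeds
  falling inside an already-extended alignment are skipped; without
  these, self-complementary simple repeats such as (AT)n make the seed
  count quadratic.

**Candidate assembly and boundary refinement.** Filters run in order:
length, terminal GC, element complexity, boundary structure. Local
alignment provably over-extends across a palindromic TSD (TA — the
canonical Tourist-family TSD — equals its own reverse complement, so both
TSD copies align as part of the TIR), and occasionally far beyond it when
flanking noise happens to align. The element boundary is therefore *not*
taken from the alignment endpoints: all inward trims of the two outer hit
ends are scanned (each side bounded by its hit-arm length minus
`tir_min_len`, capped at `boundary_trim_window`; left/right trims may
differ by at most the alignment's gap count + 2), and a boundary pair
qualifies only if it carries **both** structures — an exact TSD and a
terminal inverted-repeat run of ≥ `tir_min_len` at ≥ 0.8 complement
identity whose outermost two base pairs match exactly (a TIR starts *at*
the boundary; anchoring the outermost bases stops symmetric shifts, which
preserve the arm-pairing diagonal, from faking the structure). Among
qualifying boundaries the one with the highest terminal-arm fidelity
wins, ties going to the outermost. The reported `tir_len` is the length
of this verified terminal run.

**Nesting resolution.** Two candidates are the same locus when their TIR
structures coincide: left arms overlapping and right arms overlapping,
each by at least half the shorter arm. Such groups are boundary variants
of one element; the longest is kept, ties broken by coordinates. A
candidate that merely shares one arm region with a longer overlapping
call — typically a chance alignment seeded by a real arm — is treated as
a different locus and both survive; the family-stage filters dispose of
the spurious one. (Collapsing on *any* arm overlap was tried and
measurably deletes genuine elements whenever background noise produces a
longer overlapping call.)

**Clustering.** Greedy centroid clustering in decreasing length order
(candidate id as tie-break): each candidate joins the first centroid with
global-alignment identity ≥ 0.80 on the better strand, else founds a new
family. Identity is matching columns over all alignment columns, gap
columns included, computed from a true global alignment (match +2,
mismatch −4, gap open −10, extend −1; end gaps penalized). Two exact
prefilters skip alignments that cannot reach the threshold: identity
≤ min(len)/max(len) and ≤ shared base composition / max(len), and a
banded edit-distance screen with cap (1 − t)(|a| + |b|) — any alignment
with identity ≥ t has at most that many non-matching columns. These
change nothing in the output and everything in the runtime: the search's
irreducible background of chance inverted repeats (a few hundred
candidates per 200 kb at the default thresholds) would otherwise dominate
the clustering cost.

**Flank filter.** For each ordered pair (a, b) of same-family members,
eight local alignments (match +1, mismatch −1, gap −2): right–right,
left–left, revcomp(left)–right, revcomp(right)–left, and the same four
queries against b's flank extended with the full element, which catches
members whose annotated boundary sits slightly inside the partner. Scores
are normalized by the attainable self-score min(len(query), 50); a pair
is *shared* if any normalized score ≥ 0.5 (unrelated random 50-mers score
≈ 0.2–0.3, conserved flanks ≈ 1). The four extended rows are also
evaluated with roles swapped, so the pair verdict is order-independent. A
member is a distinct individual iff non-shared against every other
member; families keep ≥ `min_copy_number` distinct individuals.

Before the pairwise comparisons, same-family members with overlapping
genomic spans are consolidated: they are redundant calls of one locus
(same coordinates *and* ≥ 80% identity), and the call with the highest
terminal-arm fidelity (then longest TIR, TSD, element) represents the
locus while the rest are flagged non-distinct. Without this, a single
redundant call — whose mis-annotated flank contains element sequence —
is "shared" with every genuine copy and the literal
all-against-all distinctness rule zeroes the whole family.

Families larger than `max_family_pairwise` (2000) members compare each
member against a seeded random subsample of 200 others instead of
all-vs-all; a deliberate approximation for repeat-dense genomes.

**Reporting.** The representative is the family centroid — deterministic
and guaranteed ≥ threshold identity to every member. The family TSD is
the modal member TSD, count ties broken lexicographically. Members that
failed distinctness are excluded from `all.fasta`/`mites.gff3` by default
(they are putative duplication artifacts) and written to an audit FASTA.
Coordinates are 0-based half-open internally and 1-based inclusive in
GFF3 only.

## Synthetic genomes

The generator emulates exactly the structure the detector assumes:
i.i.d. background at configurable GC; per family one random TIR arm and
internal sequence (element complexity ≥ 1 and arm GC within [0.2, 0.9]
enforced at construction, so every planted element passes the structural
filters by design); each copy wrapped in its own TSD (drawn from
TA/CTA/GAT — including the palindromic TA deliberately, because it is the
hard case for boundary determination) and placed at an independent,
margin-separated position, which makes flanks unrelated between copies.
Optional per-copy point mutations hit the internal sequence only, leaving
arms and TSD exact. Decoys: homopolymer/dinucleotide-repeat interiors
between real arms (complexity/GC filters), one copy duplicated *with* its
flanks (flank filter), and structurally perfect single-copy elements
(copy-number filter). Scoring matches reported to planted elements
one-to-one at ≥ 90% reciprocal overlap; family purity is the fraction of
reported families whose members all match a single planted family.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate about real genomes: decayed TIRs and TSDs,
insertions nested inside older elements, GC/composition heterogeneity
along chromosomes, and genuinely repetitive background beyond the planted
decoys. On real data the same pipeline will trade recall for precision at
these margins (a decayed TSD is an automatic rejection, for instance).

## Numerical and tie-breaking conventions

* All randomness flows from explicit integer seeds through dedicated
  generators; identical seeds give byte-identical FASTA, tables and GFF3.
* Extension ties prefer the shorter endpoint; boundary ties the outermost
  trim; clustering ties the first (creation-order) centroid; nesting ties
  the lexicographically first candidate; modal-TSD ties the
  lexicographically smallest string.
* `N` never matches anything in any alignment or repeat check, counts in
  GC and complexity denominators only, and disqualifies a TSD.
* Degenerate inputs: empty chromosomes yield no segments; scaffolds
  shorter than `mite_min_len` are skipped with a log line; an empty
  genome produces empty outputs and a warning; a zero-length flank at a
  chromosome edge scores 0 in every comparison.
* Identity comparisons use exact integer cross-multiplication where a
  ranking depends on them (terminal-arm fidelity).

## Problem sizes

The bundled tests and the acceptance script run on 80–200 kb synthetic
genomes with 3–5 families of 2–5 copies; a 200 kb default-parameter run
takes on the order of a second per worker. These sizes exercise every
stage — including the background of chance inverted repeats that the
family filters must remove — while keeping the whole suite fast;
development sweeps over 80 generator seeds at the 200 kb / 5×4 study
condition gave recall, precision and family purity of 1.0 throughout.

## Known limitations

* TSD required by default: elements with fully decayed TSDs are invisible
  at the tested operating point.
* The verified terminal-arm measure is ungapped; a TIR with an internal
  indel is found by the gapped search but its reported `tir_len` reflects
  the ungapped run at the boundary.
* The first two base pairs of a TIR must complement-match exactly for a
  boundary to qualify; an element whose outermost arm bases have mutated
  is called at a slightly shifted boundary or rejected.
* Greedy first-match clustering is order-deterministic but, like all
  greedy centroid schemes, can split a family whose diameter exceeds the
  threshold even though adjacent members are within it.
* Flank comparison against a subsample (families > 2000 members) makes
  `distinct_count` an estimate in repeat-dense genomes.
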