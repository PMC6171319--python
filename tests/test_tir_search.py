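import random

import pytest

from mitefinder import (
    GenomeSegment,
    InvertedRepeatHit,
    MiteCandidate,
    assemble_candidate,
    detect_tsd,
    find_inverted_repeats,
    resolve_nested,
    reverse_complement,
)
from mitefinder.tir_search import same_locus, terminal_arm_length

from conftest import brute_force_exact_inverted_repeats, make_candidate, random_dna


def _guarded(seq: str, positions: dict) -> str:
    out = list(seq)
    for i, ch in positions.items():
        out[i] = ch
    return "".join(out)


class TestFindInvertedRepeats:
    def test_planted_exact_arm_pair_found_once(self):
        """A single planted arm pair in clean background gives one hit."""
        arm = "ACGTTGCAGG"
        rng = random.Random(0)
        for attempt in range(200):
            bg = random_dna(rng, 600)
            seq = bg[:100] + arm + bg[100:400] + reverse_complement(arm) + bg[400:]
            # guard columns: two mismatch pairs flanking each arm end stop
            # the extension exactly at the planted boundaries
            # arms sit at [100,110) and [410,420); guard columns (two
            # mismatch pairs just outside each arm end) stop the extension
            # exactly at the planted boundaries
            seq = _guarded(
                seq, {98: "A", 99: "A", 420: "A", 421: "A",
                      110: "A", 111: "A", 408: "A", 409: "A"}
            )
            oracle = brute_force_exact_inverted_repeats(seq, 8, 800)
            if oracle == [(100, 110, 410, 420)]:
                break
        else:
            pytest.fail("could not build a clean fixture")
        seg = GenomeSegment("c", 0, len(seq), seq)
        hits = find_inverted_repeats(seg)
        assert len(hits) == 1
        h = hits[0]
        assert (h.left_start, h.left_end, h.right_start, h.right_end) == (
            100, 110, 410, 420,
        )
        assert h.aln_len == 10 and h.identity == 1.0

    def test_repeat_free_segment_yields_nothing(self):
        """No exact 8-mer inverted seed exists, so no hit can exist."""
        rng = random.Random(1)
        for attempt in range(500):
            seq = random_dna(rng, 300)
            if not brute_force_exact_inverted_repeats(seq, 6, 10_000):
                break
        else:
            pytest.fail("could not sample a repeat-free segment")
        seg = GenomeSegment("c", 0, len(seq), seq)
        assert find_inverted_repeats(seg) == []

    def test_single_mismatch_arm_identity(self):
        """12-column arms with one substitution align at identity 11/12."""
        rng = random.Random(7)
        arm = "ACGTTGCAGGAC"
        mutated = list(arm)
        mutated[2] = {"G": "T"}.get(mutated[2], "G")
        right = reverse_complement("".join(mutated))
        for attempt in range(300):
            bg = random_dna(rng, 500)
            # left arm [80,92), internal [92,312), right arm [312,324)
            seq = bg[:80] + arm + bg[80:300] + right + bg[300:]
            seq = _guarded(
                seq, {78: "A", 79: "A", 324: "A", 325: "A",
                      92: "A", 93: "A", 310: "A", 311: "A"}
            )
            # exact runs split by the substitution at arm offset 2
            if brute_force_exact_inverted_repeats(seq, 8, 800) == [
                (83, 92, 312, 321)
            ]:
                break
        else:
            pytest.fail("could not build mismatch fixture")
        seg = GenomeSegment("c", 0, len(seq), seq)
        hits = [
            h for h in find_inverted_repeats(seg, min_identity=0.8)
            if h.left_start <= 80 and h.right_end >= 324
        ]
        assert len(hits) == 1
        assert hits[0].aln_len == 12
        assert hits[0].identity == pytest.approx(11 / 12)

    def test_hits_respect_span_and_arm_order(self):
        rng = random.Random(3)
        arm = "TTGACCGGTACG"
        bg = random_dna(rng, 2000)
        # two insertions: one within span, one separated by > mite_max_len
        seq = (
            bg[:100] + arm + bg[100:400] + reverse_complement(arm)
            + bg[400:500] + arm + bg[500:1500] + reverse_complement(arm)
            + bg[1500:]
        )
        seg = GenomeSegment("c", 0, len(seq), seq)
        hits = find_inverted_repeats(seg, mite_max_len=800)
        for h in hits:
            assert h.left_start < h.left_end <= h.right_start < h.right_end
            assert h.right_end - h.left_start <= 800
            assert h.aln_len >= 10 and h.identity >= 0.8


class TestDetectTsd:
    def test_two_base_direct_repeat(self):
        chrom = "CCCCGGTA" + "ACGTTGCAGGTTTTTGCAACGT" + "TAGGCCCC"
        assert detect_tsd(chrom, 8, 8 + 22) == "TA"

    def test_absent_when_no_shared_boundary_repeat(self):
        chrom = "CCCCGGGG" + "ACGTACGTACGT" + "TTTTAAAA"
        assert detect_tsd(chrom, 8, 20) is None

    def test_longest_repeat_wins(self):
        chrom = "TTAACGT" + "GGGGCCCCGGGG" + "AACGTTT"
        assert detect_tsd(chrom, 7, 19) == "AACGT"

    def test_repeats_containing_n_never_qualify(self):
        chrom = "CCGNA" + "ACGTACGTACGT" + "GNACC"
        assert detect_tsd(chrom, 5, 17) is None

    def test_interval_validation(self):
        with pytest.raises(ValueError):
            detect_tsd("ACGT", 2, 10)


class TestTerminalArmLength:
    def test_exact_arm_measured(self):
        arm = "ACGTTGCAGGAC"
        chrom = "AAAA" + arm + "CCGGTT" * 20 + reverse_complement(arm) + "AAAA"
        res = terminal_arm_length(chrom, 4, len(chrom) - 4, 10)
        assert res is not None
        u, matches = res
        assert u >= 12 and matches >= 12

    def test_boundary_mismatch_rejected(self):
        # first base pair does not complement-match: no arm at this boundary
        chrom = "AAAA" + "A" + "ACGTTGCAGG" + "C" * 40 + reverse_complement("ACGTTGCAGG") + "A" + "AAAA"
        assert terminal_arm_length(chrom, 4, len(chrom) - 4, 10) is None


class TestAssembleCandidate:
    def _fixture(self, element_len=430, tir_len=15, tsd="TA", seed=11):
        rng = random.Random(seed)
        arm = random_dna(rng, tir_len)
        while not (0.2 <= sum(c in "GC" for c in arm) / tir_len <= 0.9):
            arm = random_dna(rng, tir_len)
        internal = random_dna(rng, element_len - 2 * tir_len)
        element = arm + internal + reverse_complement(arm)
        bg_l, bg_r = random_dna(rng, 100), random_dna(rng, 100)
        chrom = bg_l + tsd + element + tsd + bg_r
        start = len(bg_l) + len(tsd)
        end = start + element_len
        hit = InvertedRepeatHit(
            chrom="chr1", left_start=start, left_end=start + tir_len,
            right_start=end - tir_len, right_end=end,
            aln_len=tir_len, matches=tir_len, gaps=0, score=tir_len,
        )
        return hit, chrom, start, end

    def test_valid_element_with_ta_tsd(self):
        hit, chrom, start, end = self._fixture()
        cand, reason = assemble_candidate(hit, chrom)
        assert reason is None
        assert (cand.start, cand.end) == (start, end)
        assert cand.tsd == "TA"
        assert cand.seq == chrom[start:end]
        assert len(cand.flank_left) == 50 and len(cand.flank_right) == 50
        # flanks sit outside the TSD
        assert cand.flank_right == chrom[end + 2 : end + 52]

    def test_below_minimum_length_rejected(self):
        hit, chrom, start, end = self._fixture()
        short = InvertedRepeatHit(
            chrom="chr1", left_start=start, left_end=start + 12,
            right_start=start + 28, right_end=start + 40,
            aln_len=12, matches=12, gaps=0, score=12,
        )
        cand, reason = assemble_candidate(short, chrom, mite_min_len=50)
        assert cand is None and reason == "length"

    def test_homopolymer_element_rejected_as_low_complexity(self):
        rng = random.Random(2)
        arm = "ACGTTGCAGGAC"
        chrom = (
            random_dna(rng, 60) + "CTA" + arm + "A" * 376
            + reverse_complement(arm) + "CTA" + random_dna(rng, 60)
        )
        start = 63
        end = start + 12 + 376 + 12
        hit = InvertedRepeatHit(
            chrom="chr1", left_start=start, left_end=start + 12,
            right_start=end - 12, right_end=end,
            aln_len=12, matches=12, gaps=0, score=12,
        )
        cand, reason = assemble_candidate(hit, chrom)
        assert cand is None and reason == "complexity"

    def test_extreme_terminal_gc_rejected(self):
        rng = random.Random(3)
        arm = "G" * 12
        chrom = (
            random_dna(rng, 60) + "CTA" + arm + random_dna(rng, 300)
            + reverse_complement(arm) + "CTA" + random_dna(rng, 60)
        )
        start, end = 63, 63 + 12 + 300 + 12
        hit = InvertedRepeatHit(
            chrom="chr1", left_start=start, left_end=start + 12,
            right_start=end - 12, right_end=end,
            aln_len=12, matches=12, gaps=0, score=12,
        )
        cand, reason = assemble_candidate(hit, chrom)
        assert cand is None and reason == "gc"

    def test_missing_tsd_rejected_by_default_but_optional(self):
        rng = random.Random(4)
        arm = random_dna(rng, 14)
        element = arm + random_dna(rng, 250) + reverse_complement(arm)
        # no direct repeat planted around the element
        chrom = "C" * 60 + element + "G" * 60
        start, end = 60, 60 + len(element)
        hit = InvertedRepeatHit(
            chrom="chr1", left_start=start, left_end=start + 14,
            right_start=end - 14, right_end=end,
            aln_len=14, matches=14, gaps=0, score=14,
        )
        cand, reason = assemble_candidate(hit, chrom)
        assert cand is None and reason == "tsd"
        cand, reason = assemble_candidate(hit, chrom, require_tsd=False)
        assert reason is None
        assert cand.tsd is None and cand.tsd_len == 0
        assert (cand.start, cand.end) == (start, end)

    def test_palindromic_tsd_overshoot_is_trimmed_back(self):
        """A hit that over-extended across TA TSDs recovers the true span."""
        hit, chrom, start, end = self._fixture(tsd="TA", seed=23)
        over = InvertedRepeatHit(
            chrom="chr1", left_start=start - 2, left_end=hit.left_end,
            right_start=hit.right_start, right_end=end + 2,
            aln_len=hit.aln_len + 2, matches=hit.matches + 2, gaps=0,
            score=hit.score + 2,
        )
        cand, reason = assemble_candidate(over, chrom)
        assert reason is None
        assert (cand.start, cand.end) == (start, end)
        assert cand.tsd == "TA"

    def test_out_of_chromosome_hit_is_an_error(self):
        hit = InvertedRepeatHit(
            chrom="chr1", left_start=0, left_end=12, right_start=380,
            right_end=400, aln_len=12, matches=12, gaps=0, score=12,
        )
        with pytest.raises(ValueError):
            assemble_candidate(hit, "ACGT" * 20)


class TestResolveNested:
    def test_exact_duplicates_collapse(self):
        a = make_candidate(start=100, end=400)
        b = make_candidate(start=100, end=400)
        assert len(resolve_nested([a, b])) == 1

    def test_boundary_variants_keep_longer(self):
        a = make_candidate(start=100, end=400, tir_len=15)
        b = make_candidate(start=98, end=403, tir_len=15)
        kept = resolve_nested([a, b])
        assert [(c.start, c.end) for c in kept] == [(98, 403)]

    def test_disjoint_elements_both_kept(self):
        a = make_candidate(start=100, end=400)
        b = make_candidate(start=1000, end=1300)
        assert len(resolve_nested([a, b])) == 2

    def test_single_shared_arm_is_a_different_locus(self):
        """A longer overlapping call sharing only one arm region must not
        delete the shorter element (chance alignments seeded by a real arm
        would otherwise swallow genuine elements)."""
        a = make_candidate(start=300, end=600, tir_len=14)
        b = MiteCandidate(
            chrom="chr1", start=200, end=610, seq="A" * 410, tir_len=10,
            left_tir=(200, 210), right_tir=(600, 610), tsd="CT",
            flank_left="", flank_right="",
        )
        assert not same_locus(a, b)
        assert len(resolve_nested([a, b])) == 2

    def test_equal_length_tie_breaks_lexicographically(self):
        a = make_candidate(start=100, end=400)
        b = make_candidate(start=101, end=401)
        kept = resolve_nested([a, b])
        assert [(c.start, c.end) for c in kept] == [(100, 400)]

    def test_result_is_order_independent(self):
        rng = random.Random(9)
        cands = [
            make_candidate(start=s, end=s + 300, rng_seed=s)
            for s in (100, 98, 1000, 2000, 1998)
        ]
        baseline = [(c.chrom, c.start, c.end) for c in resolve_nested(cands)]
        for _ in range(5):
            rng.shuffle(cands)
            got = [(c.chrom, c.start, c.end) for c in resolve_nested(cands)]
            assert got == baseline

    def test_no_same_locus_pairs_survive(self):
        cands = [
            make_candidate(start=s, end=s + 300, rng_seed=s)
            for s in (100, 101, 103, 700, 702)
        ]
        kept = resolve_nested(cands)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert not same_locus(a, b)
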