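import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import planted_junction_genome, random_sequence
from spliceseek._dna import revcomp
from spliceseek.aligner import build_index
from spliceseek.io_formats import Genome, ReadRecord
from spliceseek.patterned import (
    Candidate,
    PatternParams,
    find_double_matches,
    generate_fragment_pairs,
    process_read,
    refine_boundary,
    refinement_cutoffs,
    rescue_single_match,
)


def lengths(pairs, double):
    return [(p.left_len, p.right_len) for p in pairs if p.double == double]


class TestGenerateFragmentPairs:
    def test_printed_pattern_for_36nt_reads(self, params):
        pairs = generate_fragment_pairs(36, params)
        assert lengths(pairs, True) == [(14, 22), (18, 18), (22, 14)]
        assert lengths(pairs, False) == [(6, 30), (10, 26), (26, 10), (30, 6)]

    def test_equal_halves_when_m_is_half_read(self, params):
        pairs = generate_fragment_pairs(28, params)
        assert lengths(pairs, True) == [(14, 14)]

    def test_too_short_read_yields_nothing(self, params):
        assert generate_fragment_pairs(11, params) == []

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        n=st.integers(16, 120),
        m=st.integers(8, 24),
        s=st.integers(1, 6),
        min_local=st.integers(4, 8),
    )
    def test_cutoff_grid_property(self, n, m, s, min_local):
        if min_local > m or n < 2 * min_local:
            return
        p = PatternParams(m=m, s=s, min_local=min_local)
        pairs = generate_fragment_pairs(n, p)
        cutoffs = [fp.p for fp in pairs]
        # cutoffs lie on the arithmetic grid through m, cover exactly the
        # min_local-feasible range, and double-alignable ones are exactly
        # {m + i*s <= n - m}
        assert cutoffs == sorted(cutoffs)
        assert all((c - m) % s == 0 for c in cutoffs)
        assert all(min(c, n - c) >= min_local for c in cutoffs)
        expected_double = [
            c for c in range(m, n - m + 1) if (c - m) % s == 0
        ]
        assert [fp.p for fp in pairs if fp.double] == expected_double
        for fp in pairs:
            assert fp.left_len + fp.right_len == n
            assert fp.left_alignable == (fp.p >= m)
            assert fp.right_alignable == (n - fp.p >= m)


class TestFindDoubleMatches:
    def test_planted_junction_recovered_by_even_split(self, params):
        genome, (d, a), tx = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        # read centred on the junction: 18 nt on each exon
        jpos = 400  # junction offset inside the transcript
        read = tx[jpos - 18 : jpos + 18]
        cands = find_double_matches(read, generate_fragment_pairs(36, params), idx, genome, params)
        # the even split brackets the true intron and refines exactly
        match = [c for c in cands if c.intron_length == a - d]
        assert match
        refs = [refine_boundary(c, genome, params) for c in match]
        assert any(
            (r.donor_end, r.acceptor_start, r.mismatches) == (d, a, 0) for r in refs
        )

    def test_exonic_read_produces_no_candidate(self, params):
        genome, _, tx = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        read = tx[100:136]  # fully inside exon 1
        cands = find_double_matches(read, generate_fragment_pairs(36, params), idx, genome, params)
        assert cands == []

    def test_small_overlap_has_no_double_alignable_pair(self, params):
        genome, _, tx = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        read = tx[400 - 31 : 400 + 5]  # 5 nt on the right exon
        cands = find_double_matches(read, generate_fragment_pairs(36, params), idx, genome, params)
        assert cands == []


class TestRefineBoundary:
    def test_evaluated_cutoffs_are_printed_alternative_pairs(self, params):
        assert refinement_cutoffs(14, 2, 36) == [12, 13, 14, 15, 16]
        alt = [(p, 36 - p) for p in refinement_cutoffs(14, 2, 36) if p != 14]
        assert alt == [(12, 24), (13, 23), (15, 21), (16, 20)]

    def test_recovers_true_split_one_off(self, params):
        genome, (d, a), tx = planted_junction_genome(seed=6)
        read = tx[400 - 15 : 400 + 21]  # true cutoff at 15
        cand = Candidate(
            chromosome="chr1",
            left_start=d - 15,
            right_end=a + 21,
            p=14,
            seq=read,
            orient="+",
        )
        ref = refine_boundary(cand, genome, params)
        assert ref.p_star == 15
        assert (ref.donor_end, ref.acceptor_start) == (d, a)
        assert ref.mismatches == 0
        assert ref.evaluated_cutoffs == (12, 13, 14, 15, 16)

    def test_never_increases_mismatches(self, params):
        genome, (d, a), tx = planted_junction_genome(seed=8)
        arr = genome.sequences["chr1"]
        for true_cut in (13, 14, 15, 16):
            read = tx[400 - true_cut : 400 + (36 - true_cut)]
            ls = d - true_cut
            re_ = a + (36 - true_cut)
            cand = Candidate("chr1", ls, re_, 14, read, "+")
            ref = refine_boundary(cand, genome, params)
            # mismatches at the unrefined cutoff, counted directly
            base = sum(
                x != y for x, y in zip(read[:14], arr[ls : ls + 14])
            ) + sum(
                x != y for x, y in zip(read[14:], arr[re_ - 22 : re_])
            )
            assert ref.mismatches <= base

    def test_mismatch_tie_broken_by_canonical_signal(self):
        # the last base of exon 1 equals the first intron base, so cutoffs
        # 13 and 14 both align perfectly; only 13 exposes GT..AG
        rng = np.random.default_rng(33)
        exon1 = random_sequence(198, rng) + "AG"
        intron = "GT" + random_sequence(56, rng) + "AG"
        exon2 = "GT" + random_sequence(198, rng)
        # read cut at 13 ends "...A"; shift to 14 consumes the "G" that also
        # starts both the intron and exon 2
        genome = Genome({"chr1": random_sequence(100, rng) + exon1 + intron + exon2 + random_sequence(100, rng)})
        d = 100 + 200
        a = d + 60
        tx_left = genome.sequences["chr1"][100 : 100 + 200]
        tx_right = genome.sequences["chr1"][a : a + 200]
        read = tx_left[-13:] + tx_right[:23]
        params = PatternParams(max_intron=20_000)
        cand = Candidate("chr1", d - 13, a + 23, 14, read, "+")
        ref = refine_boundary(cand, genome, params)
        assert ref.mismatches == 0
        assert (ref.donor_end, ref.acceptor_start) == (d, a)


class TestRescueSingleMatch:
    def test_anchor_26_places_remaining_10(self, params):
        genome, (d, a), tx = planted_junction_genome(seed=12)
        idx = build_index(genome, 8)
        read = tx[400 - 26 : 400 + 10]  # 26 nt on the left exon, 10 on the right
        pairs = generate_fragment_pairs(36, params)
        assert find_double_matches(read, pairs, idx, genome, params) == []
        cands = rescue_single_match(read, pairs, idx, genome, params)
        assert any(c.p == 26 and len(c.seq) - c.p == 10 for c in cands)
        best = [c for c in cands if c.intron_length == a - d]
        assert best and refine_boundary(best[0], genome, params).donor_end == d

    def test_no_unique_fragment_yields_nothing(self, params):
        # a read unrelated to the genome
        rng = np.random.default_rng(44)
        genome, _, _ = planted_junction_genome(seed=12)
        idx = build_index(genome, 8)
        read = random_sequence(36, rng)
        pairs = generate_fragment_pairs(36, params)
        assert rescue_single_match(read, pairs, idx, genome, params) == []

    def test_mate_span_clips_search_window(self, params):
        # plant the remainder's exact sequence twice: once at the true
        # acceptor and once far downstream; the mate span excludes the decoy
        rng = np.random.default_rng(55)
        exon1 = random_sequence(400, rng)
        intron = "GT" + random_sequence(196, rng) + "AG"
        exon2 = random_sequence(400, rng)
        tail = random_sequence(3000, rng)
        seq = random_sequence(500, rng) + exon1 + intron + exon2 + tail
        d = 500 + 400
        a = d + 200
        read = exon1[-26:] + exon2[:10]
        decoy_pos = a + 1500
        seq = seq[:decoy_pos] + exon2[:10] + seq[decoy_pos + 10 :]
        genome = Genome({"chr1": seq})
        idx = build_index(genome, 8)
        pairs = generate_fragment_pairs(36, params)
        mate = ("chr1", a + 50, a + 100)  # mate 50-100 bp past the acceptor
        cands = rescue_single_match(
            read, pairs, idx, genome, params, mate_anchor=mate
        )
        ends = {c.right_end for c in cands if c.p == 26}
        assert a + 10 in ends
        assert decoy_pos + 10 not in ends
        # without the mate constraint the decoy is also enumerated
        cands_all = rescue_single_match(read, pairs, idx, genome, params)
        assert decoy_pos + 10 in {c.right_end for c in cands_all if c.p == 26}


class TestProcessRead:
    def test_single_double_match_scored_and_marked_best(self, params, trained_model):
        genome, (d, a), tx = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        read = ReadRecord("r1", tx[400 - 18 : 400 + 18], "I" * 36)
        juncs = process_read(read, idx, genome, params, trained_model)
        best = [j for j in juncs if j.is_best]
        assert len(best) == 1
        assert (best[0].donor_end, best[0].acceptor_start) == (d, a)
        assert 0 < best[0].score < 1
        assert best[0].signal_class == "GT-AG"
        assert best[0].strand == "+"

    def test_no_candidates_returns_empty(self, params, trained_model):
        genome, _, _ = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        read = ReadRecord("r", random_sequence(36, np.random.default_rng(1)), "I" * 36)
        assert process_read(read, idx, genome, params, trained_model) == []

    def test_short_read_skipped(self, params, trained_model):
        genome, _, _ = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        read = ReadRecord("r", "ACGTACGTAC", "I" * 10)
        assert process_read(read, idx, genome, params, trained_model) == []

    def test_minus_strand_read_recovers_same_intron(self, params, trained_model):
        genome, (d, a), tx = planted_junction_genome(seed=4)
        idx = build_index(genome, 8)
        read = ReadRecord("r", revcomp(tx[400 - 18 : 400 + 18]), "I" * 36)
        juncs = process_read(read, idx, genome, params, trained_model)
        best = [j for j in juncs if j.is_best][0]
        assert (best.donor_end, best.acceptor_start) == (d, a)
        assert best.orient == "-"

    def test_fragment_reconstruction_invariant(self, params):
        # every generated pair splits the read into a perfect partition
        rng = np.random.default_rng(3)
        for n in (30, 36, 50, 75):
            read = random_sequence(n, rng)
            for fp in generate_fragment_pairs(n, params):
                assert read[: fp.p] + read[fp.p :] == read
                assert len(read[: fp.p]) == fp.left_len
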