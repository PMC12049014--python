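import numpy as np
import pytest

from rhtmap import (
    MapParams,
    SequenceRecord,
    align_candidate,
    align_rowcol,
    chain_anchors,
    find_anchors,
    gap_cost,
    map_read,
    reverse_complement,
    score_cigar,
    to_sam_record,
)
from rhtmap.read_mapper import Anchor, AnchorChain


class TestFindAnchors:
    def test_repeated_kmer_gives_two_anchors(self):
        anchors = find_anchors("ACGTACGT", "ACGT", k=4)
        assert [(a.read_pos, a.ref_pos) for a in anchors] == [(0, 0), (0, 4)]

    def test_no_shared_kmer(self):
        assert find_anchors("AAAAAAA", "CCCC", k=4) == []

    def test_full_length_anchor(self):
        anchors = find_anchors("ACGT", "ACGT", k=4)
        assert [(a.read_pos, a.ref_pos) for a in anchors] == [(0, 0)]

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(5)
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 40))
        k = 3
        expected = sorted(
            (qp, rp)
            for qp in range(len(read) - k + 1)
            for rp in range(len(region) - k + 1)
            if read[qp : qp + k] == region[rp : rp + k]
        )
        got = [(a.read_pos, a.ref_pos) for a in find_anchors(region, read, k)]
        assert got == expected


class TestChainAnchors:
    def test_collinear_equal_offsets_chained_free(self, scheme):
        chain = chain_anchors([Anchor(0, 0, 3), Anchor(5, 5, 3)], scheme)
        assert len(chain.anchors) == 2
        assert chain.chain_score == 2 * 3 * scheme.match

    def test_costly_edge_prefers_single_anchor(self, scheme):
        # chaining both scores 12 - gap_cost(6) = -4 < 6 for one anchor
        chain = chain_anchors([Anchor(0, 0, 3), Anchor(3, 9, 3)], scheme)
        assert len(chain.anchors) == 1
        assert chain.chain_score == 3 * scheme.match

    def test_crossing_anchors_not_chained(self, scheme):
        chain = chain_anchors([Anchor(0, 4, 3), Anchor(4, 0, 3)], scheme)
        assert len(chain.anchors) == 1

    def test_empty_input(self, scheme):
        chain = chain_anchors([], scheme)
        assert (chain.anchors, chain.chain_score) == ([], 0)

    def test_matches_exhaustive_chain_enumeration(self, scheme):
        """DP equals brute-force enumeration of all anchor subsets."""
        from itertools import combinations

        rng = np.random.default_rng(9)
        k = 3
        for _ in range(20):
            n = int(rng.integers(1, 7))
            anchors = sorted(
                (Anchor(int(rng.integers(0, 30)), int(rng.integers(0, 30)), k) for _ in range(n)),
                key=lambda a: (a.read_pos, a.ref_pos),
            )
            best = 0
            for size in range(1, n + 1):
                for sub in combinations(anchors, size):
                    ok = all(
                        v.read_pos >= u.read_pos + k and v.ref_pos >= u.ref_pos + k
                        for u, v in zip(sub, sub[1:])
                    )
                    if not ok:
                        continue
                    score = size * k * scheme.match
                    for u, v in zip(sub, sub[1:]):
                        delta = abs(
                            (v.read_pos - u.read_pos - k) - (v.ref_pos - u.ref_pos - k)
                        )
                        if delta:
                            score -= gap_cost(delta, scheme)
                    best = max(best, score)
            assert chain_anchors(anchors, scheme).chain_score == best


class TestAlignCandidate:
    def test_read_equals_region_all_match(self, scheme):
        region = "ACGTACGTACGT"
        chain = chain_anchors(find_anchors(region, region, 4), scheme)
        res = align_candidate(region, region, chain, scheme)
        assert res.cigar == [(12, "M")]
        assert res.score == 12 * scheme.match
        assert res.t_span == (0, 12)

    def test_single_substitution_matches_full_rowcol(self, scheme):
        rng = np.random.default_rng(7)
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, 80))
        read = region[:40] + ("A" if region[40] != "A" else "C") + region[41:]
        chain = chain_anchors(find_anchors(region, read, 8), scheme)
        res = align_candidate(region, read, chain, scheme)
        assert res.score == align_rowcol(region, read, scheme).score
        assert res.score == 80 * scheme.match - scheme.match + scheme.mismatch

    def test_flank_trimming_adjusts_target_span(self, scheme):
        region = "TTTTTTTTTT" + "ACGTACGTACGT" + "GGGGGGGGGG"
        read = "ACGTACGTACGT"
        chain = chain_anchors(find_anchors(region, read, 6), scheme)
        res = align_candidate(region, read, chain, scheme)
        assert res.cigar == [(12, "M")]
        assert res.t_span == (10, 22)
        assert res.score == 12 * scheme.match  # flanks trimmed, not penalized

    def test_score_recomputed_from_cigar(self, scheme):
        rng = np.random.default_rng(13)
        region = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        read = region[20:100]
        chain = chain_anchors(find_anchors(region, read, 9), scheme)
        res = align_candidate(region, read, chain, scheme)
        t0, t1 = res.t_span
        assert score_cigar(res.cigar, region[t0:t1], read, scheme) == res.score

    def test_inconsistent_chain_rejected(self, scheme):
        with pytest.raises(ValueError):
            align_candidate("ACGT", "ACGT", AnchorChain([Anchor(0, 10, 4)], 8), scheme)


class TestMapRead:
    def test_exact_substring_maps_to_origin(self, small_ref_index):
        ref, rht = small_ref_index
        read = SequenceRecord(id="fwd", sequence=ref.sequence[1000:3000])
        m = map_read(rht, ref, read)
        assert m.is_mapped and m.strand == "+"
        assert m.sam_pos == 1001
        assert m.best.cigar == [(2000, "M")]

    def test_reverse_complement_maps_same_locus(self, small_ref_index):
        ref, rht = small_ref_index
        read = SequenceRecord(
            id="rev", sequence=reverse_complement(ref.sequence[1000:3000])
        )
        m = map_read(rht, ref, read)
        assert m.is_mapped and m.strand == "-"
        assert m.sam_pos == 1001
        rec = to_sam_record(m, read, rht.ref_name)
        assert rec.flag & 0x10
        assert rec.seq == ref.sequence[1000:3000]

    def test_foreign_read_unmapped(self, small_ref_index):
        ref, rht = small_ref_index
        rng = np.random.default_rng(987)
        read = SequenceRecord(
            id="alien", sequence="".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        )
        m = map_read(rht, ref, read)
        # random 2 kb shares no 11-mer hits at the indexed step with high
        # probability; if it does, the alignment score stays far below a
        # genuine locus
        if m.is_mapped:
            assert m.best.score < 1000
        rec = to_sam_record(m, read, rht.ref_name)
        rec.validate()

    def test_deterministic_and_sam_consistent(self, small_ref_index, scheme):
        ref, rht = small_ref_index
        read = SequenceRecord(id="x", sequence=ref.sequence[5000:6500])
        m1 = map_read(rht, ref, read)
        m2 = map_read(rht, ref, read)
        assert (m1.sam_pos, m1.strand, m1.best.score, m1.best.cigar) == (
            m2.sam_pos,
            m2.strand,
            m2.best.score,
            m2.best.cigar,
        )
        rec = to_sam_record(m1, read, rht.ref_name, read_index=3)
        rec.validate()
        t0, t1 = m1.best.t_span
        region = ref.sequence[m1.region.ref_start : m1.region.ref_end]
        assert score_cigar(m1.best.cigar, region[t0:t1], read.sequence, scheme) == rec.score
        assert 0 <= m1.mapq <= 60
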