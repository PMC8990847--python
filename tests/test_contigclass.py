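"""Novel-sequence construction: filtering, classification, clustering, merging."""

import numpy as np
import pytest

from panpav import contigclass as cc
from panpav._intervals import complement, covered_length, merge_intervals

TH = cc.Thresholds()


def brute_force_unaligned(contig_len, intervals, min_len):
    """Per-base aligned/unaligned scan; returns unaligned segments >= min_len."""
    covered = np.zeros(contig_len, dtype=bool)
    for s, e in intervals:
        covered[s:e] = True
    segments = []
    start = None
    for i in range(contig_len + 1):
        free = i < contig_len and not covered[i]
        if free and start is None:
            start = i
        elif not free and start is not None:
            if i - start >= min_len:
                segments.append((start, i))
            start = None
    return segments


class TestIntervalPrimitives:
    def test_merge_and_complement_match_per_base_scan(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            L = int(rng.integers(1, 300))
            ivs = []
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(0, L))
                e = int(rng.integers(s + 1, L + 1))
                ivs.append((s, e))
            covered = np.zeros(L, dtype=bool)
            for s, e in ivs:
                covered[s:e] = True
            assert covered_length(ivs, 0, L) == int(covered.sum())
            gaps = complement(ivs, 0, L)
            expect = brute_force_unaligned(L, ivs, 1)
            assert gaps == expect
            # merged intervals are disjoint, sorted and cover the same bases
            merged = merge_intervals(ivs)
            assert all(e1 < s2 for (_, e1), (s2, _) in zip(merged, merged[1:]))
            assert covered_length(merged, 0, L) == int(covered.sum())


class TestFilters:
    def test_short_contig_boundary(self):
        contigs = {"a": "A" * 499, "b": "A" * 500, "c": "A" * 501}
        assert set(cc.filter_short_contigs(contigs)) == {"b", "c"}

    def test_short_contig_degenerate(self):
        assert cc.filter_short_contigs({}) == {}
        contigs = {"a": "A" * 10}
        assert cc.filter_short_contigs(contigs, 0) == contigs

    @pytest.mark.parametrize(
        "identity,length,kept",
        [(95.0, 400, True), (89.0, 400, False), (95.0, 250, False),
         (90.0, 400, False), (90.01, 300, True), (90.01, 299, False)],
    )
    def test_reliable_alignment_boundaries(self, identity, length, kept):
        """Identity strictly above 90%, contig-side length at least 300 bp."""
        rec = cc.AlignmentRecord("c1", 0, length, "chr1", 0, length, identity)
        assert (cc.filter_reliable_alignments([rec], TH) == [rec]) is kept

    def test_empty_records(self):
        assert cc.filter_reliable_alignments([], TH) == []

    def test_malformed_record_names_contig(self):
        with pytest.raises(ValueError, match="c9"):
            cc.AlignmentRecord("c9", 100, 100, "chr1", 0, 100, 95.0)


class TestClassifyContig:
    def rec(self, cid, s, e):
        return cc.AlignmentRecord(cid, s, e, "chr1", s, e, 95.0)

    def test_partial_with_long_tail(self):
        got = cc.classify_contig("c", 2000, [self.rec("c", 0, 1200)], TH)
        assert got.status == "partially_unaligned"
        assert got.unaligned_segments == ((1200, 2000),)

    def test_short_gap_is_aligned(self):
        got = cc.classify_contig("c", 2000, [self.rec("c", 0, 900), self.rec("c", 1100, 2000)], TH)
        assert got.status == "aligned"
        assert got.unaligned_segments == ()

    def test_no_records_fully_unaligned(self):
        got = cc.classify_contig("c", 2000, [], TH)
        assert got.status == "fully_unaligned"

    def test_record_exceeding_bounds_errors(self):
        with pytest.raises(ValueError, match="c"):
            cc.classify_contig("c", 500, [self.rec("c", 0, 600)], TH)

    def test_foreign_record_rejected(self):
        with pytest.raises(ValueError, match="other"):
            cc.classify_contig("c", 2000, [self.rec("other", 0, 600)], TH)

    def test_matches_per_base_oracle_on_random_contigs(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            L = int(rng.integers(600, 5000))
            n_aln = int(rng.integers(0, 10))
            recs = []
            for _ in range(n_aln):
                s = int(rng.integers(0, L - 300))
                e = int(rng.integers(s + 300, min(L, s + 2000) + 1))
                recs.append(self.rec("c", s, e))
            got = cc.classify_contig("c", L, recs, TH)
            expect = brute_force_unaligned(L, [(r.contig_start, r.contig_end) for r in recs], 500)
            if not recs:
                assert got.status == "fully_unaligned"
            elif expect:
                assert got.status == "partially_unaligned"
                assert list(got.unaligned_segments) == expect
            else:
                assert got.status == "aligned"


class TestExtraction:
    def test_extract_counts_and_lengths(self):
        contigs = {"full": "A" * 1000, "part": "C" * 2000}
        cls = {
            "full": cc.ContigClassification("full", "fully_unaligned"),
            "part": cc.ContigClassification("part", "partially_unaligned", ((1200, 2000),)),
        }
        seqs = cc.extract_novel_sequences(contigs, cls)
        assert len(seqs) == 2
        assert sum(map(len, seqs.values())) == 1800
        assert "part:1200-2000" in seqs

    def test_aligned_only_empty(self):
        cls = {"a": cc.ContigClassification("a", "aligned")}
        assert cc.extract_novel_sequences({"a": "A" * 600}, cls) == {}

    def test_provenance_id_round_trip(self):
        assert cc.parse_segment_id("ctg7:1200-2000") == ("ctg7", 1200, 2000)
        assert cc.parse_segment_id("plaincontig") is None


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def mutate(rng, seq, rate):
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


class TestRedundancy:
    def test_identical_sequences_cluster(self):
        rng = np.random.default_rng(1)
        s = random_seq(rng, 1000)
        reps, assign = cc.remove_redundancy({"a": s, "b": s})
        assert len(reps) == 1
        assert len(set(assign.values())) == 1

    def test_unrelated_sequences_stay_apart(self):
        rng = np.random.default_rng(2)
        reps, _ = cc.remove_redundancy({"a": random_seq(rng, 1000), "b": random_seq(rng, 1000)})
        assert len(reps) == 2

    def test_subsequence_joins_longer_representative(self):
        rng = np.random.default_rng(3)
        s = random_seq(rng, 1200)
        reps, assign = cc.remove_redundancy({"long": s, "sub": s[300:900]})
        assert set(reps) == {"long"}
        assert assign["sub"] == "long"

    def test_reverse_complement_clusters(self):
        rng = np.random.default_rng(4)
        s = random_seq(rng, 800)
        rc = s.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        reps, _ = cc.remove_redundancy({"fwd": s, "rev": rc})
        assert len(reps) == 1

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        base = random_seq(rng, 1500)
        seqs = {
            "a": base,
            "b": mutate(rng, base, 0.02),
            "c": random_seq(rng, 900),
            "d": random_seq(rng, 700),
        }
        reps, _ = cc.remove_redundancy(seqs)
        reps2, assign2 = cc.remove_redundancy(reps)
        assert reps2 == reps
        assert all(assign2[r] == r for r in reps)

    def test_kmer_identity_tracks_alignment_identity(self):
        """The containment estimator should land within a few points of the
        edit-distance identity for lightly diverged sequences."""
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(6)
        for rate in (0.0, 0.01, 0.03):
            a = random_seq(rng, 2000)
            b = mutate(rng, a, rate)
            _, est = cc.kmer_identity(a, b, k=15)
            aligned = edlib.align(a, b, task="distance")
            true_ident = 100.0 * (1 - aligned["editDistance"] / len(a))
            assert abs(est - true_ident) < 5.0


class TestTaxonomyAndMerge:
    def test_taxonomy_rule(self):
        seqs = {"s1": "A" * 600, "s2": "C" * 600, "s3": "G" * 600}
        labels = {"s1": "Viridiplantae", "s2": "Bacteria", "s3": "unlabelled"}
        assert set(cc.filter_taxonomy(seqs, labels)) == {"s1", "s3"}

    def test_taxonomy_identity_cases(self):
        seqs = {"s1": "A" * 600, "s2": "C" * 600}
        assert cc.filter_taxonomy(seqs, {"s1": "Eukaryota", "s2": "Viridiplantae"}) == seqs
        assert cc.filter_taxonomy(seqs, {}) == seqs

    def test_build_pangenome_counts_and_length(self):
        rng = np.random.default_rng(7)
        ref = {f"chr{i}": random_seq(rng, 500) for i in range(12)}
        novel = {f"nov{i}": random_seq(rng, 300) for i in range(10)}
        pan, prov = cc.build_pangenome(ref, novel)
        assert len(pan) == 22
        assert (prov["source"] == "additional").sum() == 10
        assert sum(map(len, pan.values())) == sum(map(len, ref.values())) + sum(map(len, novel.values()))

    def test_build_pangenome_empty_novel(self):
        ref = {"chr1": "ACGT" * 100}
        pan, _ = cc.build_pangenome(ref, {})
        assert pan == ref

    def test_id_collision_errors(self):
        with pytest.raises(ValueError, match="collision"):
            cc.build_pangenome({"x": "ACGT"}, {"x": "ACGT"})


class TestPlantedRecovery:
    def test_full_pipeline_recovers_planted_truth(self, sequence_bundle):
        b = sequence_bundle
        novel, cls, _ = cc.build_novel_set(b.contigs, b.alignments, b.taxonomy, b.reference)
        truth = b.contig_truth.set_index("contig_id")
        for cid, row in truth.iterrows():
            if row["category"] == "novel":
                assert cls[cid].status == "fully_unaligned"
                assert cid in novel
            elif row["category"] == "contaminant":
                assert cid not in novel
            elif row["category"] == "reference":
                assert cls[cid].status == "aligned"
                assert cid not in novel
            elif row["category"] == "partial":
                segs = cls[cid].unaligned_segments
                assert len(segs) == 1
                s, e = segs[0]
                truth_len = row["novel_end"] - row["novel_start"]
                overlap = max(0, min(e, row["novel_end"]) - max(s, row["novel_start"]))
                assert overlap >= 0.99 * truth_len

    def test_filters_do_not_mutate_sequences(self, sequence_bundle):
        b = sequence_bundle
        novel, _, _ = cc.build_novel_set(b.contigs, b.alignments, b.taxonomy, b.reference)
        for seq_id, seq in novel.items():
            parsed = cc.parse_segment_id(seq_id)
            if parsed and parsed[0] in b.contigs:
                cid, s, e = parsed
                assert seq == b.contigs[cid][s:e]
            else:
                assert seq == b.contigs[seq_id]
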