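"""Local alignment, k-mer seeding, the minimal mapper, and SAM interchange."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pseudocall.align import (MappedRead, ReadMapper, ScoringScheme,
                              build_kmer_index, cigar_ref_span,
                              load_alignments, parse_cigar, smith_waterman,
                              write_sam)
from pseudocall.locus import LocusParams, derive_pseudogenes, generate_master_locus
from pseudocall.reads import ReadPair, ReadSimParams, simulate_read_pairs
from pseudocall.seq import random_sequence, revcomp

DNA = st.text(alphabet="ACGT", min_size=1, max_size=30)


def gotoh_oracle(q: str, t: str, sc: ScoringScheme) -> int:
    """Independent full-matrix affine-gap DP (scalar reference)."""
    NEG = -(10 ** 9)
    m, n = len(q), len(t)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i][j - 1] - sc.gap_open - sc.gap_extend,
                          E[i][j - 1] - sc.gap_extend)
            F[i][j] = max(H[i - 1][j] - sc.gap_open - sc.gap_extend,
                          F[i - 1][j] - sc.gap_extend)
            s = sc.match if q[i - 1] == t[j - 1] else -sc.mismatch
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSmithWaterman:
    def test_identical_sequences_full_match(self):
        aln = smith_waterman("ACGT", "ACGT", ScoringScheme(match=2))
        assert aln.score == 8
        assert aln.cigar == "4M"
        assert (aln.query_start, aln.target_start) == (0, 0)

    def test_disjoint_alphabets_empty_alignment(self):
        aln = smith_waterman("AAAA", "TTTT", ScoringScheme(match=2, mismatch=2))
        assert aln.score == 0 and aln.is_empty

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            smith_waterman("", "ACGT")

    def test_known_pair_matches_oracle(self):
        sc = ScoringScheme(2, 1, 2, 1)
        aln = smith_waterman("ACACACTA", "AGCACACA", sc)
        assert aln.score == gotoh_oracle("ACACACTA", "AGCACACA", sc)

    def test_1000_random_pairs_match_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            q = random_sequence(int(rng.integers(1, 31)), rng)
            t = random_sequence(int(rng.integers(1, 31)), rng)
            sc = ScoringScheme(int(rng.integers(1, 4)), int(rng.integers(0, 5)),
                               int(rng.integers(0, 7)), int(rng.integers(0, 3)))
            assert smith_waterman(q, t, sc).score == gotoh_oracle(q, t, sc), (q, t, sc)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(a=DNA, b=DNA)
    def test_score_symmetry(self, a, b):
        assert smith_waterman(a, b).score == smith_waterman(b, a).score

    def test_cigar_consistent_with_intervals(self):
        rng = np.random.default_rng(3)
        target = random_sequence(400, rng)
        query = "GGGG" + target[100:160] + target[170:220] + "CCCC"
        aln = smith_waterman(query, target)
        ops = parse_cigar(aln.cigar)
        q_len = sum(n for op, n in ops if op in "MIS")
        assert q_len == len(query)
        assert cigar_ref_span(aln.cigar) == aln.target_end - aln.target_start
        assert sum(n for op, n in ops if op in "MI") == aln.query_end - aln.query_start

    def test_deletion_recovered_in_cigar(self):
        rng = np.random.default_rng(4)
        target = random_sequence(300, rng)
        query = target[50:120] + target[125:190]  # 5 bp deletion
        aln = smith_waterman(query, target)
        assert "5D" in aln.cigar
        assert aln.target_start == 50


class TestKmerIndex:
    def test_unique_contig_single_hits(self, rng):
        seq = random_sequence(2000, rng)
        idx = build_kmer_index({"c": seq}, k=21)
        for pos in (0, 500, 1979):
            assert idx.hits(seq[pos:pos + 21]) == [("c", pos)]

    def test_duplicated_region_multi_hits(self, rng):
        seq = random_sequence(1000, rng)
        idx = build_kmer_index({"m": seq, "p": seq[200:800]}, k=21)
        hits = idx.hits(seq[300:321])
        assert ("m", 300) in hits and ("p", 100) in hits

    def test_absent_kmer_empty(self, rng):
        idx = build_kmer_index({"c": random_sequence(100, rng)}, k=21)
        assert idx.hits("N" * 21) == []

    def test_small_k_rejected(self, rng):
        with pytest.raises(ValueError):
            build_kmer_index({"c": random_sequence(100, rng)}, k=5)

    def test_k_longer_than_contig_rejected(self, rng):
        with pytest.raises(ValueError):
            build_kmer_index({"c": random_sequence(15, rng)}, k=21)


@pytest.fixture(scope="module")
def dup_reference():
    """Master plus one pseudogene copy of its first 600 bp at ~97% identity,
    and one exact-copy region for tie behaviour."""
    rng = np.random.default_rng(17)
    master = random_sequence(2000, rng)
    # identical copy of [1200, 1500): reads there tie
    master = master[:1500] + master[1200:1500] + master[1500:]
    params = LocusParams(exon_count=4, exon_length=100, intron_length=50,
                         duplicated_exon_range=(1, 4), n_pseudogenes=1,
                         identity=0.97, seed=18)
    locus = derive_pseudogenes(generate_master_locus(params), params)
    return locus


class TestReadMapper:
    def test_unique_read_gets_capped_mapq(self, rng):
        ref = {"c": random_sequence(3000, rng)}
        mapper = ReadMapper(ref)
        read = ref["c"][1000:1150]
        m = mapper.map_single(read)
        assert (m.contig, m.start, m.mapping_quality) == ("c", 1000, 60)
        assert m.cigar == "150M"

    def test_tied_single_read_mapq_zero(self, rng):
        seq = random_sequence(1000, rng)
        mapper = ReadMapper({"m": seq, "p": seq})  # identical contigs
        m = mapper.map_single(seq[100:250])
        assert m.mapping_quality == 0
        assert m.best_score == m.second_best_score

    def test_mate_rescues_ambiguous_read(self, rng):
        # first 400 bp identical between two contigs; tails divergent
        shared = random_sequence(400, rng)
        a = shared + random_sequence(400, rng)
        b = shared + random_sequence(400, rng)
        mapper = ReadMapper({"a": a, "b": b}, expected_outer=300,
                            outer_tolerance=150)
        # mate1 inside the shared region, mate2 in a's unique tail
        pair = ReadPair("p", a[200:350], revcomp(a[350:500]), "a", 200, True)
        r1, r2 = mapper.map_read_pair(pair)
        assert r1.contig == "a" and r2.contig == "a"
        assert r1.start == 200 and r1.properly_paired
        assert r1.mapping_quality > 0

    def test_unmapped_read_without_seed_hits(self, rng):
        mapper = ReadMapper({"c": random_sequence(500, rng)})
        m = mapper.map_single("N" * 150)
        assert m.unmapped

    def test_reads_over_divergence_sites_map_back_exactly(self, dup_reference):
        # error-free reads overlapping >=1 divergence site are never misplaced
        locus = dup_reference
        params = ReadSimParams(base_error_rate=0.0, target_coverage=30)
        pairs = simulate_read_pairs(locus.master_sequence, params, 200,
                                    contig="master",
                                    rng=np.random.default_rng(7))
        div = sorted(p for p, _m, _c in locus.divergence_sites[0])
        mapper = ReadMapper(locus.contigs(), seed=1)
        wrong = 0
        for pair in pairs:
            frag = (pair.start, pair.start + params.outer_distance)
            covers = any(frag[0] <= p < frag[1] for p in div)
            if not covers:
                continue
            r1, r2 = mapper.map_read_pair(pair)
            for m in (r1, r2):
                if m.contig != "master":
                    wrong += 1
        assert wrong == 0


class TestSamInterchange:
    def test_round_trip_preserves_fields(self, tmp_path, rng):
        ref = {"c1": random_sequence(500, rng), "c2": random_sequence(400, rng)}
        reads = [
            MappedRead("r1", "c1", 99, "+", "150M", 60, 300, 250,
                       random_sequence(150, rng), False, True, True, "c1", 150, "-"),
            MappedRead("r1", "c1", 150, "-", "20S130M", 60, 300, 250,
                       random_sequence(150, rng), True, True, True, "c1", 99, "+"),
            MappedRead("r2", "c2", 0, "+", "50S100M", 13, 200, 180,
                       random_sequence(150, rng), False, True, False),
        ]
        write_sam(reads, ref, tmp_path / "out.sam")
        back = list(load_alignments(tmp_path / "out.sam"))
        assert len(back) == 3
        for orig, rec in zip(reads, back):
            for attr in ("name", "contig", "start", "strand", "cigar",
                         "mapping_quality", "seq", "is_read2", "paired",
                         "properly_paired", "best_score", "second_best_score"):
                assert getattr(rec, attr) == getattr(orig, attr), attr

    def test_sam_position_is_one_based_on_disk(self, tmp_path, rng):
        ref = {"c": random_sequence(300, rng)}
        reads = [MappedRead("r", "c", 99, "+", "150M", 60, 300, None,
                            random_sequence(150, rng), paired=False)]
        write_sam(reads, ref, tmp_path / "o.sam")
        body = [l for l in open(tmp_path / "o.sam") if not l.startswith("@")]
        assert body[0].split("\t")[3] == "100"  # SAM POS = internal 99 + 1

    def test_soft_clip_length_recoverable(self):
        ops = parse_cigar("50S100M")
        assert ops[0] == ("S", 50)
        assert cigar_ref_span("50S100M") == 100
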