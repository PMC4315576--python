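"""Pileup construction and the tiered allele-fraction calling rules."""
import pytest

from pseudocall.align import MappedRead
from pseudocall.calling import (CallingThresholds, PileupSite, build_pileup,
                                build_region_pileup, call_site, critical_exons,
                                detect_critical_sites, filter_common_variants,
                                left_normalize, load_af_table, two_step_screen,
                                VariantCall)
from pseudocall.locus import TruthSet, Variant
from pseudocall.seq import random_sequence

TH = CallingThresholds()


def _read(name, start, cigar, seq, mapq=60):
    return MappedRead(name, "c", start, "+", cigar, mapq, 0, None, seq,
                      paired=False)


def _site(depth, alt, ref="A", alt_base="G", contig="c", pos=10):
    counts = {ref: depth - alt}
    if alt:
        counts[alt_base] = alt
    return PileupSite(contig, pos, ref, counts)


class TestPileup:
    def test_all_ref_reads(self, rng):
        ref = {"c": random_sequence(400, rng)}
        reads = [_read(f"r{i}", 100, "150M", ref["c"][100:250]) for i in range(10)]
        sites = build_pileup(reads, ref, ("c", 150, 160), TH)
        for s in sites:
            assert s.depth == 10
            assert s.base_counts == {s.ref: 10}

    def test_alt_counts_conserve_depth(self, rng):
        ref = {"c": random_sequence(400, rng)}
        p = 175
        alt = "A" if ref["c"][p] != "A" else "T"
        reads = []
        for i in range(10):
            seq = ref["c"][100:250]
            if i < 3:
                seq = seq[:p - 100] + alt + seq[p - 100 + 1:]
            reads.append(_read(f"r{i}", 100, "150M", seq))
        site = build_pileup(reads, ref, ("c", p, p + 1), TH)[0]
        assert site.base_counts[alt] == 3
        assert site.depth == 10
        assert sum(site.base_counts.values()) == 10

    def test_deletion_keyed_at_anchor_depth_conserved(self, rng):
        ref = {"c": random_sequence(400, rng)}
        # 5 reads span a 2 bp deletion after ref position 149
        reads = [_read(f"d{i}", 100, "50M2D100M",
                       ref["c"][100:150] + ref["c"][152:252]) for i in range(5)]
        reads += [_read(f"r{i}", 100, "150M", ref["c"][100:250]) for i in range(5)]
        pile = build_region_pileup(reads, ref, ("c", 0, 400), TH)
        frac, depth = pile.observed_fraction(149, ref["c"][149:152], ref["c"][149])
        assert depth == 10
        assert frac == pytest.approx(0.5)
        # positions inside the deletion only count the spanning ref reads
        inner = pile.site(150)
        assert inner.depth == 5

    def test_insertion_keyed_at_preceding_base(self, rng):
        ref = {"c": random_sequence(400, rng)}
        ins = "TT"
        reads = [_read(f"i{i}", 100, "50M2I98M",
                       ref["c"][100:150] + ins + ref["c"][150:248]) for i in range(4)]
        pile = build_region_pileup(reads, ref, ("c", 0, 400), TH)
        frac, depth = pile.observed_fraction(149, ref["c"][149], ref["c"][149] + ins)
        assert depth == 4 and frac == 1.0

    def test_low_mapq_reads_excluded_when_filter_on(self, rng):
        ref = {"c": random_sequence(400, rng)}
        th = CallingThresholds(min_mapping_quality=20)
        reads = [_read("hi", 100, "150M", ref["c"][100:250], mapq=60),
                 _read("lo", 100, "150M", ref["c"][100:250], mapq=0)]
        site = build_pileup(reads, ref, ("c", 120, 121), th)[0]
        assert site.depth == 1
        assert site.mq_failed == 1


class TestCallSite:
    @pytest.mark.parametrize("alt,in_dup,step,expect", [
        (20, False, "first", ("het", "standard")),   # >=20% rule
        (8, True, "second", ("het", "relaxed-candidate")),  # relaxed inside dup
        (8, False, "second", None),                  # relaxation scoped to dup
        (85, False, "first", ("hom", "standard")),   # >=85% homozygous
        (7, True, "second", None),                   # below both thresholds
        (7, True, "first", None),
        (19, False, "first", None),
        (19, True, "second", ("het", "relaxed-candidate")),
    ])
    def test_threshold_rules(self, alt, in_dup, step, expect):
        call = call_site(_site(100, alt), TH, in_dup, step)
        if expect is None:
            assert call is None
        else:
            assert (call.zygosity, call.tier) == expect
            assert call.alt_fraction == pytest.approx(alt / 100)

    def test_exhaustive_fraction_grid(self):
        # 5%..95% x region x step: calls appear exactly per the 20/8/85 rules
        for pct in range(5, 100, 5):
            for in_dup in (False, True):
                for step in ("first", "second"):
                    call = call_site(_site(100, pct), TH, in_dup, step)
                    should_call = pct >= 20 or (step == "second" and in_dup
                                                and pct >= 8)
                    assert (call is not None) == should_call, (pct, in_dup, step)
                    if call:
                        assert call.zygosity == ("hom" if pct >= 85 else "het")
                        assert call.tier == ("standard" if pct >= 20
                                             else "relaxed-candidate")

    def test_shallow_site_skipped(self):
        assert call_site(_site(10, 5), TH, True, "second") is None

    def test_relaxed_threshold_monotonicity(self):
        # lowering the relaxed floor never removes a call
        loose = CallingThresholds(relaxed_alt_fraction=0.05)
        for pct in range(5, 100, 5):
            strict_call = call_site(_site(100, pct), TH, True, "second")
            loose_call = call_site(_site(100, pct), loose, True, "second")
            if strict_call is not None:
                assert loose_call is not None


class TestTwoStepScreen:
    def _sites(self, fracs, pos0=10):
        return [_site(100, int(f * 100), pos=pos0 + 20 * i)
                for i, f in enumerate(fracs)]

    def test_bucketing_inside_duplicated_region(self):
        std, relaxed = two_step_screen(self._sites([0.25, 0.12, 0.05]),
                                       [(0, 1000)], TH)
        assert len(std) == 1 and len(relaxed) == 1

    def test_no_candidates_outside_duplicated_region(self):
        std, relaxed = two_step_screen(self._sites([0.25, 0.12, 0.05]), [], TH)
        assert len(std) == 1 and len(relaxed) == 0

    def test_standard_set_nested_in_relaxed_union(self):
        sites = self._sites([0.5, 0.3, 0.21, 0.19, 0.1, 0.08, 0.05])
        std, relaxed = two_step_screen(sites, [(0, 1000)], TH)
        std_keys = {c.key for c in std}
        union_keys = std_keys | {c.key for c in relaxed}
        assert std_keys <= union_keys
        assert all(c.alt_fraction >= 0.20 for c in std)
        assert all(0.08 <= c.alt_fraction < 0.20 for c in relaxed)


class TestCriticalSites:
    def _pileup_with(self, rng, pos, alt_frac, depth=100):
        ref = {"c": random_sequence(400, rng)}
        alt = "A" if ref["c"][pos] != "A" else "T"
        n_alt = int(depth * alt_frac)
        reads = []
        for i in range(depth):
            seq = ref["c"][pos - 50:pos + 100]
            if i < n_alt:
                seq = seq[:50] + alt + seq[51:]
            reads.append(_read(f"r{i}", pos - 50, "150M", seq))
        pile = build_region_pileup(reads, ref, ("c", 0, 400), TH)
        truth = TruthSet([Variant(pos, ref["c"][pos], alt, "SNV", "het")])
        return pile, truth

    def test_below_threshold_flagged(self, rng):
        pile, truth = self._pileup_with(rng, 200, 0.12)
        crit = detect_critical_sites(truth, pile, [], TH)
        assert len(crit) == 1 and crit[0].reason == "below-threshold"
        assert crit[0].observed_fraction == pytest.approx(0.12)

    def test_zygosity_mismatch_flagged(self, rng):
        pile, truth = self._pileup_with(rng, 200, 0.90)
        v = truth.variants[0]
        call = VariantCall("c", 200, v.ref, v.alt, 0.90, "hom", "standard", 100)
        crit = detect_critical_sites(truth, pile, [call], TH)
        assert len(crit) == 1 and crit[0].reason == "zygosity-mismatch"

    def test_well_behaved_site_not_critical(self, rng):
        pile, truth = self._pileup_with(rng, 200, 0.45)
        v = truth.variants[0]
        call = VariantCall("c", 200, v.ref, v.alt, 0.45, "het", "standard", 100)
        assert detect_critical_sites(truth, pile, [call], TH) == []

    def test_uncovered_site_reported(self, rng):
        pile, truth = self._pileup_with(rng, 200, 0.45, depth=5)
        crit = detect_critical_sites(truth, pile, [], TH)
        assert crit[0].reason == "uncovered"

    def test_critical_exon_listing(self):
        from pseudocall.calling import CriticalSite
        exons = [(0, 100), (200, 300), (400, 500)]
        sites = [CriticalSite("c", 250, 0.5, 0.1, "below-threshold"),
                 CriticalSite("c", 260, 0.5, 0.1, "below-threshold"),
                 CriticalSite("c", 450, 0.5, 0.1, "below-threshold")]
        assert critical_exons(sites, exons) == [2, 3]


class TestFrequencyFilter:
    def _call(self, pos=5, af=0.5):
        return VariantCall("c", pos, "A", "G", af, "het", "standard", 100)

    def test_common_variant_removed(self):
        table = {("c", 5, "A", "G"): 0.05}
        assert filter_common_variants([self._call()], table, 0.01) == []

    def test_rare_and_unknown_variants_kept(self):
        calls = [self._call(5), self._call(9)]
        table = {("c", 5, "A", "G"): 0.005}
        assert filter_common_variants(calls, table, 0.01) == calls

    def test_max_af_one_is_identity(self):
        calls = [self._call()]
        table = {("c", 5, "A", "G"): 0.99}
        assert filter_common_variants(calls, table, 1.0) == calls

    def test_af_table_parsing(self, tmp_path):
        path = tmp_path / "af.tsv"
        path.write_text("c\t6\tA\tG\t0.05\n")
        table = load_af_table(path)
        assert table == {("c", 5, "A", "G"): 0.05}  # 1-based file, 0-based key

    def test_malformed_af_row_raises(self, tmp_path):
        from pseudocall.errors import FormatError
        path = tmp_path / "af.tsv"
        path.write_text("c\tnot_a_number\tA\tG\t0.05\n")
        with pytest.raises(FormatError):
            load_af_table(path)


class TestLeftNormalize:
    def test_snv_unchanged(self):
        assert left_normalize(5, "A", "G", "TTTTTATTTT") == (5, "A", "G")

    def test_deletion_in_repeat_run_shifts_left(self):
        #            0123456
        seq = "GCAAAAT"
        # deleting one A, represented at the right edge of the run
        assert left_normalize(4, "AA", "A", seq) == (1, "CA", "C")

    def test_insertion_in_repeat_run_shifts_left(self):
        seq = "GCAAAAT"
        assert left_normalize(5, "A", "AA", seq) == (1, "C", "CA")
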