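"""Pileup construction and tiered allele-fraction variant calling.

The caller thresholds raw alternative-allele fractions rather than modelling
genotype likelihoods: a site is reported when at least 20% of the filtered
reads carry the alternative allele, called homozygous at >= 85%, and — only
inside the duplicated region, where competitive mapping against pseudogene
copies depresses alternative fractions — a second-step screen relaxes the
floor to 8% to surface candidates for orthogonal confirmation.

Pileup conventions: deletions are counted as an allele at their anchor base
(the last aligned base before the event) and replace the anchor-base count
of the carrying read, insertions likewise at the preceding base, so allele
counts always sum to depth.  Positions inside a deletion receive no
contribution from the deleted read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .align import MappedRead, parse_cigar
from .errors import FormatError
from .intervals import Interval, point_in_intervals
from .locus import TruthSet
from .seq import BASES, encode


@dataclass(frozen=True)
class CallingThresholds:
    """Detection thresholds; fractions are of total filtered depth."""

    standard_alt_fraction: float = 0.20
    relaxed_alt_fraction: float = 0.08
    hom_fraction: float = 0.85
    min_depth: int = 20
    min_base_quality: int = 13
    min_mapping_quality: int = 0  # 0 = mapping-quality filtering off

    def __post_init__(self):
        if not (0 < self.relaxed_alt_fraction < self.standard_alt_fraction
                < self.hom_fraction <= 1.0):
            raise ValueError("thresholds must satisfy relaxed < standard < hom <= 1")


@dataclass
class PileupSite:
    """Per-position allele counts after MQ/BQ filtering."""

    contig: str
    pos: int
    ref: str
    base_counts: dict[str, int]
    ins_counts: dict[str, int] = field(default_factory=dict)
    del_counts: dict[str, int] = field(default_factory=dict)
    mq_failed: int = 0
    bq_failed: int = 0
    mean_mapping_quality: float = 0.0

    @property
    def depth(self) -> int:
        return (sum(self.base_counts.values()) + sum(self.ins_counts.values())
                + sum(self.del_counts.values()))

    def allele_fraction(self, ref: str, alt: str) -> float:
        """Observed fraction of a specific (anchored) allele at this site."""
        d = self.depth
        if d == 0:
            return 0.0
        if len(ref) == 1 and len(alt) == 1:
            return self.base_counts.get(alt, 0) / d
        if len(alt) > len(ref):  # insertion
            return self.ins_counts.get(alt[1:], 0) / d
        return self.del_counts.get(ref[1:], 0) / d


@dataclass
class VariantCall:
    contig: str
    pos: int
    ref: str
    alt: str
    alt_fraction: float
    zygosity: str  # het | hom
    tier: str      # standard | relaxed-candidate
    depth: int

    @property
    def key(self) -> tuple:
        return (self.contig, self.pos, self.ref, self.alt)

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)


@dataclass
class CriticalSite:
    """A truth site where detection failed or degraded: the empirical marker
    of insufficient discriminative mapping."""

    contig: str
    pos: int
    expected_fraction: float
    observed_fraction: float
    reason: str  # below-threshold | zygosity-mismatch | uncovered


# ---------------------------------------------------------------------------
# Pileup

class RegionPileup:
    """Accumulated counts over one contig region; sites built on demand."""

    def __init__(self, contig: str, start: int, end: int, contig_seq: str):
        if end <= start:
            raise ValueError("empty region")
        self.contig = contig
        self.start = start
        self.end = end
        self.contig_seq = contig_seq  # full contig (context for normalisation)
        self.ref_seq = contig_seq[start:end]
        L = end - start
        self.base_counts = np.zeros((4, L), dtype=np.int64)
        self.ins: dict[int, dict[str, int]] = {}
        self.dels: dict[int, dict[str, int]] = {}
        self.mq_failed = np.zeros(L, dtype=np.int64)
        self.mapq_sum = np.zeros(L, dtype=np.int64)

    def site(self, pos: int) -> PileupSite:
        i = pos - self.start
        if not (0 <= i < self.end - self.start):
            raise IndexError(f"position {pos} outside pileup region")
        counts = {BASES[b]: int(self.base_counts[b, i])
                  for b in range(4) if self.base_counts[b, i]}
        ins = dict(self.ins.get(pos, {}))
        dels = dict(self.dels.get(pos, {}))
        depth = sum(counts.values()) + sum(ins.values()) + sum(dels.values())
        mean_mq = (self.mapq_sum[i] / depth) if depth else 0.0
        return PileupSite(self.contig, pos, self.ref_seq[i], counts, ins, dels,
                          mq_failed=int(self.mq_failed[i]),
                          mean_mapping_quality=float(mean_mq))

    def sites(self) -> list[PileupSite]:
        return [self.site(p) for p in range(self.start, self.end)]

    def observed_fraction(self, pos: int, ref: str, alt: str) -> tuple[float, int]:
        """Fraction (and depth) of an allele, normalised to pileup keying."""
        npos, nref, nalt = left_normalize(pos, ref, alt, self.contig_seq)
        site = self.site(npos)
        return site.allele_fraction(nref, nalt), site.depth

    def depth_array(self) -> np.ndarray:
        depth = self.base_counts.sum(axis=0).astype(np.int64)
        for pos, alleles in self.ins.items():
            depth[pos - self.start] += sum(alleles.values())
        for pos, alleles in self.dels.items():
            depth[pos - self.start] += sum(alleles.values())
        return depth


def build_region_pileup(alignments: Iterable[MappedRead],
                        reference: Mapping[str, str],
                        region: tuple[str, int, int],
                        thresholds: CallingThresholds | None = None) -> RegionPileup:
    """Accumulate filtered per-position counts over ``region``.

    Reads below the mapping-quality floor are excluded from depth (tallied in
    ``mq_failed``); base qualities, when present on a read, are screened
    against ``min_base_quality``.
    """
    thresholds = thresholds or CallingThresholds()
    contig, start, end = region
    if contig not in reference:
        raise ValueError(f"unknown contig {contig!r}")
    ref_seq = reference[contig]
    if not (0 <= start < end <= len(ref_seq)):
        raise ValueError(f"region {start}-{end} outside contig of length {len(ref_seq)}")
    pile = RegionPileup(contig, start, end, ref_seq)
    L = end - start

    # batched fast path for all-match alignments
    batch_starts: list[int] = []
    batch_codes: list[np.ndarray] = []
    batch_mapq: list[int] = []

    for read in alignments:
        if read.unmapped or read.contig != contig or not read.cigar:
            continue
        if read.start >= end or read.end <= start:
            continue
        if read.mapping_quality < thresholds.min_mapping_quality:
            s = max(read.start, start) - start
            e = min(read.end, end) - start
            pile.mq_failed[s:e] += 1
            continue
        ops = parse_cigar(read.cigar)
        if len(ops) == 1 and ops[0][0] == "M":
            batch_starts.append(read.start)
            batch_codes.append(encode(read.seq))
            batch_mapq.append(read.mapping_quality)
            if len(batch_starts) >= 20000:
                _flush_match_batch(pile, batch_starts, batch_codes, batch_mapq)
                batch_starts, batch_codes, batch_mapq = [], [], []
            continue
        _add_cigar_read(pile, read, ops)
    if batch_starts:
        _flush_match_batch(pile, batch_starts, batch_codes, batch_mapq)
    return pile


def _flush_match_batch(pile: RegionPileup, starts, codes, mapqs) -> None:
    L = pile.end - pile.start
    rl = codes[0].size
    starts_arr = np.asarray(starts, dtype=np.int64) - pile.start
    mat = np.stack(codes)
    mapq_arr = np.asarray(mapqs, dtype=np.int64)
    pos = starts_arr[:, None] + np.arange(rl)
    valid = (pos >= 0) & (pos < L) & (mat < 4)
    flat_pos = pos[valid]
    flat_code = mat[valid].astype(np.int64)
    np.add.at(pile.base_counts, (flat_code, flat_pos), 1)
    mq_per_cell = np.broadcast_to(mapq_arr[:, None], pos.shape)[valid]
    np.add.at(pile.mapq_sum, flat_pos, mq_per_cell)


def _add_cigar_read(pile: RegionPileup, read: MappedRead, ops) -> None:
    qpos = 0
    rpos = read.start
    seq = read.seq
    code = {b: i for i, b in enumerate(BASES)}
    for op, n in ops:
        if op in ("S", "H"):
            qpos += n if op == "S" else 0
        elif op == "M":
            for j in range(n):
                p = rpos + j
                if pile.start <= p < pile.end:
                    b = seq[qpos + j]
                    if b in code:
                        pile.base_counts[code[b], p - pile.start] += 1
                        pile.mapq_sum[p - pile.start] += read.mapping_quality
            qpos += n
            rpos += n
        elif op == "I":
            anchor = rpos - 1
            ins_seq = seq[qpos:qpos + n]
            if 0 <= anchor < len(pile.contig_seq):
                base = pile.contig_seq[anchor]
                npos, _nref, nalt = left_normalize(anchor, base, base + ins_seq,
                                                   pile.contig_seq)
                if pile.start <= npos < pile.end and npos >= read.start:
                    nb = pile.contig_seq[npos]
                    if nb in code and pile.base_counts[code[nb], npos - pile.start] > 0:
                        pile.base_counts[code[nb], npos - pile.start] -= 1
                    pile.ins.setdefault(npos, {}).setdefault(nalt[1:], 0)
                    pile.ins[npos][nalt[1:]] += 1
            qpos += n
        elif op == "D":
            anchor = rpos - 1
            del_seq = pile.contig_seq[rpos: rpos + n]
            if 0 <= anchor < len(pile.contig_seq) and len(del_seq) == n:
                base = pile.contig_seq[anchor]
                npos, nref, _nalt = left_normalize(anchor, base + del_seq, base,
                                                   pile.contig_seq)
                if pile.start <= npos < pile.end and npos >= read.start:
                    nb = pile.contig_seq[npos]
                    if nb in code and pile.base_counts[code[nb], npos - pile.start] > 0:
                        pile.base_counts[code[nb], npos - pile.start] -= 1
                    pile.dels.setdefault(npos, {}).setdefault(nref[1:], 0)
                    pile.dels[npos][nref[1:]] += 1
            rpos += n
        else:
            raise FormatError(f"unsupported CIGAR op {op!r} in {read.cigar}")


def build_pileup(alignments: Iterable[MappedRead],
                 reference: Mapping[str, str],
                 region: tuple[str, int, int],
                 thresholds: CallingThresholds | None = None) -> list[PileupSite]:
    """Convenience entry point: list of per-position sites over ``region``."""
    return build_region_pileup(alignments, reference, region, thresholds).sites()


# ---------------------------------------------------------------------------
# Calling

def _top_alt_allele(site: PileupSite) -> tuple[str, str, int] | None:
    """Highest-count non-reference allele as (ref, alt, count)."""
    options: list[tuple[int, int, str, str]] = []  # (-count, order, ref, alt)
    for b, n in sorted(site.base_counts.items()):
        if b != site.ref and n > 0:
            options.append((-n, 0, site.ref, b))
    for ins_seq, n in sorted(site.ins_counts.items()):
        if n > 0:
            options.append((-n, 1, site.ref, site.ref + ins_seq))
    for del_seq, n in sorted(site.del_counts.items()):
        if n > 0:
            options.append((-n, 2, site.ref + del_seq, site.ref))
    if not options:
        return None
    options.sort()
    neg_n, _order, ref, alt = options[0]
    return ref, alt, -neg_n


def call_site(site: PileupSite, thresholds: CallingThresholds,
              in_duplicated_region: bool = False,
              step: str = "first") -> VariantCall | None:
    """Apply the tiered fraction rules to one pileup site.

    First step: standard-tier calls at >= ``standard_alt_fraction``.  Second
    step additionally emits relaxed-candidate calls at
    >= ``relaxed_alt_fraction``, but only inside the duplicated region.
    Sites below ``min_depth`` are skipped (reported upstream as uncovered).
    """
    if step not in ("first", "second"):
        raise ValueError(f"unknown step {step!r}")
    depth = site.depth
    if depth < thresholds.min_depth:
        return None
    top = _top_alt_allele(site)
    if top is None:
        return None
    ref, alt, count = top
    fraction = count / depth
    if fraction >= thresholds.standard_alt_fraction:
        tier = "standard"
    elif (step == "second" and in_duplicated_region
          and fraction >= thresholds.relaxed_alt_fraction):
        tier = "relaxed-candidate"
    else:
        return None
    zygosity = "hom" if fraction >= thresholds.hom_fraction else "het"
    return VariantCall(site.contig, site.pos, ref, alt, fraction, zygosity,
                       tier, depth)


def two_step_screen(pileup_sites: Sequence[PileupSite],
                    duplicated_intervals: Sequence[Interval],
                    thresholds: CallingThresholds | None = None
                    ) -> tuple[list[VariantCall], list[VariantCall]]:
    """Standard-tier calls plus the additional relaxed candidates.

    The standard set is invariant under the second step; relaxed candidates
    are the extra calls surfaced inside the duplicated region and are meant
    for orthogonal confirmation.
    """
    thresholds = thresholds or CallingThresholds()
    standard: list[VariantCall] = []
    relaxed: list[VariantCall] = []
    for site in pileup_sites:
        in_dup = point_in_intervals(site.pos, duplicated_intervals)
        call = call_site(site, thresholds, in_dup, step="second")
        if call is None:
            continue
        if call.tier == "standard":
            standard.append(call)
        else:
            relaxed.append(call)
    key = lambda c: (c.contig, c.pos, c.ref, c.alt)
    return sorted(standard, key=key), sorted(relaxed, key=key)


def detect_critical_sites(truth: TruthSet,
                          pileup: RegionPileup,
                          calls: Sequence[VariantCall],
                          thresholds: CallingThresholds | None = None
                          ) -> list[CriticalSite]:
    """Flag truth sites detected below the standard threshold or with wrong
    zygosity — the empirical critical-site list feeding the CNV ledger."""
    thresholds = thresholds or CallingThresholds()
    calls_by_pos = {c.pos: c for c in calls}
    out: list[CriticalSite] = []
    for v in truth:
        expected = 1.0 if v.zygosity == "hom" else 0.5
        if not (pileup.start <= v.pos < pileup.end):
            out.append(CriticalSite(pileup.contig, v.pos, expected, 0.0, "uncovered"))
            continue
        npos, _nref, _nalt = left_normalize(v.pos, v.ref, v.alt, pileup.contig_seq)
        observed, depth = pileup.observed_fraction(v.pos, v.ref, v.alt)
        if depth < thresholds.min_depth:
            out.append(CriticalSite(pileup.contig, v.pos, expected, 0.0, "uncovered"))
            continue
        if observed < thresholds.standard_alt_fraction:
            out.append(CriticalSite(pileup.contig, v.pos, expected, observed,
                                    "below-threshold"))
            continue
        call = calls_by_pos.get(npos)
        if call is not None and call.zygosity != v.zygosity:
            out.append(CriticalSite(pileup.contig, v.pos, expected, observed,
                                    "zygosity-mismatch"))
    return out


def critical_exons(critical_sites: Sequence[CriticalSite], exons: Sequence[Interval]
                   ) -> list[int]:
    """1-based exon numbers containing at least one critical site."""
    out = set()
    for cs in critical_sites:
        for i, (s, e) in enumerate(exons, start=1):
            if s <= cs.pos < e:
                out.add(i)
    return sorted(out)


# ---------------------------------------------------------------------------
# Population-frequency filtering

def load_af_table(path) -> dict[tuple, float]:
    """Tab-delimited (contig, pos[1-based], ref, alt, af) -> frequency map."""
    table: dict[tuple, float] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}: malformed AF row {ln}: {line!r}")
            try:
                table[(parts[0], int(parts[1]) - 1, parts[2], parts[3])] = float(parts[4])
            except ValueError as exc:
                raise FormatError(f"{path}: malformed AF row {ln}: {exc}") from exc
    return table


def filter_common_variants(calls: Sequence[VariantCall],
                           allele_frequency_table: Mapping[tuple, float],
                           max_af: float = 0.01) -> list[VariantCall]:
    """Drop calls whose catalogued population frequency exceeds ``max_af``;
    calls absent from the table are retained (unknown frequency)."""
    out = []
    for c in calls:
        af = allele_frequency_table.get(c.key)
        if af is not None and af > max_af:
            continue
        out.append(c)
    return out


# ---------------------------------------------------------------------------
# Normalisation and VCF output

def left_normalize(pos: int, ref: str, alt: str, sequence: str) -> tuple[int, str, str]:
    """Shift a variant to its leftmost minimal representation (VCF style):
    right-trim shared suffix bases (extending left when an allele would
    empty), then left-trim shared prefix bases."""
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (ref and alt and ref[-1] == alt[-1]
                and (len(ref) > 1 or len(alt) > 1) and pos > 0):
            b = sequence[pos - 1]
            ref = b + ref[:-1]
            alt = b + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def write_calls_vcf(calls: Sequence[VariantCall], path, contig_lengths: Mapping[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alt read fraction">\n')
        fh.write('##INFO=<ID=TIER,Number=1,Type=String,Description="Detection tier">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsample\n")
        for c in sorted(calls, key=lambda c: (c.contig, c.pos)):
            gt = "1/1" if c.zygosity == "hom" else "0/1"
            fh.write(f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t"
                     f"AF={c.alt_fraction:.4f};TIER={c.tier};DP={c.depth}\tGT\t{gt}\n")
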