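"""Synthetic master-gene / pseudogene loci with planted truth variants.

The model emulates a disease gene whose 5' portion is mirrored by several
highly similar processed pseudogene copies (a segmental-duplication
structure).  A master contig carries evenly spaced exons; the duplicated
region — a span of consecutive exons plus intervening introns — is copied
``n_pseudogenes`` times and each copy is independently mutated so that its
expected per-base identity to the master equals ``identity``.  Truth variants
are planted on the master only; pseudogene copies always stay wild type so
that reads simulated from them act purely as mapping competitors.

All coordinates are 0-based half-open on the master contig.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import FormatError, PlantingError, SizingError
from .intervals import Interval, intersect_intervals, merge_intervals, point_in_intervals
from .seq import BASES, random_sequence

MASTER_NAME = "master"
PSEUDO_PREFIX = "pseudo"


@dataclass(frozen=True)
class LocusParams:
    """Geometry and divergence parameters of a synthetic locus.

    ``duplicated_exon_range`` is 1-based inclusive on exon indices, so the
    default ``(1, 33)`` mirrors a gene whose exons 1-33 are duplicated.
    ``identity`` is the expected per-base identity between the master
    duplicated region and each pseudogene copy (0.977 for the locus family
    this toolkit emulates).
    """

    exon_count: int = 33
    exon_length: int = 150
    intron_length: int = 100
    master_length: int | None = None  # None -> tight layout with flanks
    duplicated_exon_range: tuple[int, int] = (1, 33)
    n_pseudogenes: int = 6
    identity: float = 0.977
    substitution_indel_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.exon_count < 1 or self.exon_length < 1 or self.intron_length < 0:
            raise ValueError("exon/intron geometry must be positive")
        lo, hi = self.duplicated_exon_range
        if not (1 <= lo <= hi <= self.exon_count):
            raise ValueError("duplicated_exon_range must lie within [1, exon_count]")
        if not (0.0 < self.identity <= 1.0):
            raise ValueError("identity must be in (0, 1]")
        if self.n_pseudogenes < 0:
            raise ValueError("n_pseudogenes must be >= 0")
        if not (0.0 <= self.substitution_indel_ratio <= 1.0):
            raise ValueError("substitution_indel_ratio must be in [0, 1]")

    @property
    def layout_length(self) -> int:
        """Minimal master length: flanking intron + exons with introns + flank."""
        body = self.exon_count * self.exon_length + (self.exon_count - 1) * self.intron_length
        return body + 2 * self.intron_length


@dataclass(frozen=True)
class Variant:
    """A planted truth variant in anchored (VCF-like, but 0-based) form."""

    pos: int
    ref: str
    alt: str
    vtype: str  # "SNV" | "ins" | "del"
    zygosity: str = "het"  # "het" | "hom"
    # background: planted anywhere in coding sequence (density emulation);
    # divergent: planted at a pseudogene-divergence site with an alt allele
    #   distinct from every copy's base (discriminable by construction);
    # pseudogene_matched: alt equals a pseudogene base (the critical-site
    #   mechanism).
    var_class: str = "background"

    def __post_init__(self):
        if self.vtype not in ("SNV", "ins", "del"):
            raise ValueError(f"unknown variant type {self.vtype!r}")
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    @property
    def end(self) -> int:
        """Master position one past the last reference base consumed."""
        return self.pos + len(self.ref)


@dataclass
class TruthSet:
    """Gold-standard variants for evaluating calls."""

    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self):
        self.variants = sorted(self.variants, key=lambda v: v.pos)

    def __len__(self):
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)

    def positions(self) -> list[int]:
        return [v.pos for v in self.variants]

    def by_class(self, var_class: str) -> "TruthSet":
        return TruthSet([v for v in self.variants if v.var_class == var_class])

    def merged_with(self, other: "TruthSet") -> "TruthSet":
        merged = sorted(self.variants + list(other), key=lambda v: v.pos)
        for a, b in zip(merged, merged[1:]):
            if a.end > b.pos:
                raise PlantingError(f"overlapping truth variants at {a.pos} and {b.pos}")
        return TruthSet(merged)

    def validate_refs(self, locus: "LocusModel") -> None:
        for v in self.variants:
            if locus.master_sequence[v.pos:v.end] != v.ref:
                raise PlantingError(f"truth ref mismatch at {v.pos}")

    def to_vcf(self, path, contig: str = MASTER_NAME) -> None:
        """Write a minimal VCF (1-based POS, GT carries zygosity)."""
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(f"##contig=<ID={contig}>\n")
            fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="Planted variant class">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth\n")
            for v in self.variants:
                gt = "1/1" if v.zygosity == "hom" else "0/1"
                fh.write(f"{contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                         f"CLASS={v.var_class}\tGT\t{gt}\n")


@dataclass
class LocusModel:
    """A synthetic master locus plus derived pseudogene copies.

    ``divergence_sites[c]`` lists ``(master_pos, master_base, copy_base)``
    per pseudogene copy; for substitution divergence both bases have length
    one, insertions carry an empty master base and deletions an empty copy
    base.
    """

    master_sequence: str
    exons: list[Interval]
    duplicated_intervals: list[Interval]
    pseudogene_sequences: list[str] = field(default_factory=list)
    divergence_sites: list[list[tuple[int, str, str]]] = field(default_factory=list)

    @property
    def master_length(self) -> int:
        return len(self.master_sequence)

    @property
    def contig_names(self) -> list[str]:
        return [MASTER_NAME] + [f"{PSEUDO_PREFIX}{i + 1}" for i in range(len(self.pseudogene_sequences))]

    def contigs(self) -> dict[str, str]:
        out = {MASTER_NAME: self.master_sequence}
        for i, seq in enumerate(self.pseudogene_sequences):
            out[f"{PSEUDO_PREFIX}{i + 1}"] = seq
        return out

    def coding_in_duplicated(self) -> list[Interval]:
        """Exonic intervals inside the duplicated region."""
        return intersect_intervals(self.exons, self.duplicated_intervals)

    def exon_interval(self, exon_number: int) -> Interval:
        """1-based exon number -> master interval."""
        return self.exons[exon_number - 1]

    def exon_of(self, pos: int) -> int | None:
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i + 1
        return None

    def observed_identity(self, copy_index: int) -> float:
        """Fraction of duplicated-region bases not touched by a divergence event."""
        span = sum(e - s for s, e in self.duplicated_intervals)
        return 1.0 - len(self.divergence_sites[copy_index]) / span


def generate_master_locus(params: LocusParams) -> LocusModel:
    """Build the master contig: uniform-random sequence, evenly spaced exons."""
    length = params.master_length if params.master_length is not None else params.layout_length
    if length < params.layout_length:
        raise SizingError(
            f"master_length {length} cannot hold {params.exon_count} exons of "
            f"{params.exon_length} bp with {params.intron_length} bp introns "
            f"(need {params.layout_length})")
    rng = np.random.default_rng(params.seed)
    seq = random_sequence(length, rng)
    exons = []
    step = params.exon_length + params.intron_length
    offset = params.intron_length  # leading flank
    for i in range(params.exon_count):
        s = offset + i * step
        exons.append((s, s + params.exon_length))
    lo, hi = params.duplicated_exon_range
    dup = [(exons[lo - 1][0], exons[hi - 1][1])]
    return LocusModel(master_sequence=seq, exons=exons, duplicated_intervals=dup)


def derive_pseudogenes(locus: LocusModel, params: LocusParams) -> LocusModel:
    """Append mutated copies of the duplicated region as pseudogene contigs.

    Divergence events are drawn i.i.d. per base at rate ``1 - identity``;
    each event is a substitution with probability ``substitution_indel_ratio``
    and otherwise a single-base insertion or deletion (equiprobable).
    """
    if not locus.duplicated_intervals:
        raise ValueError("locus has no duplicated intervals to copy")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0xD17]))
    rate = 1.0 - params.identity
    for _copy in range(params.n_pseudogenes):
        pieces: list[str] = []
        sites: list[tuple[int, str, str]] = []
        for (s, e) in merge_intervals(locus.duplicated_intervals):
            sub = locus.master_sequence[s:e]
            hit = np.flatnonzero(rng.random(len(sub)) < rate)
            prev = 0
            for idx in hit:
                pos = int(idx)
                master_base = sub[pos]
                if rng.random() < params.substitution_indel_ratio:
                    shift = int(rng.integers(1, 4))
                    copy_base = BASES[(BASES.index(master_base) + shift) % 4]
                    pieces.append(sub[prev:pos])
                    pieces.append(copy_base)
                    prev = pos + 1
                    sites.append((s + pos, master_base, copy_base))
                elif rng.random() < 0.5:  # insertion into the copy
                    ins = BASES[int(rng.integers(0, 4))]
                    pieces.append(sub[prev:pos + 1])
                    pieces.append(ins)
                    prev = pos + 1
                    sites.append((s + pos, "", ins))
                else:  # deletion from the copy
                    pieces.append(sub[prev:pos])
                    prev = pos + 1
                    sites.append((s + pos, master_base, ""))
            pieces.append(sub[prev:])
        locus.pseudogene_sequences.append("".join(pieces))
        locus.divergence_sites.append(sites)
    return locus


def _coding_positions(locus: LocusModel) -> np.ndarray:
    coding = locus.coding_in_duplicated()
    if not coding:
        raise PlantingError("locus has no coding sequence inside the duplicated region")
    return np.concatenate([np.arange(s, e) for s, e in coding])


def _respects_spacing(pos: int, taken: list[int], min_spacing: int) -> bool:
    return all(abs(pos - t) >= min_spacing for t in taken)


def plant_variants(locus: LocusModel,
                   density_mode: str = "per-100bp",
                   mutation_rate: float = 0.02,
                   zygosity_policy: str = "het",
                   indel_fraction: float = 0.15,
                   indel_extension_p: float = 0.3,
                   seed: int = 0,
                   avoid: Iterable[int] = (),
                   min_spacing: int = 12,
                   window: int = 100) -> TruthSet:
    """Plant truth variants in the coding sequence of the duplicated region.

    ``density_mode='rate'`` draws per-base Bernoulli(mutation_rate) positions;
    ``'per-100bp'`` additionally guarantees at least one variant in every
    100-bp window of coding sequence (windows taken over the concatenated
    coding bases).  Pseudogene copies are never touched.
    """
    if density_mode not in ("per-100bp", "rate"):
        raise ValueError(f"unknown density_mode {density_mode!r}")
    if not (0.0 <= mutation_rate < 1.0):
        raise ValueError("mutation_rate must be in [0, 1)")
    if zygosity_policy not in ("het", "hom", "mixed"):
        raise ValueError(f"unknown zygosity_policy {zygosity_policy!r}")
    rng = np.random.default_rng(seed)
    coding = _coding_positions(locus)
    avoid = list(avoid)

    taken: list[int] = list(avoid)
    chosen: list[int] = []
    picks = coding[rng.random(coding.size) < mutation_rate] if mutation_rate > 0 else np.array([], dtype=int)
    for pos in picks.tolist():
        if _respects_spacing(pos, taken, min_spacing):
            chosen.append(pos)
            taken.append(pos)

    if density_mode == "per-100bp":
        chosen_set = set(chosen) | set(avoid)
        for w0 in range(0, coding.size, window):
            block = coding[w0:w0 + window]
            if any(int(p) in chosen_set for p in block):
                continue
            candidates = rng.permutation(block)
            placed = False
            for pos in candidates.tolist():
                if _respects_spacing(pos, taken, min_spacing):
                    chosen.append(pos)
                    taken.append(pos)
                    chosen_set.add(pos)
                    placed = True
                    break
            if not placed:
                raise PlantingError(
                    f"cannot satisfy per-{window}bp density with spacing {min_spacing}")

    chosen.sort()
    variants: list[Variant] = []
    master = locus.master_sequence
    for pos in chosen:
        if zygosity_policy == "het":
            zyg = "het"
        elif zygosity_policy == "hom":
            zyg = "hom"
        else:
            zyg = "hom" if rng.random() < 0.1 else "het"
        ref_base = master[pos]
        if rng.random() < indel_fraction:
            length = min(int(rng.geometric(indel_extension_p)), 10)
            if rng.random() < 0.5 and pos + 1 + length <= len(master):
                ref = master[pos:pos + 1 + length]
                variants.append(Variant(pos, ref, ref_base, "del", zyg))
            else:
                ins = random_sequence(length, rng)
                variants.append(Variant(pos, ref_base, ref_base + ins, "ins", zyg))
        else:
            shift = int(rng.integers(1, 4))
            alt = BASES[(BASES.index(ref_base) + shift) % 4]
            variants.append(Variant(pos, ref_base, alt, "SNV", zyg))
    return TruthSet(variants)


def discriminable_positions(locus: LocusModel, fragment_length: int = 200,
                            neutralized_sites: Iterable[int] = ()) -> np.ndarray:
    """Coding positions where competitive mapping cannot absorb reads.

    A sequencing fragment of length ``fragment_length`` covering position
    ``p`` is guaranteed to overlap at least one divergence site of copy
    ``c`` (other than ``p`` itself) whenever the gap between the nearest
    flanking ``c``-divergence sites around ``p`` is smaller than the
    fragment: every read pair then carries evidence distinguishing the
    master gene from that copy.  A position qualifying against every copy
    is a 'divergent position' in the mapping sense — variants planted there
    are recoverable at full allele fraction.

    ``neutralized_sites`` are divergence sites that no longer discriminate
    on the variant-carrying haplotype — typically positions where a planted
    variant's alternative allele equals the copy base — and are ignored.
    """
    if not locus.divergence_sites:
        raise PlantingError("locus has no pseudogene copies; derive them first")
    dead = set(neutralized_sites)
    coding = locus.coding_in_duplicated()
    pos = np.concatenate([np.arange(s, e) for s, e in coding])
    ok = np.ones(pos.size, dtype=bool)
    big = 10 ** 9
    for sites in locus.divergence_sites:
        S = np.unique(np.array([p for p, _mb, _cb in sites if p not in dead],
                               dtype=np.int64))
        if S.size == 0:
            return np.array([], dtype=np.int64)
        idx = np.searchsorted(S, pos)  # S[idx-1] < pos <= S[idx]
        left_idx = idx - 1
        left = np.where(left_idx >= 0, pos - S[np.maximum(left_idx, 0)], big)
        # exclude the site itself: if S[idx] == pos the right neighbour is idx+1
        at_site = (idx < S.size) & (S[np.minimum(idx, S.size - 1)] == pos)
        right_idx = np.where(at_site, idx + 1, idx)
        right = np.where(right_idx < S.size,
                         S[np.minimum(right_idx, S.size - 1)] - pos, big)
        ok &= (left + right) <= fragment_length - 1
    return pos[ok]


def plant_divergent_site_variants(locus: LocusModel,
                                  n: int = 100,
                                  seed: int = 0,
                                  avoid: Iterable[int] = (),
                                  min_spacing: int = 12,
                                  fragment_length: int = 200,
                                  indel_fraction: float = 0.15,
                                  indel_extension_p: float = 0.3,
                                  neutralized_sites: Iterable[int] = ()) -> TruthSet:
    """Plant heterozygous variants at divergent (discriminable) positions.

    Positions come from :func:`discriminable_positions`; SNV alternative
    alleles additionally avoid every pseudogene base at the position, so no
    allele of the variant can make a read match a copy better than the
    master.  These are the variants a pseudogene-aware pipeline should
    recover essentially completely.
    """
    rng = np.random.default_rng(seed)
    candidates = discriminable_positions(locus, fragment_length, neutralized_sites)
    if candidates.size == 0:
        raise PlantingError("no discriminable coding positions available")
    copy_bases: dict[int, set[str]] = {}
    for sites in locus.divergence_sites:
        for p, mb, cb in sites:
            if len(mb) == 1 and len(cb) == 1:
                copy_bases.setdefault(p, set()).add(cb)
    taken = list(avoid)
    master = locus.master_sequence
    variants: list[Variant] = []
    for p in rng.permutation(candidates).tolist():
        if len(variants) >= n:
            break
        if not _respects_spacing(p, taken, min_spacing):
            continue
        ref_base = master[p]
        if rng.random() < indel_fraction:
            length = min(int(rng.geometric(indel_extension_p)), 10)
            if rng.random() < 0.5 and p + 1 + length <= len(master):
                variants.append(Variant(p, master[p:p + 1 + length], ref_base,
                                        "del", "het", var_class="divergent"))
            else:
                ins = random_sequence(length, rng)
                variants.append(Variant(p, ref_base, ref_base + ins, "ins",
                                        "het", var_class="divergent"))
        else:
            forbidden = copy_bases.get(p, set()) | {ref_base}
            allowed = [b for b in BASES if b not in forbidden]
            if not allowed:
                continue
            alt = allowed[int(rng.integers(0, len(allowed)))]
            variants.append(Variant(p, ref_base, alt, "SNV", "het",
                                    var_class="divergent"))
        taken.append(p)
    if not variants:
        raise PlantingError("could not place any divergent-position variant")
    return TruthSet(variants)


def plant_matched_variants(locus: LocusModel,
                           n: int = 20,
                           seed: int = 0,
                           fragment_window: int = 200,
                           avoid: Iterable[int] = (),
                           min_spacing: int = 12) -> TruthSet:
    """Plant heterozygous SNVs whose alt allele equals a pseudogene base.

    Candidate positions are exonic substitution-divergence sites of some
    pseudogene copy; the alternative allele is set to that copy's base, so a
    read carrying the variant matches the pseudogene perfectly at the site.
    Candidates are ranked by local isolation — the number of *other*
    divergence sites of the same copy within ``fragment_window`` bases — so
    that the planted set includes sites where competitive mapping between the
    master gene and the copy is strongest (the mechanism that creates
    critical sites in real duplicated loci, where homology is locally
    complete).
    """
    if not locus.divergence_sites:
        raise PlantingError("locus has no pseudogene copies; derive them first")
    rng = np.random.default_rng(seed)
    coding = locus.coding_in_duplicated()

    candidates: list[tuple[int, int, int, int]] = []  # (isolation, -nn, pos, copy)
    for ci, sites in enumerate(locus.divergence_sites):
        sub_pos = np.array([p for p, mb, cb in sites if len(mb) == 1 and len(cb) == 1])
        for j, p in enumerate(sub_pos.tolist()):
            if not point_in_intervals(p, coding):
                continue
            near = np.abs(sub_pos - p) <= fragment_window
            isolation = int(near.sum()) - 1
            others = sub_pos[sub_pos != p]
            nn = int(np.min(np.abs(others - p))) if others.size else fragment_window + 1
            candidates.append((isolation, -nn, p, ci))
    if not candidates:
        raise PlantingError("no exonic divergence sites available for matched planting")

    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates[i][0], candidates[i][1], rng.random()))
    taken = list(avoid)
    variants: list[Variant] = []
    master = locus.master_sequence
    for i in order:
        if len(variants) >= n:
            break
        isolation, _negnn, pos, ci = candidates[i]
        if not _respects_spacing(pos, taken, min_spacing):
            continue
        copy_base = next(cb for p, mb, cb in locus.divergence_sites[ci]
                         if p == pos and len(mb) == 1 and len(cb) == 1)
        if copy_base == master[pos]:
            continue
        variants.append(Variant(pos, master[pos], copy_base, "SNV", "het",
                                var_class="pseudogene_matched"))
        taken.append(pos)
    if not variants:
        raise PlantingError("could not place any pseudogene-matched variant")
    return TruthSet(variants)


# ---------------------------------------------------------------------------
# On-disk artifacts

def write_locus_fasta(locus: LocusModel, path) -> None:
    """Combined reference FASTA: master contig plus pseudogene contigs."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in locus.contigs().items()]
    SeqIO.write(records, str(path), "fasta")


def write_exon_bed(locus: LocusModel, path) -> None:
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(locus.exons, start=1):
            fh.write(f"{MASTER_NAME}\t{s}\t{e}\texon{i}\n")


def write_duplicated_bed(locus: LocusModel, path) -> None:
    with open(path, "w") as fh:
        for s, e in locus.duplicated_intervals:
            fh.write(f"{MASTER_NAME}\t{s}\t{e}\tduplicated\n")


def read_bed(path) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: malformed BED row {ln}: {line!r}")
            name = parts[3] if len(parts) > 3 else f"region{ln}"
            out.append((parts[0], int(parts[1]), int(parts[2]), name))
    return out
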