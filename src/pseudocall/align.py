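"""Local alignment and a minimal seed-and-extend read mapper.

The mapper exists so that competitive read mapping between a master gene
and its pseudogene copies is reproducible without external tools; it is a
desk-scale instrument, not a re-implementation of a production aligner.
Externally produced SAM/BAM can be ingested through :func:`load_alignments`.

Smith-Waterman uses affine gaps (a gap of length L costs
``gap_open + gap_extend * L``) with the inner loop vectorised over the
target; the horizontal-gap dependency inside a row is resolved with a
running-maximum scan, which is exact because a second gap opening inside an
unbroken gap can never beat extending the first.
"""
from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np

from .errors import FormatError
from .seq import encode, revcomp

NEG = -(10 ** 7)

try:
    from numba import njit as _njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False


@dataclass(frozen=True)
class ScoringScheme:
    """Match bonus and mismatch/gap penalties (all penalties >= 0).

    Defaults are common short-read local-alignment settings.
    """

    match: int = 2
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class LocalAlignment:
    """An optimal local alignment of ``query`` against ``target``.

    Intervals are 0-based half-open; ``cigar`` covers the full query with
    terminal soft clips (query convention: M consumes both, I consumes
    query, D consumes target).
    """

    score: int
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    cigar: str
    co_optimal_target_ends: list[int] = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return self.score <= 0


if HAVE_NUMBA:
    @_njit(cache=True)
    def _sw_fill_scalar(q, t, match, mismatch, go, ge):  # pragma: no cover - timed
        m, n = q.size, t.size
        H = np.zeros((m + 1, n + 1), dtype=np.int32)
        E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
        F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
        for i in range(1, m + 1):
            qc = q[i - 1]
            for j in range(1, n + 1):
                e = max(H[i, j - 1] - go - ge, E[i, j - 1] - ge)
                f = max(H[i - 1, j] - go - ge, F[i - 1, j] - ge)
                tc = t[j - 1]
                s = match if (qc == tc and tc < 4) else -mismatch
                h = H[i - 1, j - 1] + s
                if e > h:
                    h = e
                if f > h:
                    h = f
                if h < 0:
                    h = 0
                H[i, j] = h
                E[i, j] = e
                F[i, j] = f
        return H, E, F


def _sw_matrices(q: np.ndarray, t: np.ndarray, scheme: ScoringScheme):
    if HAVE_NUMBA:
        return _sw_fill_scalar(q, t, scheme.match, scheme.mismatch,
                               scheme.gap_open, scheme.gap_extend)
    return _sw_matrices_vec(q, t, scheme)


def _sw_matrices_vec(q: np.ndarray, t: np.ndarray, scheme: ScoringScheme):
    m, n = q.size, t.size
    go, ge = scheme.gap_open, scheme.gap_extend
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    j_idx = np.arange(1, n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        qc = q[i - 1]
        s = np.where((t == qc) & (t < 4), scheme.match, -scheme.mismatch).astype(np.int32)
        Fi = np.maximum(F[i - 1, 1:] - ge, H[i - 1, 1:] - go - ge)
        Ht = np.maximum(np.maximum(H[i - 1, :-1] + s, Fi), 0)
        A = Ht + ge * j_idx
        P = np.maximum.accumulate(A)
        Ei = np.empty(n, dtype=np.int32)
        Ei[0] = NEG
        Ei[1:] = P[:-1] - go - ge * j_idx[1:]
        H[i, 1:] = np.maximum(Ht, Ei)
        E[i, 1:] = Ei
        F[i, 1:] = Fi
    return H, E, F


def _traceback(H, E, F, q, t, scheme, i, j):
    go, ge = scheme.gap_open, scheme.gap_extend
    ops: list[str] = []
    state = "H"
    while True:
        if state == "H":
            v = H[i, j]
            if v == 0:
                break
            s = scheme.match if (q[i - 1] == t[j - 1] and t[j - 1] < 4) else -scheme.mismatch
            if i > 0 and j > 0 and v == H[i - 1, j - 1] + s:
                ops.append("M")
                i -= 1
                j -= 1
            elif v == F[i, j]:
                state = "F"
            elif v == E[i, j]:
                state = "E"
            else:  # pragma: no cover - DP invariant
                raise AssertionError("traceback lost")
        elif state == "F":
            ops.append("I")
            if F[i, j] == H[i - 1, j] - go - ge:
                i -= 1
                state = "H"
            else:
                i -= 1
        else:  # "E"
            ops.append("D")
            if E[i, j] == H[i, j - 1] - go - ge:
                j -= 1
                state = "H"
            else:
                j -= 1
    ops.reverse()
    return i, j, ops


def _ops_to_cigar(ops: list[str], query_start: int, query_end: int, query_len: int) -> str:
    parts = []
    if query_start:
        parts.append(f"{query_start}S")
    run, count = None, 0
    for op in ops:
        if op == run:
            count += 1
        else:
            if run:
                parts.append(f"{count}{run}")
            run, count = op, 1
    if run:
        parts.append(f"{count}{run}")
    if query_len - query_end:
        parts.append(f"{query_len - query_end}S")
    return "".join(parts)


def smith_waterman(query: str, target: str, scheme: ScoringScheme | None = None,
                   report_co_optimal: bool = False) -> LocalAlignment:
    """Optimal affine-gap local alignment of ``query`` against ``target``.

    Deterministic tie-breaking: among co-optimal end cells the smallest
    target end (then smallest query end) wins, and the traceback prefers
    diagonal over vertical over horizontal moves.  With
    ``report_co_optimal`` every co-optimal target end position (thinned to
    one representative per ``max(10, len(query)//2)`` bp) is reported, which
    flags placements falling in duplicated sequence.
    """
    if not query or not target:
        raise ValueError("query and target must be non-empty")
    scheme = scheme or DEFAULT_SCHEME
    q = encode(query)
    t = encode(target)
    H, E, F = _sw_matrices(q, t, scheme)
    best = int(H.max())
    if best <= 0:
        return LocalAlignment(0, 0, 0, 0, 0, cigar=f"{len(query)}S" if query else "")
    cells = np.argwhere(H == best)
    order = np.lexsort((cells[:, 0], cells[:, 1]))  # smallest j, then smallest i
    ei, ej = (int(cells[order[0], 0]), int(cells[order[0], 1]))
    qs, ts, ops = _traceback(H, E, F, q, t, scheme, ei, ej)
    co: list[int] = []
    if report_co_optimal:
        sep = max(10, len(query) // 2)
        for j in sorted({int(c[1]) for c in cells}):
            if not co or j - co[-1] >= sep:
                co.append(j)
    return LocalAlignment(best, qs, ei, ts, ej,
                          _ops_to_cigar(ops, qs, ei, len(query)), co)


# ---------------------------------------------------------------------------
# CIGAR utilities

def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if not num:
                raise FormatError(f"malformed CIGAR {cigar!r}")
            out.append((ch, int(num)))
            num = ""
    if num:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return out


def cigar_ref_span(cigar: str) -> int:
    return sum(n for op, n in parse_cigar(cigar) if op in "MD=XN")


# ---------------------------------------------------------------------------
# k-mer seed index

class KmerIndex:
    """Exact k-mer -> (contig, position) index; multi-mapping k-mers kept."""

    def __init__(self, contigs: Mapping[str, str], k: int = 21):
        if k < 11:
            raise ValueError("k must be >= 11 to keep seeding specific")
        if not contigs:
            raise ValueError("no contigs to index")
        shortest = min(len(s) for s in contigs.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest contig length {shortest}")
        self.k = k
        self.contigs = {name: seq.upper() for name, seq in contigs.items()}
        self._idx: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            add = self._idx.setdefault
            for pos in range(len(seq) - k + 1):
                add(seq[pos:pos + k], []).append((name, pos))

    def hits(self, kmer: str) -> list[tuple[str, int]]:
        return self._idx.get(kmer, [])


def build_kmer_index(contigs: Mapping[str, str], k: int = 21) -> KmerIndex:
    return KmerIndex(contigs, k)


# ---------------------------------------------------------------------------
# Mapped reads and the minimal mapper

@dataclass
class MappedRead:
    """One aligned (or unmapped) read; ``seq`` is plus-strand oriented."""

    name: str
    contig: str | None
    start: int
    strand: str
    cigar: str
    mapping_quality: int
    best_score: int
    second_best_score: int | None
    seq: str = ""
    is_read2: bool = False
    paired: bool = True
    properly_paired: bool = False
    mate_contig: str | None = None
    mate_start: int = -1
    mate_strand: str = "+"

    @property
    def unmapped(self) -> bool:
        return self.contig is None

    @property
    def ref_span(self) -> int:
        return cigar_ref_span(self.cigar) if self.cigar else 0

    @property
    def end(self) -> int:
        return self.start + self.ref_span


@dataclass
class _Cand:
    contig: str
    start: int
    score: int
    cigar: str
    ref_span: int
    mm: int | None = None  # ungapped mismatch count; None after SW refinement


class ReadMapper:
    """Seed-and-extend mapper over a combined master+pseudogene reference.

    Candidate loci come from exact k-mer seeds at a fixed stride; each
    candidate is scored ungapped first and refined with Smith-Waterman when
    the ungapped placement shows ``refine_mismatches`` or more mismatches
    (indels and junction-spanning reads).  Pairs are placed to maximise the
    summed score subject to orientation and insert constraints; mapping
    quality is ``min(60, 6 * (best - second_best))`` and 0 on ties, with
    tied placements resolved by a seeded random draw (the behaviour of
    standard aligners at MAPQ 0, which is what makes read competition
    between master and pseudogenes symmetric).
    """

    def __init__(self, reference: Mapping[str, str], k: int = 21,
                 scheme: ScoringScheme | None = None, seed: int = 0,
                 expected_outer: int = 200, outer_tolerance: int = 120,
                 seed_stride: int = 25, refine_mismatches: int = 5,
                 refine_margin: int = 80,
                 mapq_scale: int = 6, mapq_cap: int = 60, sw_pad: int = 20,
                 max_candidates: int = 14):
        self.scheme = scheme or DEFAULT_SCHEME
        self.index = build_kmer_index(reference, k)
        self.arrs = {name: encode(seq) for name, seq in self.index.contigs.items()}
        self.rng = random.Random(seed)
        self.expected_outer = expected_outer
        self.outer_tolerance = outer_tolerance
        self.seed_stride = seed_stride
        self.refine_mismatches = refine_mismatches
        self.refine_margin = refine_margin
        self.mapq_scale = mapq_scale
        self.mapq_cap = mapq_cap
        self.sw_pad = sw_pad
        self.max_candidates = max_candidates

    # -- candidate generation ------------------------------------------------

    def _seed_starts(self, seq: str) -> set[tuple[str, int]]:
        k = self.index.k
        L = len(seq)
        if L < k:
            return set()
        offsets = list(range(0, L - k + 1, self.seed_stride))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        cands: set[tuple[str, int]] = set()
        hits = self.index.hits
        for off in offsets:
            for name, pos in hits(seq[off:off + k]):
                cands.add((name, pos - off))
        return cands

    def _score_candidate(self, seq: str, arr: np.ndarray, contig: str, start: int) -> _Cand | None:
        ref = self.arrs[contig]
        L = len(seq)
        lclip = max(0, -start)
        rclip = max(0, start + L - ref.size)
        olen = L - lclip - rclip
        if olen < self.index.k:
            return None
        sub = ref[start + lclip: start + lclip + olen]
        mm = int(np.count_nonzero(sub != arr[lclip: lclip + olen]))
        score = self.scheme.match * (olen - mm) - self.scheme.mismatch * mm
        parts = []
        if lclip:
            parts.append(f"{lclip}S")
        parts.append(f"{olen}M")
        if rclip:
            parts.append(f"{rclip}S")
        return _Cand(contig, start + lclip, score, "".join(parts), olen, mm)

    def _refine(self, seq: str, cand: _Cand) -> _Cand | None:
        """Smith-Waterman re-alignment of a candidate placement (recovers
        indels and junction soft clips that ungapped scoring cannot see)."""
        ref = self.index.contigs[cand.contig]
        pad = self.sw_pad
        w0 = max(0, cand.start - pad)
        w1 = min(len(ref), cand.start + len(seq) + pad)
        aln = smith_waterman(seq, ref[w0:w1], self.scheme)
        if aln.is_empty:
            return None
        return _Cand(cand.contig, w0 + aln.target_start, aln.score, aln.cigar,
                     aln.target_end - aln.target_start, None)

    def _candidates(self, seq: str) -> list[_Cand]:
        arr = encode(seq)
        best: dict[tuple[str, int], _Cand] = {}
        for contig, start in self._seed_starts(seq):
            cand = self._score_candidate(seq, arr, contig, start)
            if cand is None:
                continue
            key = (cand.contig, cand.start)
            if key not in best or cand.score > best[key].score:
                best[key] = cand
        cands = sorted(best.values(), key=lambda c: (-c.score, c.contig, c.start))
        cands = cands[: self.max_candidates]
        # Only when even the best ungapped placement is heavily mismatched is
        # the read plausibly gapped or junction-spanning; then re-align every
        # competitive candidate so contig competition stays fair.
        if cands and cands[0].mm is not None and cands[0].mm >= self.refine_mismatches:
            floor = cands[0].score - self.refine_margin
            refined: dict[tuple[str, int], _Cand] = {}
            for cand in cands:
                if cand.score >= floor:
                    cand = self._refine(seq, cand) or cand
                key = (cand.contig, cand.start)
                if key not in refined or cand.score > refined[key].score:
                    refined[key] = cand
            cands = sorted(refined.values(),
                           key=lambda c: (-c.score, c.contig, c.start))
        return cands

    # -- single-end placement ------------------------------------------------

    def map_single(self, seq: str, name: str = "read") -> MappedRead:
        options: list[tuple[_Cand, str, str]] = []
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for cand in self._candidates(s):
                options.append((cand, strand, s))
        if not options:
            return MappedRead(name, None, -1, "+", "", 0, 0, None, seq,
                              paired=False)
        options.sort(key=lambda o: (-o[0].score, o[0].contig, o[0].start, o[1]))
        best_score = options[0][0].score
        co_best = [o for o in options if o[0].score == best_score]
        pick = self.rng.choice(co_best) if len(co_best) > 1 else co_best[0]
        second = best_score if len(co_best) > 1 else (
            options[len(co_best)][0].score if len(options) > len(co_best) else None)
        mapq = 0 if second == best_score else (
            self.mapq_cap if second is None else
            min(self.mapq_cap, self.mapq_scale * (best_score - second)))
        cand, strand, oriented = pick
        return MappedRead(name, cand.contig, cand.start, strand, cand.cigar,
                          mapq, best_score, second, oriented, paired=False)

    # -- paired placement ----------------------------------------------------

    def _pairings(self, cands_fwd: list[_Cand], cands_rev: list[_Cand]):
        by_contig: dict[str, list[_Cand]] = {}
        for c in cands_rev:
            by_contig.setdefault(c.contig, []).append(c)
        out = []
        for f in cands_fwd:
            for r in by_contig.get(f.contig, ()):
                frag = (r.start + r.ref_span) - f.start
                if frag < 1 or abs(frag - self.expected_outer) > self.outer_tolerance:
                    continue
                out.append((f.score + r.score, f, r))
        return out

    def map_read_pair(self, pair) -> tuple[MappedRead, MappedRead]:
        """Place both mates of a ReadPair; returns (R1, R2) records."""
        seq1, seq2, name = pair.seq1, pair.seq2, pair.name
        c1f = self._candidates(seq1)
        c2r = self._candidates(revcomp(seq2))
        c2f = self._candidates(seq2)
        c1r = self._candidates(revcomp(seq1))
        pairings = [(s, f, r, "A") for s, f, r in self._pairings(c1f, c2r)]
        pairings += [(s, f, r, "B") for s, f, r in self._pairings(c2f, c1r)]
        if not pairings:
            r1 = self.map_single(seq1, name)
            r2 = self.map_single(seq2, name)
            r1.paired = r2.paired = True
            r2.is_read2 = True
            if not r1.unmapped and not r2.unmapped:
                r1.mate_contig, r1.mate_start, r1.mate_strand = r2.contig, r2.start, r2.strand
                r2.mate_contig, r2.mate_start, r2.mate_strand = r1.contig, r1.start, r1.strand
            return r1, r2

        pairings.sort(key=lambda p: (-p[0], p[1].contig, p[1].start, p[2].start, p[3]))
        best_score = pairings[0][0]
        co_best = [p for p in pairings if p[0] == best_score]
        pick = self.rng.choice(co_best) if len(co_best) > 1 else co_best[0]
        if len(co_best) > 1:
            second = best_score
        elif len(pairings) > 1:
            second = pairings[1][0]
        else:
            second = None
        mapq = 0 if second == best_score else (
            self.mapq_cap if second is None else
            min(self.mapq_cap, self.mapq_scale * (best_score - second)))
        _score, f, r, orient = pick
        if orient == "A":  # R1 forward, R2 reverse
            r1 = MappedRead(name, f.contig, f.start, "+", f.cigar, mapq,
                            f.score, None, seq1, properly_paired=True)
            r2 = MappedRead(name, r.contig, r.start, "-", r.cigar, mapq,
                            r.score, None, revcomp(seq2), is_read2=True,
                            properly_paired=True)
        else:  # R2 forward, R1 reverse
            r2 = MappedRead(name, f.contig, f.start, "+", f.cigar, mapq,
                            f.score, None, seq2, is_read2=True, properly_paired=True)
            r1 = MappedRead(name, r.contig, r.start, "-", r.cigar, mapq,
                            r.score, None, revcomp(seq1), properly_paired=True)
        r1.best_score, r1.second_best_score = best_score, second
        r2.best_score, r2.second_best_score = best_score, second
        r1.mate_contig, r1.mate_start, r1.mate_strand = r2.contig, r2.start, r2.strand
        r2.mate_contig, r2.mate_start, r2.mate_strand = r1.contig, r1.start, r1.strand
        return r1, r2

    def map_pairs(self, pairs: Iterable) -> list[MappedRead]:
        out: list[MappedRead] = []
        for pair in pairs:
            r1, r2 = self.map_read_pair(pair)
            out.append(r1)
            out.append(r2)
        return out


# ---------------------------------------------------------------------------
# SAM interchange (plain-text SAM via pysam)

def _sam_header(reference: Mapping[str, str]):
    return {"HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": name, "LN": len(seq)} for name, seq in reference.items()]}


def write_sam(reads: Iterable[MappedRead], reference: Mapping[str, str], path) -> None:
    import pysam

    header = _sam_header(reference)
    names = list(reference)
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for read in reads:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = read.name
            flag = 0
            if read.paired:
                flag |= 0x1
                if read.properly_paired:
                    flag |= 0x2
                flag |= 0x80 if read.is_read2 else 0x40
            if read.unmapped:
                flag |= 0x4
            if read.strand == "-":
                flag |= 0x10
            if read.mate_strand == "-":
                flag |= 0x20
            a.flag = flag
            a.query_sequence = read.seq or None
            if not read.unmapped:
                a.reference_id = names.index(read.contig)
                a.reference_start = read.start
                a.mapping_quality = read.mapping_quality
                a.cigarstring = read.cigar
                a.set_tag("AS", int(read.best_score))
                if read.second_best_score is not None:
                    a.set_tag("XS", int(read.second_best_score))
            if read.mate_contig is not None:
                a.next_reference_id = names.index(read.mate_contig)
                a.next_reference_start = read.mate_start
            fh.write(a)


def load_alignments(path) -> Iterator[MappedRead]:
    """Stream MappedRead records from SAM/BAM (1-based SAM -> 0-based here)."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for i, rec in enumerate(fh.fetch(until_eof=True)):
            try:
                yield MappedRead(
                    name=rec.query_name,
                    contig=None if rec.is_unmapped else rec.reference_name,
                    start=-1 if rec.is_unmapped else rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    cigar=rec.cigarstring or "",
                    mapping_quality=rec.mapping_quality,
                    best_score=int(rec.get_tag("AS")) if rec.has_tag("AS") else 0,
                    second_best_score=int(rec.get_tag("XS")) if rec.has_tag("XS") else None,
                    seq=rec.query_sequence or "",
                    is_read2=rec.is_read2,
                    paired=rec.is_paired,
                    properly_paired=rec.is_proper_pair,
                    mate_contig=None if rec.mate_is_unmapped or rec.next_reference_id < 0
                    else rec.next_reference_name,
                    mate_start=rec.next_reference_start,
                    mate_strand="-" if rec.mate_is_reverse else "+",
                )
            except (ValueError, KeyError) as exc:
                raise FormatError(f"{path}: malformed record {i}: {exc}") from exc
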