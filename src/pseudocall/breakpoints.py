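"""Deletion-breakpoint resolution from soft-clipped reads.

Reads that span a deletion junction align up to the 5' breakpoint and carry
the sequence beyond it as a soft clip.  Clips are extracted, clustered by
their boundary coordinate, and a per-column majority consensus of each
cluster is placed back onto the locus with Smith-Waterman: the best-scoring
placement marks the 3' breakpoint.  When direct placement fails (repeat- or
rearrangement-obscured endpoints) the consensus is decomposed into 20-base
sliding windows, each window placed independently, and the extremal
confidently placed windows delimit the candidate endpoint interval; if
nothing places, the resolver falls back to the coverage-CNV-supported
interval.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .align import (LocalAlignment, MappedRead, ScoringScheme, parse_cigar,
                    smith_waterman)
from .errors import BreakpointInconsistencyError


@dataclass
class ClipRecord:
    contig: str
    pos: int        # boundary between aligned and clipped part
    side: str       # "right": clip follows the alignment; "left": precedes it
    seq: str
    read_name: str
    anchor_seq: str = ""  # aligned bases immediately inside the boundary


@dataclass
class SplitReadCluster:
    contig: str
    pos: int
    side: str
    count: int
    consensus: str
    anchor_consensus: str = ""
    read_names: list[str] = field(default_factory=list)


@dataclass
class BreakpointHypothesis:
    contig: str
    bp5: int                          # 5' breakpoint (deletion start)
    bp3_candidates: list[int]         # candidate 3' breakpoints (deletion ends)
    bp3_interval: tuple[int, int]     # delimited candidate interval
    supporting_reads: int
    placement_score: int
    method: str                       # direct-SW | window-decomposition | cnv-interval
    ambiguous: bool = False
    consistent_with_cnv: bool | None = None
    # False when the junction consensus carried no pre-junction anchor bases
    # (a repeat-drifted cluster); the 5' breakpoint is then unreliable
    anchored_evidence: bool = True


def extract_soft_clips(alignments: Iterable[MappedRead],
                       min_clip_len: int = 10) -> list[ClipRecord]:
    """One record per terminal soft clip of at least ``min_clip_len`` bases."""
    out: list[ClipRecord] = []
    for read in alignments:
        if read.unmapped or not read.cigar:
            continue
        ops = parse_cigar(read.cigar)
        if ops and ops[0][0] == "S" and ops[0][1] >= min_clip_len:
            n = ops[0][1]
            out.append(ClipRecord(read.contig, read.start, "left",
                                  read.seq[:n], read.name,
                                  anchor_seq=read.seq[n:n + 12]))
        if ops and ops[-1][0] == "S" and ops[-1][1] >= min_clip_len:
            n = ops[-1][1]
            boundary = len(read.seq) - n
            out.append(ClipRecord(read.contig, read.end, "right",
                                  read.seq[boundary:], read.name,
                                  anchor_seq=read.seq[max(0, boundary - 12):boundary]))
    return out


def _majority_consensus(seqs: Sequence[str], anchored_left: bool) -> str:
    """Per-column majority; ties go to the first-seen base.  Right-side clips
    share their left edge (anchored at the boundary), left-side clips share
    their right edge."""
    width = max(len(s) for s in seqs)
    cols: list[str] = []
    for i in range(width):
        seen: dict[str, int] = {}
        order: list[str] = []
        for s in seqs:
            j = i if anchored_left else len(s) - width + i
            if 0 <= j < len(s):
                b = s[j]
                if b not in seen:
                    seen[b] = 0
                    order.append(b)
                seen[b] += 1
        best = max(order, key=lambda b: seen[b])
        cols.append(best)
    return "".join(cols)


def cluster_clips(records: Sequence[ClipRecord], tolerance: int = 0
                  ) -> list[SplitReadCluster]:
    """Merge clips sharing a boundary (within ``tolerance``) and side;
    clusters come back ranked by supporting-read count."""
    recs = sorted(records, key=lambda r: (r.contig, r.side, r.pos))
    clusters: list[list[ClipRecord]] = []
    for r in recs:
        if (clusters and clusters[-1][0].contig == r.contig
                and clusters[-1][0].side == r.side
                and abs(r.pos - clusters[-1][-1].pos) <= tolerance):
            clusters[-1].append(r)
        else:
            clusters.append([r])
    out = []
    for group in clusters:
        anchored_left = group[0].side == "right"
        consensus = _majority_consensus([g.seq for g in group], anchored_left)
        anchors = [g.anchor_seq for g in group if g.anchor_seq]
        anchor_consensus = _majority_consensus(anchors, not anchored_left) \
            if anchors else ""
        # boundary by majority too (relevant only with tolerance > 0)
        pos_counts: dict[int, int] = {}
        for g in group:
            pos_counts[g.pos] = pos_counts.get(g.pos, 0) + 1
        pos = max(sorted(pos_counts), key=lambda p: pos_counts[p])
        out.append(SplitReadCluster(group[0].contig, pos, group[0].side,
                                    len(group), consensus, anchor_consensus,
                                    [g.read_name for g in group]))
    out.sort(key=lambda c: (-c.count, c.contig, c.pos))
    return out


def placement_floor(length: int, scheme: ScoringScheme | None = None,
                    fraction: float = 0.9) -> float:
    scheme = scheme or ScoringScheme()
    return fraction * scheme.match * length


def place_clip(consensus: str, locus_sequence: str,
               scheme: ScoringScheme | None = None,
               min_score_fraction: float = 0.9) -> LocalAlignment | None:
    """Best local placement of a clipped consensus on the locus, or None when
    the score stays below ``min_score_fraction`` of the maximum attainable
    (the trigger for window decomposition).  Co-optimal placements are
    reported so duplicated-sequence endpoints surface as ambiguous."""
    if not consensus:
        raise ValueError("empty consensus")
    aln = smith_waterman(consensus, locus_sequence, scheme, report_co_optimal=True)
    if aln.score < placement_floor(len(consensus), scheme, min_score_fraction):
        return None
    return aln


@dataclass
class WindowPlacement:
    offset: int          # window start inside the consensus
    alignment: LocalAlignment | None
    confident: bool
    ambiguous: bool


def window_decompose(consensus: str, locus_sequence: str, window: int = 20,
                     step: int = 1, scheme: ScoringScheme | None = None,
                     min_score_fraction: float = 0.9
                     ) -> tuple[list[WindowPlacement], tuple[int, int] | None]:
    """Slide ``window``-base fragments over the consensus, place each locally,
    and delimit the boundary interval from the extremal confident placements.

    Returns the per-window placements and the delimited locus interval
    (None when no window places confidently).
    """
    if len(consensus) < window:
        raise ValueError("consensus shorter than the window")
    floor = placement_floor(window, scheme, min_score_fraction)
    placements: list[WindowPlacement] = []
    confident: list[LocalAlignment] = []
    for off in range(0, len(consensus) - window + 1, step):
        frag = consensus[off:off + window]
        if set(frag) <= {"N"}:
            placements.append(WindowPlacement(off, None, False, False))
            continue
        aln = smith_waterman(frag, locus_sequence, scheme, report_co_optimal=True)
        ok = aln.score >= floor
        ambiguous = ok and len(aln.co_optimal_target_ends) > 1
        placements.append(WindowPlacement(off, aln if aln.score > 0 else None,
                                          ok, ambiguous))
        if ok:
            confident.append(aln)
    if not confident:
        return placements, None
    lo = min(a.target_start for a in confident)
    hi = max(a.target_end for a in confident)
    return placements, (lo, hi)


def _refine_junction(anchor: str, clip: str, locus: str, pos: int,
                     b3_raw: int, radius: int = 10) -> tuple[int, int, int]:
    """Joint micro-refinement of a deletion junction.

    Aligners extend a few bases past the true junction when the 3' side
    nearly matches the 5' flank (and the raw clip placement inherits the
    shift), so the cluster boundary and placement can each be off by a few
    bases.  The junction consensus — aligned anchor plus clipped bases — is
    re-split exhaustively over small offsets of both endpoints; the split
    maximising base matches (ties to the leftmost junction) is the refined
    breakpoint pair.  The split index of the winning candidate is also
    returned: a split of zero means the anchor consensus carried no
    pre-junction bases, leaving the 5' breakpoint unconstrained.
    """
    J = anchor + clip[:40]
    A = len(anchor)
    best = None
    for k in range(0, A + 1):
        # with split at J[k], the boundary and the raw clip placement are
        # both displaced by the A-k absorbed bases (give or take mismatch
        # and indel slippage covered by the radius)
        b5_center = pos - (A - k)
        b3_center = b3_raw - (A - k)
        for b5 in range(b5_center - radius, b5_center + radius + 1):
            if b5 - k < 0 or b5 > len(locus):
                continue
            left_m = sum(a == b for a, b in zip(J[:k], locus[b5 - k: b5]))
            for b3 in range(max(b5, b3_center - radius), b3_center + radius + 1):
                right = locus[b3: b3 + len(J) - k]
                m = left_m + sum(a == b for a, b in zip(J[k:], right))
                key = (m, -b5, -b3)
                if best is None or key > best[0]:
                    best = (key, b5, b3, k)
    if best is None:
        return pos, b3_raw, 0
    return best[1], best[2], best[3]


def resolve_deletion(cluster: SplitReadCluster,
                     locus_sequence: str,
                     cnv_event=None,
                     scheme: ScoringScheme | None = None,
                     window: int = 20,
                     min_score_fraction: float = 0.9,
                     max_consensus: int = 120) -> BreakpointHypothesis:
    """Resolve a deletion from a right-side clip cluster.

    The 5' breakpoint is the cluster boundary; the 3' endpoint comes from
    direct Smith-Waterman placement of the clipped consensus, falling back
    to 20-base window decomposition and finally to the CNV-supported
    interval.  A deletion whose clip places upstream of its own 5' boundary
    is geometrically impossible and raises.
    """
    if cluster.side != "right":
        raise ValueError("deletion resolution expects a right-side (5') clip cluster")
    consensus = cluster.consensus[:max_consensus]
    aln = place_clip(consensus, locus_sequence, scheme, min_score_fraction)
    if aln is not None:
        candidates = [end - (aln.target_end - aln.target_start)
                      for end in (aln.co_optimal_target_ends or [aln.target_end])]
        candidates = sorted({c - aln.query_start for c in candidates})
        downstream = [c for c in candidates if c >= cluster.pos]
        if not downstream:
            raise BreakpointInconsistencyError(
                f"clip at {cluster.pos} places only upstream ({candidates})")
        bp5 = cluster.pos
        anchored = True
        if len(downstream) == 1 and cluster.anchor_consensus:
            bp5, b3, k_used = _refine_junction(cluster.anchor_consensus,
                                               consensus, locus_sequence,
                                               cluster.pos, downstream[0])
            downstream = [b3]
            anchored = k_used > 0
        hyp = BreakpointHypothesis(
            cluster.contig, bp5, downstream,
            (min(downstream), max(downstream)), cluster.count, aln.score,
            "direct-SW", ambiguous=len(downstream) > 1)
        hyp.anchored_evidence = anchored
    else:
        if len(consensus) >= window:
            _placements, interval = window_decompose(
                consensus, locus_sequence, window, 1, scheme, min_score_fraction)
        else:
            interval = None
        if interval is not None:
            hyp = BreakpointHypothesis(cluster.contig, cluster.pos, [],
                                       interval, cluster.count, 0,
                                       "window-decomposition")
        elif cnv_event is not None:
            hyp = BreakpointHypothesis(cluster.contig, cluster.pos, [],
                                       (cnv_event.start, cnv_event.end),
                                       cluster.count, 0, "cnv-interval")
        else:
            hyp = BreakpointHypothesis(cluster.contig, cluster.pos, [],
                                       (cluster.pos, len(locus_sequence)),
                                       cluster.count, 0, "unresolved")
    if cnv_event is not None:
        lo, hi = hyp.bp3_interval
        hyp.consistent_with_cnv = (cnv_event.contig == cluster.contig
                                   and cnv_event.start - 1000 <= cluster.pos
                                   and lo <= cnv_event.end + 1000)
    return hyp


def write_breakpoint_report(hypotheses: Sequence[BreakpointHypothesis], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tbp5\tbp3_interval\tbp3_candidates\tsupport\t"
                 "method\tambiguous\tconsistent_with_cnv\n")
        for h in hypotheses:
            cands = ",".join(map(str, h.bp3_candidates)) or "."
            fh.write(f"{h.contig}\t{h.bp5}\t{h.bp3_interval[0]}-{h.bp3_interval[1]}\t"
                     f"{cands}\t{h.supporting_reads}\t{h.method}\t"
                     f"{int(h.ambiguous)}\t{h.consistent_with_cnv}\n")
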