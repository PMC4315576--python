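"""Scoring calls against truth and detection-rate reporting.

The evaluation region is the exon set dilated by a flank (30 bp by
default); truth variants and calls outside it are ignored.  A call matches
a truth variant when position and alleles agree after left-normalisation;
near misses (within one base, same type) are reported as a separate
discordance class, not as matches.  Specificity uses a per-site negative
universe: every evaluated reference position with neither a truth variant
nor a call is a true negative.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .calling import VariantCall, left_normalize
from .errors import TallyError
from .intervals import Interval, dilate_intervals, point_in_intervals, total_length
from .locus import TruthSet, Variant


@dataclass(frozen=True)
class EvalParams:
    flank: int = 30
    count_relaxed_tier: bool = False
    negative_universe: str = "per-site"

    def __post_init__(self):
        if self.flank < 0:
            raise ValueError("flank must be >= 0")


@dataclass
class VariantStatus:
    variant: Variant
    status: str  # detected | near-miss | missed
    call: VariantCall | None = None


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    zygosity_concordance: float
    evaluated_positions: int
    per_variant: list[VariantStatus] = field(default_factory=list)
    class_tallies: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k in ("tp", "fp", "fn", "tn"):
                fh.write(f"{k}\t{getattr(self, k)}\n")
            fh.write(f"sensitivity\t{self.sensitivity:.6f}\n")
            fh.write(f"specificity\t{self.specificity:.6f}\n")
            fh.write(f"zygosity_concordance\t{self.zygosity_concordance:.6f}\n")
            fh.write(f"evaluated_positions\t{self.evaluated_positions}\n")
            for cls, (total, det) in sorted(self.class_tallies.items()):
                fh.write(f"class:{cls}\t{det}/{total}\n")
            fh.write("pos\tref\talt\tclass\tstatus\n")
            for vs in self.per_variant:
                v = vs.variant
                fh.write(f"{v.pos}\t{v.ref}\t{v.alt}\t{v.var_class}\t{vs.status}\n")


def compare_to_truth(calls: Sequence[VariantCall], truth: TruthSet,
                     exons: Sequence[Interval], params: EvalParams | None = None,
                     reference_sequence: str = "",
                     master_length: int | None = None) -> EvalReport:
    """Score ``calls`` against ``truth`` inside exons +/- flank.

    ``reference_sequence`` (the master contig) enables left-normalisation of
    indel representations before matching.
    """
    params = params or EvalParams()
    bound = master_length if master_length is not None else (
        len(reference_sequence) if reference_sequence else None)
    region = dilate_intervals(exons, params.flank, bound)

    def norm(pos, ref, alt):
        if reference_sequence:
            return left_normalize(pos, ref, alt, reference_sequence)
        return (pos, ref, alt)

    truth_eval = [v for v in truth if point_in_intervals(v.pos, region)]
    calls_eval = [c for c in calls if point_in_intervals(c.pos, region)]
    for c in calls_eval:
        if reference_sequence and reference_sequence[c.pos:c.pos + len(c.ref)] != c.ref:
            raise ValueError(
                f"call ref {c.ref!r} at {c.pos} disagrees with the reference "
                "(coordinate-system mismatch?)")

    truth_keys = {norm(v.pos, v.ref, v.alt): v for v in truth_eval}
    call_keys = {norm(c.pos, c.ref, c.alt): c for c in calls_eval}
    calls_by_pos: dict[int, list[VariantCall]] = {}
    for (npos, _r, _a), c in call_keys.items():
        calls_by_pos.setdefault(npos, []).append(c)

    per_variant: list[VariantStatus] = []
    tp = 0
    zyg_ok = 0
    matched_calls = set()
    for key, v in sorted(truth_keys.items()):
        call = call_keys.get(key)
        if call is not None:
            tp += 1
            matched_calls.add(id(call))
            if call.zygosity == v.zygosity:
                zyg_ok += 1
            per_variant.append(VariantStatus(v, "detected", call))
            continue
        near = None
        v_is_indel = len(v.ref) != len(v.alt)
        for dpos in (-1, 0, 1):
            for cand in calls_by_pos.get(key[0] + dpos, ()):
                if id(cand) not in matched_calls and cand.is_indel == v_is_indel:
                    near = cand
                    break
            if near:
                break
        per_variant.append(VariantStatus(v, "near-miss" if near else "missed", near))
    fn = len(truth_eval) - tp
    fp = sum(1 for c in calls_eval if id(c) not in matched_calls)

    evaluated = total_length(region)
    occupied = len({v.pos for v in truth_eval} | {c.pos for c in calls_eval})
    tn = evaluated - occupied

    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    zyg_conc = zyg_ok / tp if tp else 0.0

    class_tallies: dict[str, tuple[int, int]] = {}
    for vs in per_variant:
        cls = vs.variant.var_class
        total, det = class_tallies.get(cls, (0, 0))
        class_tallies[cls] = (total + 1, det + (1 if vs.status == "detected" else 0))

    return EvalReport(tp, fp, fn, tn, sensitivity, specificity, zyg_conc,
                      evaluated, per_variant, class_tallies)


@dataclass
class DetectionRateRow:
    category: str
    total: int
    detected: int
    rate_percent: float

    @property
    def rate_str(self) -> str:
        return f"{self.rate_percent:.1f}%"


def detection_rate_table(tallies: Sequence[tuple[str, int, int]]
                         ) -> list[DetectionRateRow]:
    """Detection rates as percentages rounded half-up to one decimal."""
    rows = []
    for category, total, detected in tallies:
        if detected > total:
            raise TallyError(f"{category}: detected {detected} > total {total}")
        if total <= 0:
            raise TallyError(f"{category}: total must be positive")
        pct = Decimal(100 * detected) / Decimal(total)
        pct = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        rows.append(DetectionRateRow(category, total, detected, pct))
    return rows
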