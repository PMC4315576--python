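"""Depth-of-coverage CNV detection against a control panel.

Each sample's per-target mean depth is internally normalised (sample mean
over targets scaled to 1) and compared per target against every control of
the same batch as a log2 ratio.  A target is a *pass* event when its ratio
clears the direction's log2 threshold (+0.6 amplification / -0.6 deletion)
against at least 85% of controls, and *indicated* between 50% and 85%
control support.  Adjacent passing targets merge into one event, so a
seven-exon deletion reads out as one call.  A filter ledger then knocks out
calls in regions known to misbehave — critical exons with restricted
discriminative mapping, recurrent artifact exons, low/varying-coverage
exons — and deletion calls that contain heterozygous variant evidence (a
true heterozygous deletion cannot show het sites).

An MLPA-style comparator (relative peak area ratio, deletion below 75%) and
per-target coverage QC complete the module.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import MappedRead
from .calling import VariantCall
from .intervals import Interval, overlaps

Target = tuple[str, int, int, str]  # contig, start, end, name


@dataclass(frozen=True)
class CnvParams:
    log2_amp: float = 0.6
    log2_del: float = -0.6
    support_pass: float = 0.85
    support_indicated: float = 0.50
    max_segment_size: int = 300
    min_controls: int = 3
    recommended_controls: int = 6
    critical_regions: tuple[Target, ...] = ()
    artifact_regions: tuple[Target, ...] = ()
    lowcov_regions: tuple[Target, ...] = ()

    def __post_init__(self):
        if not (0 < self.support_indicated < self.support_pass <= 1.0):
            raise ValueError("need 0 < support_indicated < support_pass <= 1")
        if not (self.log2_del < 0 < self.log2_amp):
            raise ValueError("log2 thresholds must bracket zero")


@dataclass
class CnvCall:
    contig: str
    start: int
    end: int
    targets: list[str]
    direction: str  # del | amp
    median_log2: float
    support_fraction: float
    status: str  # pass | indicated | filtered
    filter_reasons: set[str] = field(default_factory=set)

    @property
    def region(self) -> Interval:
        return (self.start, self.end)


def split_targets(targets: Sequence[Target], max_segment_size: int = 300) -> list[Target]:
    """Split targets longer than ``max_segment_size`` into equal sub-segments."""
    out: list[Target] = []
    for contig, start, end, name in targets:
        length = end - start
        if length <= max_segment_size:
            out.append((contig, start, end, name))
            continue
        n = math.ceil(length / max_segment_size)
        bounds = np.linspace(start, end, n + 1).astype(int)
        for i in range(n):
            out.append((contig, int(bounds[i]), int(bounds[i + 1]), f"{name}.{i + 1}"))
    return out


def depth_from_alignments(alignments: Iterable[MappedRead], contig: str,
                          length: int, min_mapping_quality: int = 0) -> np.ndarray:
    """Per-base aligned depth over one contig (difference-array accumulation)."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for read in alignments:
        if read.unmapped or read.contig != contig:
            continue
        if read.mapping_quality < min_mapping_quality:
            continue
        s = max(0, read.start)
        e = min(length, read.end)
        if e > s:
            diff[s] += 1
            diff[e] -= 1
    return np.cumsum(diff[:-1])


def target_coverage_matrix(sample_depths: Mapping[str, Mapping[str, np.ndarray]],
                           targets: Sequence[Target]) -> pd.DataFrame:
    """Mean per-base depth per target per sample (samples x targets).

    ``sample_depths`` maps sample name -> contig -> per-base depth array.
    """
    if not sample_depths:
        raise ValueError("need at least one sample")
    names = [t[3] for t in targets]
    if len(set(names)) != len(names):
        raise ValueError("duplicate target names")
    rows = {}
    for sample, depths in sample_depths.items():
        vals = []
        for contig, start, end, _name in targets:
            if contig not in depths:
                raise ValueError(f"sample {sample!r} has no depth for contig {contig!r}")
            arr = depths[contig]
            if end > arr.size:
                raise ValueError(f"target {start}-{end} outside contig {contig!r}")
            vals.append(float(arr[start:end].mean()) if end > start else 0.0)
        rows[sample] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def normalize_coverage(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample (row) so its mean target depth is 1."""
    means = matrix.mean(axis=1)
    if (means == 0).any():
        dead = means[means == 0].index.tolist()
        raise ValueError(f"samples with zero coverage: {dead}")
    return matrix.div(means, axis=0)


def normalize_and_ratio(matrix: pd.DataFrame, index_sample: str,
                        control_samples: Sequence[str],
                        params: CnvParams | None = None) -> pd.DataFrame:
    """log2(normalised index / normalised control) per target per control.

    Targets where a control has zero normalised depth get NaN ratios (they
    surface through the low-coverage ledger, not as events).
    """
    params = params or CnvParams()
    if index_sample in control_samples:
        raise ValueError("index sample cannot be its own control")
    if len(control_samples) < params.min_controls:
        raise ValueError(f"need at least {params.min_controls} controls")
    norm = normalize_coverage(matrix.loc[[index_sample, *control_samples]])
    idx = norm.loc[index_sample]
    out = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for ctrl in control_samples:
            denom = norm.loc[ctrl]
            ratio = np.where(denom > 0, idx / denom, np.nan)
            ratio = np.where(ratio > 0, ratio, np.nan)
            out[ctrl] = np.log2(ratio.astype(float))
    return pd.DataFrame(out, index=matrix.columns)


def call_cnv(ratios: pd.DataFrame, targets: Sequence[Target],
             params: CnvParams | None = None) -> list[CnvCall]:
    """Support-fraction CNV calls with merging of adjacent passing targets.

    ``ratios`` is targets x controls as from :func:`normalize_and_ratio`;
    ``targets`` supplies genomic spans and the (contig-wise) adjacency order.
    """
    params = params or CnvParams()
    by_name = {t[3]: t for t in targets}
    per_target: list[CnvCall] = []
    for name in ratios.index:
        contig, start, end, _ = by_name[name]
        row = ratios.loc[name].dropna()
        if row.empty:
            continue
        for direction, ok in (("del", row <= params.log2_del),
                              ("amp", row >= params.log2_amp)):
            support = float(ok.mean())
            if support >= params.support_pass:
                status = "pass"
            elif support >= params.support_indicated:
                status = "indicated"
            else:
                continue
            per_target.append(CnvCall(contig, start, end, [name], direction,
                                      float(row.median()), support, status))
    # merge runs of adjacent passing targets of the same direction
    order = {t[3]: i for i, t in enumerate(targets)}
    per_target.sort(key=lambda c: order[c.targets[0]])
    merged: list[CnvCall] = []
    for call in per_target:
        prev = merged[-1] if merged else None
        if (prev is not None and call.status == "pass" and prev.status == "pass"
                and call.direction == prev.direction and call.contig == prev.contig
                and order[call.targets[0]] == order[prev.targets[-1]] + 1):
            prev.end = call.end
            prev.targets.append(call.targets[0])
            prev.median_log2 = float(np.median([prev.median_log2, call.median_log2]))
            prev.support_fraction = min(prev.support_fraction, call.support_fraction)
        else:
            merged.append(call)
    return merged


def apply_filter_ledger(calls: Sequence[CnvCall], params: CnvParams,
                        het_variant_evidence: Sequence[VariantCall] = (),
                        het_band: tuple[float, float] = (0.20, 0.80)) -> list[CnvCall]:
    """Final status after the named-region and het-evidence filters.

    Reasons are a set, so filter order is immaterial.  Het evidence only
    counts against deletion calls: standard-tier heterozygous calls with an
    alt fraction inside ``het_band`` located inside the call span.
    """
    ledger = (("critical-region", params.critical_regions),
              ("artifact-region", params.artifact_regions),
              ("low-coverage-region", params.lowcov_regions))
    out: list[CnvCall] = []
    for call in calls:
        reasons: set[str] = set(call.filter_reasons)
        for reason, regions in ledger:
            for contig, s, e, _name in regions:
                if contig == call.contig and overlaps((s, e), (call.start, call.end)):
                    reasons.add(reason)
                    break
        if call.direction == "del":
            for v in het_variant_evidence:
                if (v.contig == call.contig and call.start <= v.pos < call.end
                        and v.zygosity == "het" and v.tier == "standard"
                        and het_band[0] <= v.alt_fraction <= het_band[1]):
                    reasons.add("het-evidence")
                    break
        status = "filtered" if reasons else call.status
        out.append(replace_call(call, status=status, filter_reasons=reasons))
    return out


def replace_call(call: CnvCall, **kw) -> CnvCall:
    fields = dict(contig=call.contig, start=call.start, end=call.end,
                  targets=list(call.targets), direction=call.direction,
                  median_log2=call.median_log2,
                  support_fraction=call.support_fraction,
                  status=call.status, filter_reasons=set(call.filter_reasons))
    fields.update(kw)
    return CnvCall(**fields)


# ---------------------------------------------------------------------------
# MLPA-style comparator

@dataclass
class MlpaProbe:
    name: str
    ratio: float | None
    status: str  # deletion | normal | undefined


def mlpa_ratio(sample_rpa: Mapping[str, float], control_rpa: Mapping[str, float],
               deletion_threshold: float = 0.75) -> list[MlpaProbe]:
    """Relative-peak-area ratios; a probe flags a deletion when its
    sample/control ratio falls strictly below ``deletion_threshold``."""
    if set(sample_rpa) != set(control_rpa):
        raise ValueError("sample and control probe sets differ")
    out = []
    for name in sample_rpa:
        ctrl = control_rpa[name]
        if ctrl == 0:
            out.append(MlpaProbe(name, None, "undefined"))
            continue
        ratio = sample_rpa[name] / ctrl
        out.append(MlpaProbe(name, ratio, "deletion" if ratio < deletion_threshold
                             else "normal"))
    return out


# ---------------------------------------------------------------------------
# Coverage QC

def coverage_qc(depths: Mapping[str, np.ndarray], targets: Sequence[Target],
                floor: int = 20) -> tuple[pd.DataFrame, dict]:
    """Per-target mean depth and fraction of bases at or above ``floor``,
    plus aggregate statistics and the low-coverage target list."""
    rows = []
    for contig, start, end, name in targets:
        arr = depths[contig][start:end]
        if arr.size == 0:
            rows.append((name, contig, start, end, 0.0, 0.0))
            continue
        rows.append((name, contig, start, end, float(arr.mean()),
                     float((arr >= floor).mean())))
    df = pd.DataFrame(rows, columns=["target", "contig", "start", "end",
                                     "mean_depth", "frac_ge_floor"]).set_index("target")
    total = sum(e - s for _c, s, e, _n in targets)
    covered = sum((depths[c][s:e] >= floor).sum() for c, s, e, _n in targets)
    agg = {
        "mean_depth": float(np.mean(df["mean_depth"])) if len(df) else 0.0,
        "frac_bases_ge_floor": float(covered / total) if total else 0.0,
        "lowcov_targets": df.index[df["frac_ge_floor"] < 1.0].tolist(),
    }
    return df, agg


def write_cnv_report(calls: Sequence[CnvCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\ttargets\tdirection\tmedian_log2\t"
                 "support_fraction\tstatus\tfilter_reasons\n")
        for c in calls:
            reasons = ",".join(sorted(c.filter_reasons)) or "."
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{','.join(c.targets)}\t"
                     f"{c.direction}\t{c.median_log2:.3f}\t{c.support_fraction:.3f}\t"
                     f"{c.status}\t{reasons}\n")
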