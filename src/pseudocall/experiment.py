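"""End-to-end synthetic validation experiments.

Three orchestrated studies, all fully reproducible from a single seed:

* :func:`run_validation_experiment` — the core variant-detection study:
  synthesise a master/pseudogene locus, plant truth variants (divergent
  plus pseudogene-matched classes), simulate deep paired-end reads from the
  master haplotypes and wild-type pseudogenes, map competitively, run the
  two-step tiered caller and score against truth.
* :func:`run_cnv_experiment` — plant a heterozygous multi-exon deletion in
  an index sample, simulate a control panel, and run depth-ratio CNV
  calling, including control-versus-control specificity runs.
* :func:`run_breakpoint_experiment` — plant random deletions and recover
  their breakpoints from soft-clipped reads.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import MappedRead, ReadMapper
from .breakpoints import (BreakpointHypothesis, cluster_clips,
                          extract_soft_clips, resolve_deletion)
from .calling import (CallingThresholds, CriticalSite, RegionPileup,
                      VariantCall, build_region_pileup, critical_exons,
                      detect_critical_sites, two_step_screen, write_calls_vcf)
from .cnv import (CnvCall, CnvParams, Target, call_cnv, depth_from_alignments,
                  normalize_and_ratio, split_targets, target_coverage_matrix)
from .evaluate import EvalParams, EvalReport, compare_to_truth
from .locus import (LocusModel, LocusParams, TruthSet, generate_master_locus,
                    derive_pseudogenes, plant_divergent_site_variants,
                    plant_matched_variants, plant_variants,
                    write_duplicated_bed, write_exon_bed, write_locus_fasta,
                    MASTER_NAME)
from .reads import (ReadPair, ReadSimParams, make_haplotypes,
                    pairs_for_coverage, simulate_read_pairs, write_fastq)
from .seq import random_sequence

_MOD = 2 ** 31 - 1


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1_000_003 + k) % _MOD


# ---------------------------------------------------------------------------
# Variant-detection validation experiment

@dataclass(frozen=True)
class ValidationConfig:
    locus: LocusParams = field(default_factory=LocusParams)
    reads: ReadSimParams = field(default_factory=ReadSimParams)
    thresholds: CallingThresholds = field(default_factory=CallingThresholds)
    eval_params: EvalParams = field(default_factory=EvalParams)
    mutation_rate: float = 0.02
    density_mode: str = "per-100bp"
    n_matched_variants: int = 20
    n_divergent_variants: int = 40
    mapper_k: int = 21
    seed: int = 0
    out_dir: str | None = None
    write_reads: bool = False

    @classmethod
    def from_yaml(cls, path) -> "ValidationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub_cls in (("locus", LocusParams), ("reads", ReadSimParams),
                             ("thresholds", CallingThresholds),
                             ("eval_params", EvalParams)):
            if key in raw:
                kwargs[key] = sub_cls(**raw.pop(key))
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class ValidationResult:
    locus: LocusModel
    truth: TruthSet
    standard_calls: list[VariantCall]
    relaxed_candidates: list[VariantCall]
    critical_sites: list[CriticalSite]
    report: EvalReport
    pileup: RegionPileup
    site_fractions: list[dict]
    n_pairs: int

    @property
    def divergent_detection(self) -> tuple[int, int]:
        return self.report.class_tallies.get("divergent", (0, 0))

    @property
    def divergent_sensitivity(self) -> float:
        total, det = self.divergent_detection
        return det / total if total else 0.0

    @property
    def depressed_matched_sites(self) -> list[dict]:
        """Matched-class truth sites whose observed alt fraction falls more
        than 3 binomial sigma below its truth expectation."""
        out = []
        for rec in self.site_fractions:
            if rec["var_class"] != "pseudogene_matched" or rec["depth"] == 0:
                continue
            exp = rec["expected_fraction"]
            sigma = (exp * (1 - exp) / rec["depth"]) ** 0.5
            if rec["observed_fraction"] < exp - 3 * sigma:
                out.append(rec)
        return out

    @property
    def critical_exon_list(self) -> list[int]:
        return critical_exons(self.critical_sites, self.locus.exons)


def _simulate_locus_reads(locus: LocusModel, truth: TruthSet,
                          params: ReadSimParams, seed: int) -> list[ReadPair]:
    """Master haplotypes at half the target coverage each; every pseudogene
    contig wild type at full coverage (equal per-contig fold coverage)."""
    pairs: list[ReadPair] = []
    frag = params.outer_distance
    haps = make_haplotypes(locus.master_sequence, truth)
    for i, hap in enumerate(haps):
        n = pairs_for_coverage(len(hap.seq), params.target_coverage / 2, frag)
        rng = np.random.default_rng(_sub_seed(seed, 100 + i))
        pairs.extend(simulate_read_pairs(hap.seq, params, n,
                                         contig=MASTER_NAME, hap=i, rng=rng))
    for j, pseq in enumerate(locus.pseudogene_sequences):
        n = pairs_for_coverage(len(pseq), params.target_coverage, frag)
        rng = np.random.default_rng(_sub_seed(seed, 200 + j))
        pairs.extend(simulate_read_pairs(pseq, params, n,
                                         contig=f"pseudo{j + 1}", hap=0, rng=rng))
    return pairs


def run_validation_experiment(config: ValidationConfig) -> ValidationResult:
    """Simulate -> map -> call -> evaluate, reproducibly from one seed."""
    seed = config.seed
    lp = dataclasses.replace(config.locus, seed=_sub_seed(seed, 1))
    locus = generate_master_locus(lp)
    derive_pseudogenes(locus, lp)

    truth = TruthSet([])
    if lp.n_pseudogenes > 0:
        if config.n_matched_variants > 0:
            matched = plant_matched_variants(locus, n=config.n_matched_variants,
                                             seed=_sub_seed(seed, 2))
            truth = truth.merged_with(matched)
        if config.n_divergent_variants > 0:
            divergent = plant_divergent_site_variants(
                locus, n=config.n_divergent_variants, seed=_sub_seed(seed, 5),
                avoid=truth.positions(), neutralized_sites=truth.positions())
            truth = truth.merged_with(divergent)
    background = plant_variants(locus, density_mode=config.density_mode,
                                mutation_rate=config.mutation_rate,
                                seed=_sub_seed(seed, 3),
                                avoid=truth.positions())
    truth = truth.merged_with(background)
    truth.validate_refs(locus)

    pairs = _simulate_locus_reads(locus, truth, config.reads, seed)

    reference = locus.contigs()
    tol = max(120, 4 * config.reads.outer_distance_sd)
    mapper = ReadMapper(reference, k=config.mapper_k, seed=_sub_seed(seed, 4),
                        expected_outer=config.reads.outer_distance,
                        outer_tolerance=tol)
    mapped = mapper.map_pairs(pairs)

    pileup = build_region_pileup(mapped, reference,
                                 (MASTER_NAME, 0, locus.master_length),
                                 config.thresholds)
    standard, relaxed = two_step_screen(pileup.sites(), locus.duplicated_intervals,
                                        config.thresholds)
    crit = detect_critical_sites(truth, pileup, standard, config.thresholds)

    calls_for_eval = list(standard)
    if config.eval_params.count_relaxed_tier:
        calls_for_eval += relaxed
    report = compare_to_truth(calls_for_eval, truth, locus.exons,
                              config.eval_params,
                              reference_sequence=locus.master_sequence)

    site_fractions = []
    for v in truth:
        observed, depth = pileup.observed_fraction(v.pos, v.ref, v.alt)
        site_fractions.append({
            "pos": v.pos, "var_class": v.var_class, "vtype": v.vtype,
            "expected_fraction": 1.0 if v.zygosity == "hom" else 0.5,
            "observed_fraction": observed,
            "depth": depth,
        })

    result = ValidationResult(locus, truth, standard, relaxed, crit, report,
                              pileup, site_fractions, len(pairs))
    if config.out_dir:
        _write_validation_artifacts(result, pairs, mapped, config)
    return result


def _write_validation_artifacts(result: ValidationResult, pairs, mapped,
                                config: ValidationConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_locus_fasta(result.locus, out / "reference.fa")
    write_exon_bed(result.locus, out / "exons.bed")
    write_duplicated_bed(result.locus, out / "duplicated.bed")
    result.truth.to_vcf(out / "truth.vcf")
    lengths = {n: len(s) for n, s in result.locus.contigs().items()}
    write_calls_vcf(result.standard_calls + result.relaxed_candidates,
                    out / "calls.vcf", lengths)
    result.report.to_tsv(out / "report.tsv")
    with open(out / "critical_sites.tsv", "w") as fh:
        fh.write("contig\tpos\texpected\tobserved\treason\n")
        for cs in result.critical_sites:
            fh.write(f"{cs.contig}\t{cs.pos}\t{cs.expected_fraction:.3f}\t"
                     f"{cs.observed_fraction:.3f}\t{cs.reason}\n")
    if config.write_reads:
        write_fastq(pairs, out / "reads_R1.fastq", out / "reads_R2.fastq")
        from .align import write_sam
        write_sam(mapped, result.locus.contigs(), out / "alignments.sam")


# ---------------------------------------------------------------------------
# CNV experiment

@dataclass
class CnvStudy:
    locus: LocusModel
    targets: list[Target]
    deleted_exons: list[int]
    deletion_interval: tuple[int, int]
    index_calls: list[CnvCall]
    control_pass_calls: int
    index_alignments: list[MappedRead]
    matrix: "object"  # pandas DataFrame (samples x targets)


def run_cnv_experiment(deleted_exons: Sequence[int],
                       n_controls: int = 6,
                       coverage: float = 600.0,
                       seed: int = 0,
                       locus_params: LocusParams | None = None,
                       read_params: ReadSimParams | None = None,
                       cnv_params: CnvParams | None = None) -> CnvStudy:
    """Heterozygous deletion of consecutive exons versus a control panel.

    The index sample is simulated as one wild-type haplotype plus one
    haplotype missing the deleted exons (breakpoints placed mid-intron), at
    half the panel coverage each, so deleted exons sit near a 0.5 depth
    ratio.  Control-versus-control comparisons quantify specificity.
    """
    deleted_exons = sorted(deleted_exons)
    if deleted_exons and deleted_exons != list(range(deleted_exons[0],
                                                     deleted_exons[-1] + 1)):
        raise ValueError("deleted exons must be consecutive")
    lp = locus_params or LocusParams(n_pseudogenes=0)
    lp = dataclasses.replace(lp, n_pseudogenes=0, seed=_sub_seed(seed, 1))
    rp = read_params or ReadSimParams(target_coverage=coverage,
                                      base_error_rate=0.001)
    params = cnv_params or CnvParams()
    locus = generate_master_locus(lp)
    master = locus.master_sequence

    half_intron = lp.intron_length // 2
    if deleted_exons:
        s = locus.exon_interval(deleted_exons[0])[0] - half_intron
        e = locus.exon_interval(deleted_exons[-1])[1] + half_intron
    else:
        s = e = 0
    del_hap = master[:s] + master[e:]

    frag = rp.outer_distance
    mapper = ReadMapper({MASTER_NAME: master}, seed=_sub_seed(seed, 2),
                        expected_outer=rp.outer_distance)

    depths = {}
    index_alignments: list[MappedRead] = []
    sample_names = [f"ctrl{i + 1}" for i in range(n_controls)] + ["index"]
    for si, name in enumerate(sample_names):
        pairs: list[ReadPair] = []
        if name == "index" and deleted_exons:
            n1 = pairs_for_coverage(len(master), coverage / 2, frag)
            n2 = pairs_for_coverage(len(del_hap), coverage / 2, frag)
            rng = np.random.default_rng(_sub_seed(seed, 50 + si))
            pairs += simulate_read_pairs(master, rp, n1, contig=MASTER_NAME,
                                         hap=0, rng=rng)
            pairs += simulate_read_pairs(del_hap, rp, n2, contig=MASTER_NAME,
                                         hap=1, rng=rng)
        else:
            n = pairs_for_coverage(len(master), coverage, frag)
            rng = np.random.default_rng(_sub_seed(seed, 50 + si))
            pairs += simulate_read_pairs(master, rp, n, contig=MASTER_NAME,
                                         hap=0, rng=rng)
        mapped = mapper.map_pairs(pairs)
        if name == "index":
            index_alignments = mapped
        depths[name] = {MASTER_NAME: depth_from_alignments(mapped, MASTER_NAME,
                                                           len(master))}

    targets = split_targets(
        [(MASTER_NAME, s0, e0, f"exon{i}") for i, (s0, e0) in
         enumerate(locus.exons, start=1)], params.max_segment_size)
    matrix = target_coverage_matrix(depths, targets)

    controls = sample_names[:-1]
    ratios = normalize_and_ratio(matrix, "index", controls, params)
    index_calls = call_cnv(ratios, targets, params)

    ctrl_pass = 0
    for ci, ctrl in enumerate(controls):
        others = [c for c in controls if c != ctrl]
        r = normalize_and_ratio(matrix, ctrl, others, params)
        ctrl_pass += sum(1 for c in call_cnv(r, targets, params)
                         if c.status == "pass")

    return CnvStudy(locus, targets, list(deleted_exons), (s, e), index_calls,
                    ctrl_pass, index_alignments, matrix)


# ---------------------------------------------------------------------------
# Breakpoint experiment

@dataclass
class BreakpointTrial:
    truth_start: int
    truth_end: int
    hypothesis: BreakpointHypothesis | None
    recovered: bool


@dataclass
class BreakpointStudy:
    trials: list[BreakpointTrial]

    @property
    def recovery_rate(self) -> float:
        if not self.trials:
            return 0.0
        return sum(t.recovered for t in self.trials) / len(self.trials)


def _normalize_deletion(ref: str, b5: int, b3: int) -> tuple[int, int]:
    """Leftmost representation of a deletion interval under microhomology."""
    while b5 > 0 and b3 > 0 and ref[b5 - 1] == ref[b3 - 1]:
        b5 -= 1
        b3 -= 1
    return b5, b3


def run_breakpoint_experiment(n_deletions: int = 50,
                              seed: int = 0,
                              contig_length: int = 9000,
                              del_size_range: tuple[int, int] = (500, 5000),
                              coverage: float = 60.0,
                              sim_window: int = 1500,
                              read_params: ReadSimParams | None = None
                              ) -> BreakpointStudy:
    """Plant random deletions with unique flanks and recover breakpoints.

    Reads are simulated from a window around each junction of the deleted
    haplotype, mapped back to the intact reference, and the top right-side
    clip cluster is resolved.  Recovery means both breakpoints within one
    base of truth after microhomology left-normalisation.
    """
    rp = read_params or ReadSimParams(target_coverage=coverage,
                                      base_error_rate=0.001)
    rng = np.random.default_rng(_sub_seed(seed, 7))
    trials: list[BreakpointTrial] = []
    for t in range(n_deletions):
        ref = random_sequence(contig_length, rng)
        dl = int(rng.integers(del_size_range[0], del_size_range[1] + 1))
        a = int(rng.integers(400, contig_length - dl - 400))
        b = a + dl
        hap = ref[:a] + ref[b:]
        w0 = max(0, a - sim_window)
        w1 = min(len(hap), a + sim_window)
        sub = hap[w0:w1]
        n = pairs_for_coverage(len(sub), coverage, rp.outer_distance)
        pairs = simulate_read_pairs(sub, rp, n, contig="delhap",
                                    rng=np.random.default_rng(_sub_seed(seed, 1000 + t)))
        mapper = ReadMapper({"ref": ref}, seed=_sub_seed(seed, 2000 + t),
                            expected_outer=rp.outer_distance)
        mapped = mapper.map_pairs(pairs)
        clips = extract_soft_clips(mapped, min_clip_len=10)
        clusters = [c for c in cluster_clips(clips) if c.side == "right"]
        if not clusters:
            trials.append(BreakpointTrial(a, b, None, False))
            continue
        # prefer the best-supported cluster whose junction consensus retains
        # pre-junction anchor bases (repeat drift can strip the top cluster)
        hyp = None
        for cluster in clusters[:5]:
            try:
                cand_hyp = resolve_deletion(cluster, ref)
            except Exception:
                continue
            if hyp is None:
                hyp = cand_hyp
            if cand_hyp.anchored_evidence:
                hyp = cand_hyp
                break
        if hyp is None:
            trials.append(BreakpointTrial(a, b, None, False))
            continue
        ta, tb = _normalize_deletion(ref, a, b)
        recovered = False
        for cand in hyp.bp3_candidates:
            hb5, hb3 = _normalize_deletion(ref, hyp.bp5, cand)
            if abs(hb5 - ta) <= 1 and abs(hb3 - tb) <= 1:
                recovered = True
                break
        trials.append(BreakpointTrial(a, b, hyp, recovered))
    return BreakpointStudy(trials)


def run_ambiguous_breakpoint_case(seed: int = 0, coverage: float = 60.0
                                  ) -> BreakpointHypothesis:
    """A deletion ending inside sequence present twice in the reference:
    the 3' endpoint must come back as a multi-candidate ambiguous interval."""
    rng = np.random.default_rng(_sub_seed(seed, 11))
    unique = random_sequence(6400, rng)
    dup_seg = random_sequence(400, rng)
    ref = unique[:2000] + dup_seg + unique[2000:4000] + dup_seg + unique[4000:]
    a, b = 1000, 2200  # deletion ends 200 bp into the first duplicate copy
    hap = ref[:a] + ref[b:]
    rp = ReadSimParams(target_coverage=coverage, base_error_rate=0.001)
    sub = hap[max(0, a - 1200): a + 1200]
    n = pairs_for_coverage(len(sub), coverage, rp.outer_distance)
    pairs = simulate_read_pairs(sub, rp, n, contig="delhap",
                                rng=np.random.default_rng(_sub_seed(seed, 12)))
    mapper = ReadMapper({"ref": ref}, seed=_sub_seed(seed, 13),
                        expected_outer=rp.outer_distance)
    mapped = mapper.map_pairs(pairs)
    clusters = [c for c in cluster_clips(extract_soft_clips(mapped))
                if c.side == "right"]
    return resolve_deletion(clusters[0], ref)
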