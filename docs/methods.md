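# Methods

This note records the models behind `pseudocall`, the defaults and why they
were chosen, what the synthetic data does and does not emulate, and the
numerical conventions. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The locus model

A synthetic master contig carries `exon_count` evenly spaced exons
(default 33 × 150 bp with 100 bp introns and flanks) on a uniform-random
base composition. The *duplicated region* spans a consecutive exon range
(default exons 1–33, i.e. the whole gene body); it is copied
`n_pseudogenes` times (default 6) and each copy is independently mutated
at per-base rate `1 − identity` (default identity 0.977). Divergence
events are substitutions by default (`substitution_indel_ratio = 1.0`),
which keeps master↔copy coordinates identical and every downstream
assertion exact; single-base indel divergence is available but not the
default because pseudogene indel spectra are not characterised well enough
to justify a particular rate. Divergence is placed uniformly; real
segmental duplications show gene-conversion tracts with clustered
identity, which is *not* modelled — see "planted-variant classes" below
for how the consequences of clustering are emulated where they matter.

Pseudogene copies are never given variants: their reads are pure mapping
competition, as in a wild-type pseudogene background.

### Planted-variant classes

Detection behaviour at a site is governed by whether read pairs covering
it carry evidence distinguishing master from copies. Three classes of
heterozygous truth variants are planted:

* **divergent** — positions where, for *every* copy, the gap between the
  flanking divergence sites of that copy is smaller than one fragment
  (200 bp), so every fragment covering the position overlaps discriminating
  divergence, and with the SNV alternative also chosen to differ from every
  copy's base, no allele can make a read prefer a pseudogene. These are the
  positions a pseudogene-aware pipeline must recover essentially
  completely, and the package's sensitivity figure is defined over them
  (default 40 per experiment, 15% small indels).
* **pseudogene_matched** — planted *at* divergence sites with the
  alternative allele equal to the copy's base. A read carrying the variant
  matches that copy perfectly at the site; where the surrounding fragment
  carries little other divergence, such reads are absorbed by the copy and
  the observed fraction collapses. Candidate sites are ranked by local
  isolation (fewest same-copy divergence sites within a fragment length),
  which reproduces at desk scale the real-locus situation where critical
  sites sit in tracts of complete local homology. Default 20 per
  experiment. Because the matched allele neutralises its own divergence
  site on the carrier haplotype, these positions are excluded from the
  divergent-class discriminability computation.
* **background** — uniform planting over coding sequence at mutation rate
  0.02 with a guarantee of at least one variant per 100 bp coding window
  (the validation-simulation convention). Background variants land wherever
  they land; a few fall in weakly discriminable windows and are reported
  through critical-site detection rather than counted against the
  sensitivity bound.

Planted variants keep a ≥12 bp spacing so representations never interact;
indel lengths are 1 + Geometric(p = 0.3), capped at 10.

## Read simulation

2×150 bp pairs with a 200 bp outer distance (mates overlap by 100 bp),
i.i.d. substitution errors at 0.001 per base, constant Q30 qualities,
uniform fragment placement, random R1/R2 strand assignment. Pair counts
follow fragment-based accounting, `ceil(coverage × length / 200)`, with
the master's two haplotypes at half the target coverage each and every
pseudogene contig at full coverage. Heterozygous variants go on haplotype
1 only; homozygous on both. Not modelled: capture/GC bias, duplicate
reads, quality decay, sequencing indel errors.

## Mapping

The internal mapper is a desk-scale instrument for reproducing competitive
mapping, not a production aligner. Candidate loci come from exact 21-mer
seeds at a 25 bp stride; candidates are scored ungapped (match +2,
mismatch −4), and when even the best ungapped placement has ≥5 mismatches
the competitive candidates are re-aligned with affine-gap Smith–Waterman
(gap cost 6 + L), which recovers indels and junction soft clips. Pairs are
placed to maximise the summed score subject to FR orientation and an
insert window around the expected outer distance; a mate with an ambiguous
placement is pulled to its anchor by the summed-score criterion. Mapping
quality is `min(60, 6 × (best − second best))`, zero on ties; tied pair
placements are resolved by a seeded random draw. Random tie-breaking is
deliberate: it reproduces the MAPQ-0 behaviour of production aligners and
makes read exchange between master and copies symmetric, which is what
creates realistic depth (and depressed alt fractions) in locally identical
tracts. Duplicate marking, realignment and base-quality recalibration are
not reproduced; on error-free synthetic data their effect is neutral.

The Smith–Waterman matrix fill runs in a numba-compiled scalar Gotoh
kernel (a vectorised numpy implementation with a running-maximum scan for
the in-row gap dependency is the fallback); the DP is exact, verified
against a brute-force full-matrix oracle on random pairs, and its
tie-breaks are deterministic: smallest target end, then smallest query
end, with diagonal preferred over vertical over horizontal in traceback.

## Pileup and calling

Pileups count filtered reads per position; reads below the
mapping-quality floor are excluded (the floor defaults to 0, i.e. off —
competitive loci lose real variant reads when MAPQ filtering is on, and
the opt-in flag exists to demonstrate exactly that trade-off). Deletions
are counted as an allele at their anchor base and insertions at the
preceding base, both keyed in left-normalised (VCF-style) representation
at build time; the carrying read's anchor-base count is replaced by the
indel allele so allele counts always sum to depth. Positions inside a
deletion get no contribution from deleted reads.

Calling thresholds: alternative fraction ≥0.20 of *total* filtered depth
(not ref+alt) for a standard call, ≥0.85 homozygous, ≥0.08 for
relaxed-candidate calls emitted only by the second step and only inside
the duplicated region. `min_depth` defaults to 20 — the usual coverage
adequacy floor — and shallower sites are reported as uncovered rather
than silently negative. Critical sites are truth positions whose observed
alternative fraction stays under 0.20 or whose called zygosity disagrees;
their exon list is what the CNV ledger consumes. Population-frequency
filtering removes calls with catalogued frequency above 1%; unknown
variants are kept.

## CNV detection

Per-exon mean depths (targets longer than 300 bp are split into ≤300 bp
segments first) are normalised per sample to unit mean and compared as
log2(index/control) per control. Support is the fraction of controls
whose ratio clears the direction's threshold (+0.6 / −0.6): pass at
≥85%, indicated at 50–85%. Adjacent passing exons merge into one event
(so a seven-exon deletion reads out as one call). The filter ledger —
critical regions, artifact regions, low-coverage regions, and
heterozygous-variant evidence inside deletion spans (standard-tier het
calls with fractions in [0.20, 0.80]) — is a set of named reasons, so
filter order cannot matter. The MLPA comparator flags a probe as deleted
when its relative-peak-area ratio falls strictly below 0.75.

The packaged CNV study simulates a 6-control panel at 600× with the index
as one wild-type plus one deletion haplotype at 300× each (breakpoints
mid-intron). 600× is a scaled-down stand-in for the very deep coverage on
which depth-ratio CNV calling is practised on this kind of locus; the
choice is deliberate — at ~100× the per-control ratio noise (σ ≈ 0.14 in
log2) makes the all-controls support requirement unstable, whereas at
600× the margin between the deletion ratio (≈ −0.85 after renormalisation)
and the −0.6 threshold is >3σ per control.

## Breakpoint resolution

Soft clips of ≥10 bases are clustered by boundary and side; consensus is
per-column majority (ties to the first-seen base). The clipped consensus
is placed on the locus by Smith–Waterman with a confidence floor of 90% of
the maximum attainable score; co-optimal placements are reported so
endpoints falling in duplicated sequence surface as ambiguous
multi-candidate intervals. When direct placement fails, the consensus is
decomposed into 20-base windows at step 1 and the extremal confident
windows delimit the endpoint interval; when nothing places, the
coverage-CNV interval is reported.

Aligners systematically extend alignments a few bases past a deletion
junction whenever the 3' side nearly matches the 5' flank (including
homopolymer slippage), shifting the clip boundary and the clip placement
together. Each cluster therefore also carries a consensus of the last 12
*aligned* bases, and the junction is re-derived by exhaustively
re-splitting the combined anchor+clip consensus over small offsets of both
endpoints, keeping the split with the most matching bases (ties to the
leftmost representation). A cluster whose winning split uses no
pre-junction anchor bases cannot constrain the 5' endpoint and is flagged
(`anchored_evidence = False`); the packaged study then falls back to the
next-best cluster. Breakpoint pairs are compared after microhomology
left-normalisation, since representations shifted through identical bases
denote the same deletion.

The breakpoint study plants 0.5–5 kb deletions in 9 kb unique contigs and
simulates 60× reads from a ±1.5 kb window around each junction — the
informative reads are those crossing the junction, so simulating the full
haplotype would only add runtime, not signal.

## Evaluation

The evaluation region is the exon set dilated by 30 bp. Calls match truth
when position and alleles agree after left-normalisation; near misses
(±1 bp, same indel/SNV type) form a separate discordance class and still
count as false positives. Specificity uses a per-site negative universe —
every evaluated reference position with neither truth nor call is a true
negative — because the headline specificity number is otherwise
undefined; the report's raw TP/FP/FN counts support a per-variant reading
as well. Detection rates are printed as percentages rounded half-up to
one decimal.

## Problem sizes and determinism

The full validation experiment (33 exons, six copies, 1000×) simulates
and maps ~286 000 read pairs and runs in about a minute on one CPU; the
CNV and breakpoint studies are sized to a few minutes together. All
randomness in every generator, the mapper's tie-breaks included, derives
from a single integer seed, and two runs with the same configuration are
byte-identical down to the written reports.

## Known limitations

* Uniform divergence understates clustered homology; the matched-variant
  class emulates its detection consequences but not its sequence
  structure (no gene-conversion tracts, no partial pseudogene copies).
* The mapper is not BWA-MEM: MAPQ values, clipping decisions and
  tie-break details differ, so externally mapped data may show slightly
  different critical sites than the internal mapper on the same locus.
* The caller thresholds raw fractions; there is no genotype-likelihood
  model, no strand-bias or base-quality weighting beyond the floors.
* CNV calling is exon-granular with a control panel from the same
  simulated batch; no segmentation model, no purity/ploidy handling.
* Exons are evenly sized and spaced; real loci have heterogeneous exon
  sizes, GC-driven capture dropout (e.g. a GC-rich first exon) and
  capture-escaping repeat regions, none of which are modelled.
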