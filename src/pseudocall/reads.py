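"""Paired-end short-read simulation with fragment-based coverage accounting.

The simulator mirrors the behaviour of classic whole-genome read simulators:
fragments of a fixed outer distance are placed uniformly over a contig, the
two mates read the fragment ends (2 x 150 bp by default, so with a 200 bp
outer distance the mates overlap by 100 bp), per-base substitution errors
are drawn i.i.d., and every read name carries its true origin so that
downstream evaluation can score mapping and calling decisions against
truth.  Sequencing errors are substitutions only and qualities are a
constant Q30.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import PlantingError
from .locus import TruthSet
from .seq import decode, encode, revcomp

Q30 = "?"  # phred 30 in Sanger encoding


@dataclass(frozen=True)
class ReadSimParams:
    """Simulation parameters (defaults follow the validated deep-capture run:
    2 x 150 bp pairs, 200 bp outer distance, base error 0.001, 1000x)."""

    read_length: int = 150
    outer_distance: int = 200
    outer_distance_sd: int = 0
    base_error_rate: float = 0.001
    target_coverage: float = 1000.0
    coverage_accounting: str = "fragment"  # or "sequenced"
    seed: int = 0

    def __post_init__(self):
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.outer_distance < self.read_length:
            raise ValueError("outer_distance must be >= read_length "
                             "(overlapping mates are supported, split mates are not)")
        if not (0.0 <= self.base_error_rate < 1.0):
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.coverage_accounting not in ("fragment", "sequenced"):
            raise ValueError("coverage_accounting must be 'fragment' or 'sequenced'")


@dataclass
class ReadPair:
    """One simulated pair; ``seq1``/``seq2`` are as sequenced (R2 is the
    reverse-complemented far end of the fragment when ``r1_forward``)."""

    name: str
    seq1: str
    seq2: str
    contig: str
    start: int          # fragment start, contig coordinates
    r1_forward: bool    # True: R1 reads the 5' end on the plus strand
    hap: int = 0

    @property
    def qual(self) -> str:
        return Q30 * len(self.seq1)


@dataclass
class Haplotype:
    """A master haplotype with a per-base map back to master coordinates.

    ``to_master[i]`` is the master position of haplotype base ``i``;
    inserted bases map to -1.
    """

    seq: str
    to_master: np.ndarray


def pairs_for_coverage(region_length: int, coverage: float, fragment_length: int) -> int:
    """Number of pairs for a fold coverage under fragment-based accounting:
    ``ceil(coverage * region_length / fragment_length)``."""
    if region_length <= 0 or fragment_length <= 0:
        raise ValueError("region_length and fragment_length must be positive")
    if coverage < 0:
        raise ValueError("coverage must be non-negative")
    return math.ceil(coverage * region_length / fragment_length - 1e-12)


def make_haplotypes(master_sequence: str, truth: TruthSet) -> list[Haplotype]:
    """Apply truth variants to produce two haplotypes.

    Heterozygous variants go on haplotype 1 only; homozygous variants on
    both.  Variants must not overlap.
    """
    variants = sorted(truth, key=lambda v: v.pos)
    for a, b in zip(variants, variants[1:]):
        if a.end > b.pos:
            raise PlantingError(f"overlapping truth variants at {a.pos}/{b.pos}")
    for v in variants:
        if master_sequence[v.pos:v.end] != v.ref:
            raise PlantingError(f"truth ref mismatch at {v.pos}")

    haps = []
    for hap_idx in (0, 1):
        pieces: list[str] = []
        maps: list[np.ndarray] = []
        prev = 0
        for v in variants:
            if v.zygosity == "het" and hap_idx == 0:
                continue
            pieces.append(master_sequence[prev:v.pos])
            maps.append(np.arange(prev, v.pos, dtype=np.int64))
            pieces.append(v.alt)
            alt_map = np.full(len(v.alt), -1, dtype=np.int64)
            alt_map[: min(len(v.alt), len(v.ref))] = np.arange(
                v.pos, v.pos + min(len(v.alt), len(v.ref)), dtype=np.int64)
            maps.append(alt_map)
            prev = v.end
        pieces.append(master_sequence[prev:])
        maps.append(np.arange(prev, len(master_sequence), dtype=np.int64))
        haps.append(Haplotype("".join(pieces), np.concatenate(maps)))
    return haps


def simulate_read_pairs(contig_sequence: str,
                        params: ReadSimParams,
                        n_pairs: int,
                        contig: str = "contig",
                        hap: int = 0,
                        rng: np.random.Generator | None = None) -> list[ReadPair]:
    """Simulate ``n_pairs`` pairs from one contig (vectorised).

    Fragment starts are uniform over the valid range; which physical mate is
    R1 is random, matching real paired-end libraries.
    """
    L = len(contig_sequence)
    rl = params.read_length
    if L < params.outer_distance:
        raise ValueError(f"contig length {L} shorter than outer distance {params.outer_distance}")
    if n_pairs == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(params.seed)

    if params.outer_distance_sd > 0:
        outers = np.rint(rng.normal(params.outer_distance, params.outer_distance_sd,
                                    n_pairs)).astype(np.int64)
        outers = np.clip(outers, rl, L)
    else:
        outers = np.full(n_pairs, params.outer_distance, dtype=np.int64)
    starts = (rng.random(n_pairs) * (L - outers + 1)).astype(np.int64)

    codes = encode(contig_sequence)
    offs = np.arange(rl)
    fwd = codes[starts[:, None] + offs]                       # 5' mate, plus strand
    rev_plus = codes[(starts + outers)[:, None] - rl + offs]  # 3' mate, plus strand

    err_rate = params.base_error_rate
    if err_rate > 0:
        for mat in (fwd, rev_plus):
            mask = rng.random(mat.shape) < err_rate
            shift = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
            mat[mask] = (mat[mask] + shift[mask]) % 4

    swap = rng.integers(0, 2, n_pairs).astype(bool)
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        five = decode(fwd[i])
        three = revcomp(decode(rev_plus[i]))
        if swap[i]:
            seq1, seq2, r1f = three, five, False
        else:
            seq1, seq2, r1f = five, three, True
        name = f"{contig}|{hap}|{starts[i]}|{'F' if r1f else 'R'}|{i}"
        pairs.append(ReadPair(name, seq1, seq2, contig, int(starts[i]), r1f, hap))
    return pairs


def write_fastq(pairs: list[ReadPair], r1_path, r2_path) -> None:
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{Q30 * len(p.seq1)}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{Q30 * len(p.seq2)}\n")
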