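"""Haplotype-aware paired-end read simulation.

Each cell's mutated genome is converted back to DNA: every allele lineage's
region list is substituted with the corresponding bp segments of one of two
haploid references (hap1 for A-derived lineages, hap2 for B-derived; hap2
differs from hap1 at injected SNP sites).  Each lineage sequence is
partitioned into non-overlapping fixed-size windows, a smooth per-window
coverage multiplier is drawn from a stationary AR(1) process on the log
scale (mean multiplier 1), and read pairs are drawn per window *per genome
copy* — so expected depth at a copy-number-c locus is (c/2) x coverage x
the local multiplier, making depth proportional to copy number by
construction.

Reads carry uniform substitution errors and a constant Phred-30 quality
string; read names record the cell, chromosome, lineage, window, pair
index, source haplotype and fragment start, which makes truth tracking
trivial downstream.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .exceptions import ParameterError
from .genome import CellGenome, GenomeTemplate, founding_label

__all__ = [
    "CoverageModel",
    "HaplotypePair",
    "make_haplotypes",
    "write_snp_table",
    "reconstruct_sequence",
    "simulate_window_rates",
    "ReadPair",
    "simulate_read_pairs",
    "generate_reads",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = "ACGT"
PHRED30 = "?"  # chr(33 + 30)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CoverageModel:
    """Sequencing and coverage-landscape parameters.

    coverage
        Mean sequencing depth C (x) per (diploid) cell.
    window_size
        Width W in bp of the non-overlapping read-count windows.
    read_length, insert_mean, insert_sd
        Read length L and Normal fragment-size parameters, bp.
    base_error_rate
        Per-base substitution probability.
    coverage_sd
        Standard deviation sigma_c of the log coverage multiplier.
    autocorr
        AR(1) coefficient rho in [0, 1) controlling window-to-window
        smoothness of the coverage landscape.
    """

    coverage: float = 0.1
    window_size: int = 100_000
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.002
    coverage_sd: float = 0.2
    autocorr: float = 0.5

    def __post_init__(self):
        if self.coverage < 0:
            raise ParameterError("coverage must be >= 0")
        if self.window_size < 1 or self.read_length < 1:
            raise ParameterError("window_size and read_length must be >= 1")
        if self.read_length > self.insert_mean:
            raise ParameterError("read_length must not exceed insert_mean")
        if not 0 <= self.base_error_rate <= 1:
            raise ParameterError("base_error_rate must be in [0, 1]")
        if self.coverage_sd < 0:
            raise ParameterError("coverage_sd must be >= 0")
        if not 0 <= self.autocorr < 1:
            raise ParameterError("autocorr must be in [0, 1)")


@dataclass
class HaplotypePair:
    """Two haploid references per chromosome, differing only at SNP sites.

    ``snps`` lists (chrom, 0-based pos, hap1 base, hap2 base).
    """

    hap1: dict[str, str]
    hap2: dict[str, str]
    snps: list[tuple[str, int, str, str]]
    snp_rate: float


def _load_sequences(reference) -> dict[str, str]:
    if isinstance(reference, dict):
        return dict(reference)
    from pyfaidx import Fasta

    fasta = Fasta(str(reference))
    return {name: str(fasta[name][:]) for name in fasta.keys()}


def make_haplotypes(reference, snp_rate: float, rng: np.random.Generator) -> HaplotypePair:
    """Build hap1 = reference and hap2 with Binomial(length, snp_rate)
    uniformly placed substitutions to a uniformly different base.

    ``reference`` is a FASTA path or a dict of chromosome sequences.
    """
    if not 0 <= snp_rate <= 0.1:
        raise ParameterError("snp_rate must be in [0, 0.1]")
    hap1 = _load_sequences(reference)
    hap2: dict[str, str] = {}
    snps: list[tuple[str, int, str, str]] = []
    for chrom, seq in hap1.items():
        seq = seq.upper()
        hap1[chrom] = seq
        n_sites = rng.binomial(len(seq), snp_rate)
        if n_sites == 0:
            hap2[chrom] = seq
            continue
        sites = np.sort(rng.choice(len(seq), size=n_sites, replace=False))
        mutated = list(seq)
        for pos in sites:
            ref_base = seq[pos]
            choices = [b for b in _BASES if b != ref_base] or list(_BASES)
            alt = choices[rng.integers(0, len(choices))]
            mutated[pos] = alt
            snps.append((chrom, int(pos), ref_base, alt))
        hap2[chrom] = "".join(mutated)
    return HaplotypePair(hap1=hap1, hap2=hap2, snps=snps, snp_rate=snp_rate)


def write_snp_table(haplotypes: HaplotypePair, path) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tpos\thap1_base\thap2_base\n")
        for chrom, pos, b1, b2 in haplotypes.snps:
            handle.write(f"{chrom}\t{pos}\t{b1}\t{b2}\n")


def reconstruct_sequence(
    genome: CellGenome,
    haplotypes: HaplotypePair,
    template: GenomeTemplate,
) -> dict[tuple[str, str], str]:
    """Full DNA sequence of every allele lineage.

    Each region identifier is substituted with its bp segment from hap1 if
    the lineage's founding label is A-derived, else hap2 (lineages created
    by duplication or WGD inherit their source's haplotype through the
    label prefix).
    """
    out: dict[tuple[str, str], str] = {}
    rs = template.region_size
    for chrom, lineages in genome.alleles.items():
        length = template.lengths[chrom]
        for label, regions in lineages.items():
            hap = haplotypes.hap1 if founding_label(label) == "A" else haplotypes.hap2
            source = hap[chrom]
            out[(chrom, label)] = "".join(
                source[r * rs : min((r + 1) * rs, length)] for r in regions
            )
    return out


def simulate_window_rates(
    n_windows: int, model: CoverageModel, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1)-lognormal coverage multipliers with mean 1.

    x_1 ~ N(0, sigma_c^2); x_t = rho x_{t-1} + N(0, sigma_c^2 (1 - rho^2));
    multiplier = exp(x - sigma_c^2 / 2).
    """
    if n_windows < 1:
        raise ParameterError("n_windows must be >= 1")
    sigma, rho = model.coverage_sd, model.autocorr
    if sigma == 0:
        return np.ones(n_windows)
    x = np.empty(n_windows)
    innovations = rng.normal(0.0, 1.0, size=n_windows)
    x[0] = sigma * innovations[0]
    step_sd = sigma * np.sqrt(1.0 - rho * rho)
    for t in range(1, n_windows):
        x[t] = rho * x[t - 1] + step_sd * innovations[t]
    return np.exp(x - sigma * sigma / 2.0)


@dataclass(frozen=True)
class ReadPair:
    """One simulated fragment with its provenance."""

    name: str
    chrom: str
    allele: str
    haplotype: int  # 1 or 2
    window: int
    start: int  # fragment start, lineage-sequence coordinates
    fragment_length: int
    mate1: str
    mate2: str


def _add_errors(read: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return read
    flips = np.flatnonzero(rng.random(len(read)) < rate)
    if len(flips) == 0:
        return read
    bases = list(read)
    for i in flips:
        choices = [b for b in _BASES if b != bases[i]] or list(_BASES)
        bases[i] = choices[rng.integers(0, len(choices))]
    return "".join(bases)


def simulate_read_pairs(
    sequences: dict[tuple[str, str], str],
    model: CoverageModel,
    rng: np.random.Generator,
    cell: str = "cell",
) -> Iterator[ReadPair]:
    """Yield read pairs over every allele lineage of one cell.

    Each lineage sequence is split into windows of ``window_size``; the
    expected pair count in a window of W_eff bp on one haploid copy is
    (C/2) * W_eff * rate / (2L), realized as a Poisson draw, so depth is
    proportional to local copy number.  Fragment starts are uniform in the
    window; fragment lengths are Normal(insert_mean, insert_sd) clipped to
    at least L and to the sequence end.
    """
    L = model.read_length
    warned_short = False
    for (chrom, allele), seq in sorted(sequences.items()):
        if len(seq) < L or model.coverage == 0:
            continue
        hap = 1 if founding_label(allele) == "A" else 2
        n_windows = -(-len(seq) // model.window_size)
        rates = simulate_window_rates(n_windows, model, rng)
        for wi in range(n_windows):
            w_start = wi * model.window_size
            w_len = min(model.window_size, len(seq) - w_start)
            mean_pairs = model.coverage / 2.0 * w_len * rates[wi] / (2.0 * L)
            n_pairs = int(rng.poisson(mean_pairs))
            for pi in range(n_pairs):
                frag_len = int(round(rng.normal(model.insert_mean, model.insert_sd)))
                frag_len = max(frag_len, L)
                if frag_len > len(seq):
                    if not warned_short:
                        logger.warning(
                            "sequence shorter than insert size; fragments clipped"
                        )
                        warned_short = True
                    frag_len = len(seq)
                start = int(rng.integers(w_start, w_start + w_len))
                start = min(start, len(seq) - frag_len)
                frag = seq[start : start + frag_len]
                mate1 = _add_errors(frag[:L], model.base_error_rate, rng)
                mate2 = _add_errors(
                    reverse_complement(frag[-L:]), model.base_error_rate, rng
                )
                name = f"{cell}_{chrom}_{allele}_w{wi}_p{pi}_hap{hap}_s{start}"
                yield ReadPair(name, chrom, allele, hap, wi, start, frag_len,
                               mate1, mate2)


def _gzip_text_writer(path):
    # mtime pinned and filename suppressed so identical content gives
    # identical bytes regardless of when/where the file is written
    raw = open(path, "wb")
    return io.TextIOWrapper(
        gzip.GzipFile(filename="", fileobj=raw, mode="wb", mtime=0),
        encoding="ascii",
    )


def generate_reads(
    sequences: dict[tuple[str, str], str],
    model: CoverageModel,
    rng: np.random.Generator,
    out_r1,
    out_r2,
    cell: str = "cell",
) -> int:
    """Write gzip FASTQ mates for one cell; returns the pair count."""
    qual = PHRED30 * model.read_length
    count = 0
    with _gzip_text_writer(out_r1) as r1, _gzip_text_writer(out_r2) as r2:
        for pair in simulate_read_pairs(sequences, model, rng, cell=cell):
            r1.write(f"@{pair.name}/1\n{pair.mate1}\n+\n{qual[: len(pair.mate1)]}\n")
            r2.write(f"@{pair.name}/2\n{pair.mate2}\n+\n{qual[: len(pair.mate2)]}\n")
            count += 1
    return count


def write_window_counts(
    sequences: dict[tuple[str, str], str],
    model: CoverageModel,
    rng: np.random.Generator,
    path,
    cell: str = "cell",
) -> None:
    """Export per-window expected pair counts (extension point for driving
    an external read simulator instead of the built-in one)."""
    L = model.read_length
    with open(path, "w") as handle:
        handle.write("cell\tchrom\tallele\twindow\tstart\tend\texpected_pairs\n")
        for (chrom, allele), seq in sorted(sequences.items()):
            n_windows = -(-len(seq) // model.window_size)
            rates = simulate_window_rates(n_windows, model, rng)
            for wi in range(n_windows):
                w_start = wi * model.window_size
                w_len = min(model.window_size, len(seq) - w_start)
                mean_pairs = model.coverage / 2.0 * w_len * rates[wi] / (2.0 * L)
                handle.write(
                    f"{cell}\t{chrom}\t{allele}\t{wi}\t{w_start}\t{w_start + w_len}"
                    f"\t{mean_pairs:.6f}\n"
                )
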