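"""Discretized genome coordinate system and diploid cell genomes.

The simulator operates on a simplified genome: each chromosome is an ordered
set of uniform-sized *regions* (the unit of the event model).  Copy-number
profiles are reported over coarser *bins* (an integer multiple of the region
size) and read counts are drawn over *windows* (see :mod:`sccnsim.reads`).
All coordinates are 0-based, half-open.

A cell genome is, per chromosome, a collection of *allele lineages*.  Each
lineage has a label recording its ancestry ("A", "B", "A.wgd", "B.dup1", ...)
and an ordered list of reference region indices.  Duplicated chromosomes
(whole-chromosome gains, WGD) become new lineages; the founding letter of a
label ("A" or "B") decides which haplotype its sequence is drawn from.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError

__all__ = [
    "GenomeTemplate",
    "CellGenome",
    "build_template",
    "generate_synthetic_reference",
    "init_diploid_genome",
    "read_arm_table",
    "write_arm_table",
    "convert_ucsc_cytoband",
    "founding_label",
]


def founding_label(label: str) -> str:
    """Founding allele letter ("A" or "B") of a lineage label."""
    head = label.split(".", 1)[0]
    if head not in ("A", "B"):
        raise ValueError(f"allele label {label!r} does not derive from A or B")
    return head


@dataclass(frozen=True)
class GenomeTemplate:
    """Shared coordinate system: chromosomes, arm boundaries, region/bin sizes.

    Parameters
    ----------
    chromosomes
        Ordered chromosome names.
    lengths
        Chromosome length in bp.
    arm_boundaries
        0-based bp coordinate of the first q-arm base per chromosome.
    region_size
        Size in bp of the uniform regions the event model acts on.
    bin_size
        Size in bp of the copy-number-profile bins; must be a positive
        integer multiple of ``region_size``.
    """

    chromosomes: tuple[str, ...]
    lengths: dict[str, int] = field(hash=False)
    arm_boundaries: dict[str, int] = field(hash=False)
    region_size: int = 1_000
    bin_size: int = 1_000_000

    def __post_init__(self):
        if self.region_size <= 0 or self.bin_size <= 0:
            raise ParameterError("region_size and bin_size must be positive")
        if self.bin_size % self.region_size != 0:
            raise ParameterError(
                f"bin_size ({self.bin_size}) must be an integer multiple of "
                f"region_size ({self.region_size})"
            )
        for chrom in self.chromosomes:
            length = self.lengths[chrom]
            if length <= 0:
                raise ParameterError(f"{chrom}: length must be positive")
            boundary = self.arm_boundaries[chrom]
            if not 0 < boundary < length:
                raise ParameterError(
                    f"{chrom}: arm boundary {boundary} outside (0, {length})"
                )

    def n_regions(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.region_size)

    def n_bins(self, chrom: str) -> int:
        return -(-self.lengths[chrom] // self.bin_size)

    def region_lengths(self, chrom: str) -> np.ndarray:
        """bp length of every region; only the last may be short."""
        length = self.lengths[chrom]
        n = self.n_regions(chrom)
        out = np.full(n, self.region_size, dtype=np.int64)
        out[-1] = length - (n - 1) * self.region_size
        return out

    def arm_boundary_region(self, chrom: str) -> int:
        """First region index of the q arm (regions spanning the boundary
        stay on the p arm)."""
        return -(-self.arm_boundaries[chrom] // self.region_size)

    def arm_region_range(self, chrom: str, arm: str) -> tuple[int, int]:
        """Half-open region-index range of an arm ('p', 'q' or 'whole')."""
        boundary = self.arm_boundary_region(chrom)
        n = self.n_regions(chrom)
        if arm == "p":
            return (0, boundary)
        if arm == "q":
            return (boundary, n)
        if arm == "whole":
            return (0, n)
        raise ParameterError(f"unknown arm {arm!r}")

    def bins(self) -> list[tuple[str, int, int]]:
        """(chrom, start bp, end bp) for every profile bin, in order."""
        out = []
        for chrom in self.chromosomes:
            length = self.lengths[chrom]
            for start in range(0, length, self.bin_size):
                out.append((chrom, start, min(start + self.bin_size, length)))
        return out


class CellGenome:
    """Mutable per-cell genome: allele lineages of reference-region lists.

    ``alleles[chrom]`` maps lineage label -> list of region indices, in the
    physical order they appear on that (mutated) chromosome copy.
    """

    __slots__ = ("alleles",)

    def __init__(self, alleles: dict[str, dict[str, list[int]]]):
        self.alleles = alleles

    def copy(self) -> "CellGenome":
        return CellGenome(
            {
                chrom: {label: list(seq) for label, seq in lineages.items()}
                for chrom, lineages in self.alleles.items()
            }
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, CellGenome):
            return NotImplemented
        return self.alleles == other.alleles

    def total_copy_number(self, template: GenomeTemplate, chrom: str) -> np.ndarray:
        """Per-region total copy number: occurrences across all lineages."""
        n = template.n_regions(chrom)
        counts = np.zeros(n, dtype=np.int64)
        for seq in self.alleles[chrom].values():
            if seq:
                counts += np.bincount(np.asarray(seq, dtype=np.int64), minlength=n)
        return counts

    def allele_copy_number(
        self, template: GenomeTemplate, chrom: str
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-region copy number split by founding allele (A-derived, B-derived)."""
        n = template.n_regions(chrom)
        out = {"A": np.zeros(n, dtype=np.int64), "B": np.zeros(n, dtype=np.int64)}
        for label, seq in self.alleles[chrom].items():
            if seq:
                out[founding_label(label)] += np.bincount(
                    np.asarray(seq, dtype=np.int64), minlength=n
                )
        return out["A"], out["B"]


def init_diploid_genome(template: GenomeTemplate) -> CellGenome:
    """Healthy diploid genome: lineages A and B carry every region once, in order."""
    return CellGenome(
        {
            chrom: {
                "A": list(range(template.n_regions(chrom))),
                "B": list(range(template.n_regions(chrom))),
            }
            for chrom in template.chromosomes
        }
    )


# ---------------------------------------------------------------------------
# Arm table I/O.  Minimal cytoband digest: chrom, length, centromere_start.
# ---------------------------------------------------------------------------

_ARM_HEADER = ("chrom", "length", "centromere_start")


def read_arm_table(path) -> list[tuple[str, int, int]]:
    rows = []
    with open(path) as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if i == 0 and parts[0] == "chrom":
                continue
            if len(parts) != 3:
                raise ParameterError(f"{path}: expected 3 columns, got {len(parts)}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    return rows


def write_arm_table(rows, path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_ARM_HEADER) + "\n")
        for chrom, length, centromere in rows:
            handle.write(f"{chrom}\t{length}\t{centromere}\n")


def convert_ucsc_cytoband(cytoband_path, out_path) -> None:
    """Digest a UCSC cytoBand.txt file into the minimal arm table.

    Chromosome length is the maximum band end; the centromere position is
    the start of the first 'acen' band.
    """
    lengths: dict[str, int] = {}
    centromeres: dict[str, int] = {}
    order: list[str] = []
    with open(cytoband_path) as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 5:
                continue
            chrom, start, end, _band, stain = parts[:5]
            if chrom not in lengths:
                lengths[chrom] = 0
                order.append(chrom)
            lengths[chrom] = max(lengths[chrom], int(end))
            if stain == "acen" and chrom not in centromeres:
                centromeres[chrom] = int(start)
    missing = [c for c in order if c not in centromeres]
    if missing:
        raise ParameterError(f"no acen band for chromosome(s): {', '.join(missing)}")
    write_arm_table([(c, lengths[c], centromeres[c]) for c in order], out_path)


def _fasta_lengths(path) -> list[tuple[str, int]]:
    """Record names and sequence lengths from a FASTA file, in file order."""
    from pyfaidx import Fasta

    fasta = Fasta(str(path), build_index=True, rebuild=False)
    return [(name, len(fasta[name])) for name in fasta.keys()]


def build_template(
    reference=None,
    arm_table=None,
    region_size: int = 1_000,
    bin_size: int = 1_000_000,
) -> GenomeTemplate:
    """Build the shared coordinate system.

    With a FASTA ``reference``, chromosome names/lengths come from the FASTA
    (order preserved) and every record must appear in ``arm_table``.  Without
    a FASTA (copy-number-profile-only mode) names, lengths and order come
    from the arm table alone.
    """
    if arm_table is None:
        raise ParameterError("an arm table is required to build a template")
    rows = read_arm_table(arm_table)
    table = {chrom: (length, cen) for chrom, length, cen in rows}
    if reference is not None:
        records = _fasta_lengths(reference)
        missing = [name for name, _ in records if name not in table]
        if missing:
            raise ParameterError(
                "chromosome(s) in FASTA missing from arm table: " + ", ".join(missing)
            )
        chromosomes = tuple(name for name, _ in records)
        lengths = {name: length for name, length in records}
    else:
        chromosomes = tuple(chrom for chrom, _, _ in rows)
        lengths = {chrom: table[chrom][0] for chrom in chromosomes}
    boundaries = {chrom: table[chrom][1] for chrom in chromosomes}
    return GenomeTemplate(
        chromosomes=chromosomes,
        lengths=lengths,
        arm_boundaries=boundaries,
        region_size=region_size,
        bin_size=bin_size,
    )


def generate_synthetic_reference(
    out_dir,
    n_chromosomes: int = 2,
    chrom_length: int = 1_000_000,
    arm_fraction: float = 0.4,
    gc: float = 0.41,
    seed: int = 0,
    line_width: int = 80,
) -> tuple[str, str]:
    """Write an i.i.d.-base synthetic FASTA and matching arm table.

    Bases are drawn independently with P(G) = P(C) = gc/2 and
    P(A) = P(T) = (1 - gc)/2, so the realized GC fraction matches ``gc`` in
    expectation.  The arm boundary sits at ``round(arm_fraction * length)``.
    Deterministic under ``seed``.  Returns (fasta_path, arm_table_path).
    """
    if n_chromosomes < 1:
        raise ParameterError("n_chromosomes must be >= 1")
    if not 0 < arm_fraction < 1:
        raise ParameterError("arm_fraction must be in (0, 1)")
    if not 0 <= gc <= 1:
        raise ParameterError("gc must be in [0, 1]")
    if chrom_length < 2:
        raise ParameterError("chrom_length must be >= 2")
    rng = np.random.default_rng(seed)
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "reference.fa")
    arm_path = os.path.join(out_dir, "arms.tsv")
    bases = np.frombuffer(b"ACGT", dtype="S1")
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rows = []
    with open(fasta_path, "w") as handle:
        for i in range(n_chromosomes):
            chrom = f"chr{i + 1}"
            handle.write(f">{chrom}\n")
            draws = rng.choice(bases, size=chrom_length, p=probs)
            seq = draws.tobytes().decode("ascii")
            for start in range(0, chrom_length, line_width):
                handle.write(seq[start : start + line_width] + "\n")
            boundary = int(round(arm_fraction * chrom_length))
            boundary = min(max(boundary, 1), chrom_length - 1)
            rows.append((chrom, chrom_length, boundary))
    write_arm_table(rows, arm_path)
    return fasta_path, arm_path
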