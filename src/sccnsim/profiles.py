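"""Binned copy-number profiles and the caller-error model.

Ground-truth profiles are computed from each cell's allele lineages: the
total copy number of a reference region is simply the number of occurrences
of its identifier across all lineages; bin values are length-weighted means
over the bin's regions, rounded half away from zero to an integer.

Two error mechanisms mimic the output of CNA callers on noisy low-coverage
single-cell data:

* *boundary noise* — segmentation breakpoints between adjacent bins with
  differing copy number are displaced by a geometric number of bins in a
  random direction, reflecting the observation that errors concentrate at
  segment boundaries;
* *jitter* — zero-mean Gaussian fluctuation with standard deviation
  proportional to the true copy-number state, reflecting read-count
  nonuniformity; values are re-rounded and floored at zero.

Boundary noise is applied first (segmentation error on the latent signal),
jitter second (read-count noise on top).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .genome import CellGenome, GenomeTemplate

__all__ = [
    "ErrorModelParams",
    "CopyNumberProfile",
    "compute_ground_truth_cnp",
    "build_profiles",
    "add_boundary_noise",
    "add_jitter",
    "add_noise",
    "write_profiles",
    "read_profiles",
    "write_segments",
]


@dataclass(frozen=True)
class ErrorModelParams:
    """Parameters of the copy-number error model.

    boundary_prob
        Probability p_b that a segment boundary is perturbed.
    boundary_geom_p
        Geometric parameter p_s of the displacement size (support 1, 2, ...;
        mean displacement 1/p_s); expected displaced bins per boundary is
        therefore p_b / p_s.
    jitter_sd
        Standard deviation of the Gaussian fluctuation per unit copy
        (a CN-c bin receives noise with s.d. jitter_sd * c).
    """

    boundary_prob: float = 0.5
    boundary_geom_p: float = 0.5
    jitter_sd: float = 0.15

    def __post_init__(self):
        if not 0 <= self.boundary_prob <= 1:
            raise ParameterError("boundary_prob must be in [0, 1]")
        if not 0 < self.boundary_geom_p <= 1:
            raise ParameterError("boundary_geom_p must be in (0, 1]")
        if self.jitter_sd < 0:
            raise ParameterError("jitter_sd must be >= 0")


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


class CopyNumberProfile:
    """Cells x bins integer copy-number matrix (total plus allele split).

    ``bins`` is a list of (chrom, start bp, end bp); ``total`` has shape
    (n_cells, n_bins); ``allele_a``/``allele_b`` partition the total by
    founding allele and may be None for profiles without an allele split.
    """

    def __init__(self, cells, bins, total, allele_a=None, allele_b=None):
        self.cells = list(cells)
        self.bins = list(bins)
        self.total = np.asarray(total, dtype=np.int64)
        self.allele_a = None if allele_a is None else np.asarray(allele_a, dtype=np.int64)
        self.allele_b = None if allele_b is None else np.asarray(allele_b, dtype=np.int64)
        if self.total.shape != (len(self.cells), len(self.bins)):
            raise ParameterError("profile matrix shape does not match cells x bins")

    def copy(self) -> "CopyNumberProfile":
        return CopyNumberProfile(
            self.cells,
            self.bins,
            self.total.copy(),
            None if self.allele_a is None else self.allele_a.copy(),
            None if self.allele_b is None else self.allele_b.copy(),
        )

    def __eq__(self, other):
        if not isinstance(other, CopyNumberProfile):
            return NotImplemented
        same_alleles = (
            (self.allele_a is None) == (other.allele_a is None)
            and (self.allele_a is None or np.array_equal(self.allele_a, other.allele_a))
            and (self.allele_b is None or np.array_equal(self.allele_b, other.allele_b))
        )
        return (
            self.cells == other.cells
            and self.bins == other.bins
            and np.array_equal(self.total, other.total)
            and same_alleles
        )

    def chrom_slices(self) -> list[tuple[str, slice]]:
        out, start = [], 0
        for i, (chrom, _, _) in enumerate(self.bins):
            if i + 1 == len(self.bins) or self.bins[i + 1][0] != chrom:
                out.append((chrom, slice(start, i + 1)))
                start = i + 1
        return out


def _bin_region_cn(values: np.ndarray, template: GenomeTemplate, chrom: str) -> np.ndarray:
    """Length-weighted mean of per-region values over each bin, rounded
    half away from zero."""
    weights = template.region_lengths(chrom).astype(float)
    per_bin = template.bin_size // template.region_size
    starts = np.arange(0, len(values), per_bin)
    num = np.add.reduceat(values * weights, starts)
    den = np.add.reduceat(weights, starts)
    return _round_half_away(num / den).astype(np.int64)


def compute_ground_truth_cnp(
    genome: CellGenome, template: GenomeTemplate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin (total, A-derived, B-derived) copy number for one cell."""
    totals, a_parts, b_parts = [], [], []
    for chrom in template.chromosomes:
        cn_a, cn_b = genome.allele_copy_number(template, chrom)
        totals.append(_bin_region_cn(cn_a + cn_b, template, chrom))
        a_parts.append(_bin_region_cn(cn_a, template, chrom))
        b_parts.append(_bin_region_cn(cn_b, template, chrom))
    return np.concatenate(totals), np.concatenate(a_parts), np.concatenate(b_parts)


def build_profiles(
    genomes: dict[int, CellGenome],
    cell_names: dict[int, str],
    template: GenomeTemplate,
) -> CopyNumberProfile:
    """Ground-truth profile matrix for the named cells (sorted by name)."""
    order = sorted(cell_names, key=lambda nid: cell_names[nid])
    n_bins = len(template.bins())
    if not order:
        empty = np.zeros((0, n_bins), dtype=np.int64)
        return CopyNumberProfile([], template.bins(), empty, empty.copy(), empty.copy())
    totals, a_all, b_all = [], [], []
    for nid in order:
        t, a, b = compute_ground_truth_cnp(genomes[nid], template)
        totals.append(t)
        a_all.append(a)
        b_all.append(b)
    return CopyNumberProfile(
        [cell_names[nid] for nid in order],
        template.bins(),
        np.vstack(totals),
        np.vstack(a_all),
        np.vstack(b_all),
    )


# ---------------------------------------------------------------------------
# Error model
# ---------------------------------------------------------------------------

def _perturb_boundaries(values: np.ndarray, params: ErrorModelParams,
                        rng: np.random.Generator) -> np.ndarray:
    """Boundary noise on one cell x one chromosome, against the original."""
    out = values.copy()
    n = len(values)
    boundaries = np.flatnonzero(values[:-1] != values[1:])
    for bi, i in enumerate(boundaries):
        if rng.random() >= params.boundary_prob:
            continue
        shift = int(rng.geometric(params.boundary_geom_p))
        go_right = rng.random() < 0.5
        if go_right:
            # right segment spans (i, j]; keep its last bin so every
            # original CN state survives on the chromosome
            j = boundaries[bi + 1] if bi + 1 < len(boundaries) else n - 1
            shift = min(shift, (j - i) - 1)
            if shift > 0:
                out[i + 1 : i + 1 + shift] = values[i]
        else:
            p = boundaries[bi - 1] if bi > 0 else -1
            shift = min(shift, (i - p) - 1)
            if shift > 0:
                out[i - shift + 1 : i + 1] = values[i + 1]
    return out


def add_boundary_noise(
    profile: CopyNumberProfile,
    params: ErrorModelParams,
    rng: np.random.Generator,
) -> CopyNumberProfile:
    """Displace copy-number segment boundaries.

    For each within-chromosome boundary between bins of differing total CN,
    with probability ``boundary_prob`` the boundary moves by
    Geometric(boundary_geom_p) bins in a uniformly random direction; the
    displaced bins adopt the CN of the segment the boundary moved away
    from.  Boundaries are processed left to right against the *original*
    profile, and displacement is clipped so the receding segment keeps at
    least one bin.  The allele split is rescaled to the perturbed totals.
    """
    noisy = profile.copy()
    for ci in range(len(profile.cells)):
        for _, sl in profile.chrom_slices():
            noisy.total[ci, sl] = _perturb_boundaries(profile.total[ci, sl], params, rng)
    _rescale_allele_split(noisy, profile)
    return noisy


def add_jitter(
    profile: CopyNumberProfile,
    params: ErrorModelParams,
    rng: np.random.Generator,
) -> CopyNumberProfile:
    """State-proportional Gaussian fluctuation per bin per cell.

    A bin with value c becomes max(0, round(c + eps)) with
    eps ~ Normal(0, (jitter_sd * c)^2); zero bins remain zero.
    """
    noisy = profile.copy()
    c = profile.total.astype(float)
    eps = rng.normal(0.0, 1.0, size=c.shape) * params.jitter_sd * c
    noisy.total = np.maximum(_round_half_away(c + eps), 0).astype(np.int64)
    _rescale_allele_split(noisy, profile)
    return noisy


def add_noise(
    profile: CopyNumberProfile,
    params: ErrorModelParams,
    rng: np.random.Generator,
) -> CopyNumberProfile:
    """Full error model: boundary noise, then jitter."""
    return add_jitter(add_boundary_noise(profile, params, rng), params, rng)


def _rescale_allele_split(noisy: CopyNumberProfile, truth: CopyNumberProfile) -> None:
    """Rescale the truth allele split proportionally to the noisy totals.

    Callers rarely report reliable allele-specific CN under this noise
    level, so the noisy allele columns are a proportional re-split of the
    noisy total (rounded; B takes the remainder).  Bins with true total 0
    split evenly.
    """
    if truth.allele_a is None:
        return
    t_true = truth.total.astype(float)
    t_noisy = noisy.total.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_a = np.where(t_true > 0, truth.allele_a / t_true, 0.5)
    a = np.minimum(_round_half_away(frac_a * t_noisy), t_noisy).astype(np.int64)
    noisy.allele_a = a
    noisy.allele_b = noisy.total - a


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _long_frame(profile: CopyNumberProfile) -> pd.DataFrame:
    n_cells, n_bins = profile.total.shape
    chroms = [b[0] for b in profile.bins]
    starts = [b[1] for b in profile.bins]
    ends = [b[2] for b in profile.bins]
    has_alleles = profile.allele_a is not None
    frame = pd.DataFrame(
        {
            "cell_id": np.repeat(profile.cells, n_bins),
            "chrom": np.tile(chroms, n_cells),
            "start": np.tile(starts, n_cells),
            "end": np.tile(ends, n_cells),
            "cn_total": profile.total.ravel(),
            "cn_a": profile.allele_a.ravel() if has_alleles else pd.NA,
            "cn_b": profile.allele_b.ravel() if has_alleles else pd.NA,
        }
    )
    return frame


def write_profiles(profile: CopyNumberProfile, long_path, matrix_path=None) -> None:
    """Write the long-format TSV and, optionally, the wide bins x cells matrix."""
    _long_frame(profile).to_csv(long_path, sep="\t", index=False)
    if matrix_path is not None:
        index = [f"{c}:{s}-{e}" for c, s, e in profile.bins]
        wide = pd.DataFrame(profile.total.T, index=index, columns=profile.cells)
        wide.to_csv(matrix_path, sep="\t", index_label="bin")


def read_profiles(long_path) -> CopyNumberProfile:
    """Inverse of :func:`write_profiles` (long format)."""
    frame = pd.read_csv(long_path, sep="\t")
    if frame.empty:
        return CopyNumberProfile([], [], np.zeros((0, 0), dtype=np.int64))
    cells = list(dict.fromkeys(frame["cell_id"]))
    first = frame[frame["cell_id"] == cells[0]]
    bins = list(zip(first["chrom"], first["start"], first["end"]))
    n_bins = len(bins)
    total = frame["cn_total"].to_numpy().reshape(len(cells), n_bins)
    has_alleles = not frame["cn_a"].isna().all()
    a = frame["cn_a"].to_numpy().reshape(len(cells), n_bins) if has_alleles else None
    b = frame["cn_b"].to_numpy().reshape(len(cells), n_bins) if has_alleles else None
    return CopyNumberProfile(cells, bins, total, a, b)


def write_segments(profile: CopyNumberProfile, path) -> None:
    """BED-style per-segment file: equal adjacent bins merged per cell."""
    with open(path, "w") as handle:
        handle.write("cell_id\tchrom\tstart\tend\tcn_total\n")
        for ci, cell in enumerate(profile.cells):
            for chrom, sl in profile.chrom_slices():
                values = profile.total[ci, sl]
                bins = profile.bins[sl]
                seg_start, seg_val = bins[0][1], values[0]
                for i in range(1, len(values) + 1):
                    if i == len(values) or values[i] != seg_val:
                        handle.write(
                            f"{cell}\t{chrom}\t{seg_start}\t{bins[i - 1][2]}\t{seg_val}\n"
                        )
                        if i < len(values):
                            seg_start, seg_val = bins[i][1], values[i]
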