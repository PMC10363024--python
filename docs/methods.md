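# Methods

This note documents the models implemented in `sccnsim`, the defaults and
why they were chosen, the numerical conventions, and what the verification
suite does and does not demonstrate.

## Lineage model

The tumor sample of *n* cells is treated as a draw from a much larger
exponentially growing population, so its genealogy follows the neutral
coalescent. Time is measured in coalescent units (population-size-scaled);
branch lengths are converted to expected event counts through per-unit
event rates, so no calendar-time calibration is needed. The coalescent
itself is delegated to `msprime` (haploid model, relative size 1), which
gives the standard pairwise rate k(k−1)/2 at growth rate α = 0 and
N(t) = e^(−αt) backward in time for α > 0.

**Sweeps.** A selective sweep is modeled as an instantaneous bottleneck:
at the sweep time the backward-time population size is multiplied by a
severity s ∈ (0, 1], raising the coalescence rate by 1/s from that time on
and concentrating coalescences just after it. This is the simplest
mechanism that produces sweep-like bursts; a full logistic sweep trajectory
is out of scope. A sweep older than the sample's TMRCA has no effect and is
silently inert.

**Outgroups.** Normal and pseudo-normal cells attach along a stem of
configurable length (default 1.0 coalescent unit) added above the tumor
MRCA, at evenly spaced points — deterministic spacing keeps runs
reproducible and is easy to reason about; uniform random spacing is
available as an option. Normals sit closest to the new root and
pseudo-normals between them and the founder, which orders divergence times
the way the biology suggests (pseudo-normals are closer to, but still
outside, the tumor).

**Subclones.** k disjoint clades with at least `min_size` tumor leaves are
selected greedy-randomly (shuffle candidates, accept while leaf-disjoint,
retry on failure). Feasibility is decided first by bottom-up dynamic
programming over the founder subtree, so an infeasible request fails fast
with the achievable maximum. The founder itself is not a candidate: a
subclone is a *proper* subpopulation.

## Genome representation and event model

Chromosomes are discretized into fixed-size regions (default 1,000 bp), the
unit of the event model; profile bins (default 1,000,000 bp) must be an
integer multiple of the region size. These defaults keep human-scale runs
in memory and match the resolution common among CNA callers. The last
region of a chromosome may be short; it participates in events like any
other region, and its true bp length is honored in bin averaging and
sequence reconstruction.

A cell genome is, per chromosome, a set of allele lineages — label plus
ordered region list. Whole-chromosome duplications and WGD create new
lineages (labels `A.dup1`, `A.wgd`, ...); the founding letter of a label
decides the haplotype used when rebuilding DNA. Repeated WGDs disambiguate
labels (`A.wgd`, `A.wgd2`) so labels stay unique within a chromosome.

**Focal events.** Counts per edge are Poisson(λ_f × branch length); a
fixed-count-per-edge switch exists for controlled experiments. The acting
allele is chosen proportionally to its current region count, making the
per-bp event rate uniform over the current genome. Lengths are
`min_length` plus a geometric excess matched to the configured mean
(geometric lengths discretized to regions mirror the exponential length
laws of comparable simulators), truncated to fit the allele. Gains carry a
geometric magnitude with mean 1/p_mag and insert tandem copies after the
template segment. Events drawn on an edge are applied sequentially in draw
order, so later coordinates refer to the already-mutated sequence — this
makes interval semantics under prior insertions/deletions well defined and
makes the event log replayable.

**CNLOH.** Copy-neutral LOH is restricted to focal scale. Because each
lineage carries a single haplotype, CNLOH is realized as a paired
loss-and-duplication: the segment is deleted from the target lineage and
each lost copy is duplicated beside the homologous (donor) lineage's own
occurrence of the same region. Total copy number is conserved exactly at
every region while the allele split moves — which is the defining
observable of CNLOH. The donor is the lexicographically smallest other
lineage carrying the whole segment, a deterministic rule that keeps log
replay exact; when no donor exists the draw falls back to a gain/loss.

**Chromosomal events and WGD.** The edge into the founder receives the
optional WGD first, then Poisson(μ_founder) chromosomal events (arm with
probability p_arm, else whole-chromosome; gain with probability p_cgain;
chromosome uniform; acting allele uniform among carriers), then its focal
events. Each subclone-root edge receives 1 + Poisson(μ_sc) chromosomal
events, redrawn (up to 100 attempts) until the (chromosome, arm, type)
multiset differs from every other subclone's, so each subclone has a unique
chromosomal signature. Events that find no carrier (e.g. a loss on a
nullisomic chromosome) are skipped with a logged warning rather than
failing the run.

Edges on the stem above the founder carry no events, so normal leaves are
bit-identical to the initialized diploid; pseudo-normal leaves draw
Poisson(μ_pn) focal events on their pendant edge only.

**Replayability.** The event log records every applied event with its
resolved stochastic choices; the two remaining rules (CNLOH donor,
duplicate-label generation) are deterministic functions of genome state,
so replaying the log from a fresh diploid reproduces every genome exactly.
This is verified over randomized configurations in the test suite.

## Profiles and the error model

Ground truth: the total copy number of a region is the count of its
identifier across lineages; bins take the length-weighted mean of their
regions' values, rounded half away from zero (fixed rule, reproducible
across platforms). Allele-specific values split the count by founding
haplotype and are rounded the same way.

Noise is applied boundary-first, jitter-second: boundary displacement
models segmentation error on the latent signal, jitter models read-count
noise on top.

- **Boundary noise.** Each within-chromosome boundary between bins of
  differing total CN is, with probability p_b, displaced by
  Geometric(p_s) bins (support 1, 2, ...) in a uniform random direction;
  displaced bins adopt the value of the segment the boundary moved away
  from. Boundaries are processed left to right against the original
  profile, and the displacement is clipped so the receding segment keeps
  at least one bin — hence boundary noise never removes a copy-number
  state from a chromosome. Expected displaced bins per boundary is
  p_b / p_s.
- **Jitter.** A bin at state c becomes max(0, round(c + ε)) with
  ε ~ Normal(0, (σ_j · c)²); the proportionality to state reflects
  read-count nonuniformity, and zero bins stay zero. Gaussian is a
  modeling choice; only the proportionality is essential.
- **Allele split under noise.** Callers rarely report reliable
  allele-specific CN at this noise level, so noisy allele columns are a
  proportional re-split of the noisy total (B takes the remainder; bins
  with true total 0 split evenly).

With all error parameters zero the noisy outputs are byte-identical to the
truth.

## Read simulation

Read generation is implemented internally (uniform substitution errors,
constant Phred-30 qualities) so the package is self-contained and
bit-reproducible end to end; `write_window_counts` exports per-window
expected pair counts as an extension point for driving any external
short-read simulator instead.

Two haploid references are built per run: hap1 is the reference, hap2
substitutes Binomial(L, θ) uniformly placed sites (default θ = 0.001,
around the human heterozygosity scale); each allele lineage is rebuilt from
the haplotype of its founding label. Lineage sequences are split into
windows (default 100 kb); log coverage multipliers follow a stationary
AR(1) process — x₁ ~ N(0, σ_c²), x_t = ρ x_{t−1} + N(0, σ_c²(1−ρ²)),
multiplier e^(x − σ_c²/2) so the mean multiplier is exactly 1 — giving one
smoothness knob (ρ) and one dispersion knob (σ_c). Expected pairs per
window per haploid copy are (C/2) · W_eff / (2L) times the local
multiplier, realized as Poisson draws per copy, so depth tracks copy
number by construction. Fragments start uniformly in the window with
Normal(insert_mean, insert_sd) lengths clipped to at least L and to the
sequence end; mate 2 is the reverse complement of the fragment's 3′ end.
Paired-end only. Gzip members are written with fixed mtime and no embedded
filename so identical content yields identical bytes.

## Reproducibility

One master seed fans out to fixed per-stage seed-sequence tags (reference,
tree, subclones, events, noise, haplotypes, reads), so enabling read
generation does not perturb the tree or the profiles. Read generation
additionally derives one stream per cell. The run manifest echoes the full
resolved configuration and a SHA-256 checksum per output file;
re-running a configuration reproduces every checksum.

## What the synthetic data does and does not emulate

The built-in reference generator draws i.i.d. bases at a target GC
fraction with a single arm boundary per chromosome. It has no repeats, no
mappability structure, no GC-coverage coupling, no telomere/centromere
masking; the error model has no caller-specific artifacts and no
whole-genome-amplification chimeras or allelic dropout. Tests passing on
this synthetic data therefore validate the simulator's *contracts*
(bookkeeping, calibration, determinism, depth–CN proportionality), not
fidelity to any particular sequencing platform. Real references and arm
tables (a UCSC cytoBand converter is included) can replace the synthetic
ones without code changes.

## Verification problem sizes

The test suite and the acceptance script run desk-scale configurations
chosen to give tight Monte-Carlo bands at interactive runtimes: coalescent
moments with n = 10 over 2,000 replicates; bookkeeping-oracle agreement
over 200 randomized toy genomes (≤ 50 regions, ≤ 20 events); event-log
replay over 100 randomized configurations; boundary/jitter calibration at
10⁵ replicates; depth proportionality on a 1 Mb genome at 5× coverage;
pseudo-normal event-count calibration over 10⁴ draws. Larger runs (100
cells, CNP mode) complete in seconds; thousands of cells remain practical
because genomes are region lists, not sequences.

## Known limitations

No SNVs/indels, structural insertions, breakage–fusion–bridge,
translocations, chromothripsis/chromoplexy or kataegis; no bulk or exome
modes; no temporal sampling; no misalignment/mappability error patterns.
Sweep and outgroup-attachment mechanisms are deliberately simple documented
stand-ins. CNLOH occurs only at focal scale.
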