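# sccnsim

Simulation of single-cell tumor copy-number data: timed cell genealogies,
multi-scale copy-number alterations (CNAs), realistic error-injected
copy-number profiles (CNPs), and haplotype-aware paired-end sequencing reads.

Benchmarking CNA callers and tumor-phylogeny methods on single-cell
DNA-sequencing data is hard because real datasets have no ground truth and
very high error rates. `sccnsim` generates datasets where the truth is known
at every level — the lineage tree, every mutation event, every cell's exact
genome — together with observations degraded the way low-coverage scDNA-seq
and downstream CNA calling degrade them.

## Model

**Lineage.** The *n* sampled tumor cells get a genealogy under the neutral
coalescent: while *k* ancestral lineages remain, pairs coalesce at rate
k(k−1)/2 per coalescent time unit, scaled by the relative population size
N(t). Exponential tumor growth appears backward in time as
N(t) = e^(−αt); selective sweeps are instantaneous bottlenecks that multiply
N by a severity in (0, 1], producing bursts of coalescence. The tumor MRCA
is the *founder* cell; normal and pseudo-normal (near-diploid, tumor-
unrelated) cells attach as outgroups on a stem above it, and disjoint clades
inside the tumor are marked as subclones.

**Genome and events.** Each chromosome is an ordered set of fixed-size
regions (default 1 kb); a cell genome is a set of *allele lineages* per
chromosome, each an ordered list of region identifiers founded from
haplotype A or B. Along each edge of the tree, in a top-down traversal:

- **focal gains / losses / copy-neutral LOH** arrive as a Poisson process in
  branch length, with truncated-geometric lengths and geometric gain
  magnitudes;
- **chromosome-arm and whole-chromosome CNAs** occur on the edge into the
  founder (a burst of genomic instability) and on edges into subclone roots,
  each subclone acquiring a unique event signature;
- an optional **whole-genome duplication (WGD)** at tumor onset copies every
  allele lineage. Chromosomes created by WGD or whole-chromosome duplication
  become *new* allele lineages, so allele-specific copy number stays well
  defined.

**Outputs.** Ground-truth CNPs are binned (default 1 Mb), length-weighted,
integer copy numbers per cell, total and allele-specific. Noisy CNPs add
(i) segment-boundary displacement — geometric shifts of breakpoints,
mimicking caller segmentation error — and (ii) state-proportional Gaussian
jitter, mimicking read-count nonuniformity. In reads mode, each allele
lineage is rebuilt into DNA from one of two SNP-bearing haploid references,
an AR(1)-lognormal coverage landscape is drawn over fixed windows, and
paired-end reads are emitted per window *per genome copy*, so sequencing
depth is proportional to local copy number by construction.

## Worked example

```bash
sccnsim -n 20 --normal-cells 2 --pseudo-normal-cells 2 --subclones 2 \
        --wgd --num-chromosomes 2 --chrom-length 2000000 \
        --bin-size 100000 --mean-focal-length 100 --min-focal-length 10 \
        --seed 42 --out demo
# wrote 8 files to demo ({'events_applied': 29, 'observed_cells': 24})
```

`demo/` now holds `tree.nwk`, `leaf_metadata.tsv`, `event_log.tsv`, truth
and noisy profiles, and `manifest.json` with a SHA-256 checksum of every
output (re-running the same command reproduces all of them bit-for-bit).
The event log starts at the founder edge — WGD first, then the chromosomal
burst:

```
edge_child_id  order  scale       type  chrom  arm    allele  start_region  length  magnitude
38             0      wgd         gain
38             1      arm         loss  chr2   q      A.wgd
38             2      arm         loss  chr1   p      A.wgd
38             3      chromosome  gain  chr2   whole  A                             1
```

and the noisy profile of a subclone-1 tumor cell shows the resulting
aneuploidy (total copy 3 after WGD plus an arm loss, a focal gain at
200–300 kb, and the allele split skewed to the B haplotype):

```
cell_id         chrom  start   end     cn_total  cn_a  cn_b
tumor_0005_sc1  chr1   0       100000  3         1     2
tumor_0005_sc1  chr1   100000  200000  3         1     2
tumor_0005_sc1  chr1   200000  300000  4         1     3
tumor_0005_sc1  chr1   300000  400000  3         1     2
```

Normal cells (`normal_0001`, ...) stay exactly diploid in the truth files.
Add `--mode both --coverage 0.1` to also write per-cell gzip FASTQ pairs
with haplotype-tagged read names.

The same pipeline is available as a library:

```python
from sccnsim import validate_config, run

manifest = run(validate_config({"num_cells": 100, "wgd": True, "seed": 7}))
```

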