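"""Independent brute-force oracles for cross-checking the simulator.

These deliberately avoid the package's event-application code paths: copy
numbers are tracked by direct per-region counter arithmetic driven by the
event log, and the genealogy oracle is a naive pairwise-merger coalescent.
"""

import math
import random


def counter_cn_from_log(template, events):
    """Per-region total CN from event arithmetic alone.

    Starts every region at 2 and adds/subtracts per event, using a naive
    mirror of the allele state only to resolve which reference regions an
    event touches.  Returns {chrom: [cn per region]}.
    """
    state = {
        chrom: {
            "A": list(range(template.n_regions(chrom))),
            "B": list(range(template.n_regions(chrom))),
        }
        for chrom in template.chromosomes
    }
    counter = {chrom: [2] * template.n_regions(chrom) for chrom in template.chromosomes}
    for ev in events:
        if ev.scale == "wgd":
            for chrom in counter:
                counter[chrom] = [2 * c for c in counter[chrom]]
                for label, seq in list(state[chrom].items()):
                    new, k = label + ".wgd", 2
                    while new in state[chrom]:
                        new = f"{label}.wgd{k}"
                        k += 1
                    state[chrom][new] = list(seq)
            continue
        chrom = ev.chrom
        if ev.scale == "focal":
            seq = state[chrom][ev.allele]
            seg = seq[ev.start : ev.start + ev.length]
            if ev.type == "gain":
                for r in seg:
                    counter[chrom][r] += ev.magnitude
                seq[ev.start + ev.length : ev.start + ev.length] = seg * ev.magnitude
            elif ev.type == "loss":
                for r in seg:
                    counter[chrom][r] -= 1
                del seq[ev.start : ev.start + ev.length]
            else:  # cnloh: copy-neutral, move copies to the donor lineage
                donor = None
                for label in sorted(state[chrom]):
                    if label != ev.allele and set(seg) <= set(state[chrom][label]):
                        donor = label
                        break
                del seq[ev.start : ev.start + ev.length]
                dseq = state[chrom][donor]
                for r in seg:
                    dseq.insert(dseq.index(r) + 1, r)
        else:  # arm or whole-chromosome
            lo, hi = template.arm_region_range(chrom, ev.arm)
            seq = state[chrom][ev.allele]
            touched = [r for r in seq if lo <= r < hi]
            if ev.type == "loss":
                for r in touched:
                    counter[chrom][r] -= 1
                if ev.scale == "chromosome":
                    del state[chrom][ev.allele]
                else:
                    state[chrom][ev.allele] = [r for r in seq if not lo <= r < hi]
            else:
                for r in touched:
                    counter[chrom][r] += 1
                if ev.scale == "chromosome":
                    i = 1
                    while f"{ev.allele}.dup{i}" in state[chrom]:
                        i += 1
                    state[chrom][f"{ev.allele}.dup{i}"] = list(seq)
                else:
                    idx = [i for i, r in enumerate(seq) if lo <= r < hi]
                    pos = idx[-1] + 1
                    seq[pos:pos] = touched
    return counter


def pairwise_merger_tmrca(n, py_rng):
    """One Kingman genealogy by naive pairwise merging; returns
    (tmrca, total branch length)."""
    k, t, total = n, 0.0, 0.0
    while k > 1:
        wait = py_rng.expovariate(k * (k - 1) / 2.0)
        total += k * wait
        t += wait
        k -= 1
    return t, total


def harmonic(n):
    return sum(1.0 / i for i in range(1, n + 1))
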