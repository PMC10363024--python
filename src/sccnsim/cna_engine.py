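"""Copy-number event model: drawing and applying CNAs along the tree.

Events act on :class:`~sccnsim.genome.CellGenome` objects in a top-down
traversal of the cell lineage tree.  Three scales exist:

* focal gain / loss / copy-neutral LOH, drawn per edge at a Poisson rate
  proportional to branch length, with geometric lengths (in regions) and
  geometric gain magnitudes;
* chromosome-arm and whole-chromosome gains/losses, placed on the edge into
  the tumor founder (the burst of genomic instability that creates the
  tumor) and on edges into subclone roots, where each subclone acquires a
  unique multiset of chromosomal events;
* whole-genome duplication (WGD), optionally at the onset of the tumor.

Chromosomes created by WGD or whole-chromosome duplication are treated as
new allele lineages (fresh labels), so allele-specific copy number remains
well defined after any event history.  Copy-neutral LOH moves a segment's
copies from one lineage to a homologous lineage carrying the same reference
regions, leaving total copy number untouched.

Every applied event is recorded with its resolved stochastic choices
(allele, coordinates, magnitude), so replaying the log from a fresh diploid
genome reproduces each cell's genome exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ContractViolationError, ParameterError
from .genome import CellGenome, GenomeTemplate, init_diploid_genome
from . import lineage as _lineage

__all__ = [
    "CNAEvent",
    "EventModelParams",
    "draw_focal_event",
    "apply_focal_event",
    "draw_chromosomal_event",
    "apply_chromosomal_event",
    "apply_wgd",
    "apply_event",
    "evolve_tree",
    "make_pseudo_normal",
    "replay_event_log",
    "write_event_log",
    "read_event_log",
]

logger = logging.getLogger(__name__)

FOCAL, ARM, CHROMOSOME, WGD = "focal", "arm", "chromosome", "wgd"
GAIN, LOSS, CNLOH = "gain", "loss", "cnloh"


@dataclass(frozen=True)
class CNAEvent:
    """One copy-number event, with all stochastic choices resolved.

    ``start`` indexes the acting allele's *current* region sequence at the
    moment the event applies (not reference coordinates), so a log replay
    must apply events in recorded order.
    """

    node: int  # child node of the edge the event lies on
    order: int  # application order within that edge
    scale: str  # focal | arm | chromosome | wgd
    type: str  # gain | loss | cnloh (wgd scale implies gain)
    chrom: str | None = None
    arm: str | None = None  # p | q | whole (non-focal only)
    allele: str | None = None
    start: int | None = None  # focal only
    length: int | None = None  # focal only, in regions
    magnitude: int | None = None  # gains only, copies added

    def __post_init__(self):
        if self.scale == FOCAL:
            if self.start is None or self.start < 0 or not self.length or self.length < 1:
                raise ParameterError("focal event needs start >= 0 and length >= 1")
            if self.type == CNLOH and self.magnitude is not None:
                raise ParameterError("CNLOH has no magnitude")
        elif self.scale in (ARM, CHROMOSOME):
            if self.type == CNLOH:
                raise ParameterError("CNLOH is restricted to focal scale")
            if self.arm not in ("p", "q", "whole"):
                raise ParameterError("chromosomal event needs arm in {p, q, whole}")
        elif self.scale == WGD:
            if self.chrom is not None or self.allele is not None or self.arm is not None:
                raise ParameterError("WGD takes no chromosome/arm/allele fields")
        else:
            raise ParameterError(f"unknown scale {self.scale!r}")
        if self.type == GAIN and self.scale != WGD and (self.magnitude or 0) < 1:
            raise ParameterError("gains need magnitude >= 1")


@dataclass(frozen=True)
class EventModelParams:
    """Tunable parameters of the event model.

    Rates are per coalescent time unit; lengths are in regions.
    """

    focal_rate: float = 2.0  # lambda_f, focal events per unit branch length
    mean_focal_length: float = 1000.0  # mean length in regions (1 Mb at 1 kb regions)
    min_focal_length: int = 100
    p_gain: float = 0.5  # P(focal event is a gain)
    p_cnloh: float = 0.1  # P(focal event reclassified as CNLOH)
    p_mag: float = 0.5  # geometric success prob; magnitude mean = 1/p_mag
    founder_event_mean: float = 5.0  # mu_founder, chromosomal events into founder
    subclone_event_mean: float = 2.0  # mu_sc, extra chromosomal events per subclone
    p_arm: float = 0.5  # P(chromosomal event is arm-level rather than whole)
    p_chrom_gain: float = 0.5  # P(chromosomal event is a gain)
    wgd: bool = False  # whole-genome duplication at tumor onset
    pseudo_normal_event_mean: float = 3.0  # mu_pn, focal events per pseudo-normal
    events_per_edge: int | None = None  # fixed focal count per edge (overrides Poisson)

    def __post_init__(self):
        for name in ("p_gain", "p_cnloh", "p_mag", "p_arm", "p_chrom_gain"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.p_mag == 0:
            raise ParameterError("p_mag must be > 0")
        for name in ("focal_rate", "founder_event_mean", "subclone_event_mean",
                     "pseudo_normal_event_mean"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.min_focal_length < 1:
            raise ParameterError("min_focal_length must be >= 1")
        if self.mean_focal_length < self.min_focal_length:
            raise ParameterError("mean_focal_length must be >= min_focal_length")


# ---------------------------------------------------------------------------
# Drawing events
# ---------------------------------------------------------------------------

def _nonempty_lineages(genome: CellGenome) -> list[tuple[str, str, int]]:
    return [
        (chrom, label, len(seq))
        for chrom, lineages in genome.alleles.items()
        for label, seq in lineages.items()
        if seq
    ]


def draw_focal_event(
    genome: CellGenome,
    params: EventModelParams,
    rng: np.random.Generator,
    node: int = -1,
    order: int = 0,
) -> CNAEvent | None:
    """Draw one focal event against the genome's current state.

    The acting allele is chosen with probability proportional to its current
    region count (uniform per-bp rate over the genome); the start is uniform;
    the length is min_focal_length plus a geometric excess matched to
    mean_focal_length, truncated to fit the allele.  Type is gain with
    probability p_gain else loss, then reclassified CNLOH with probability
    p_cnloh when a homologous lineage carries the whole segment.  Returns
    None when every allele is empty (fully deleted genome).
    """
    lineages = _nonempty_lineages(genome)
    if not lineages:
        logger.warning("focal event skipped: all allele lineages empty")
        return None
    weights = np.array([n for _, _, n in lineages], dtype=float)
    chrom, allele, n = lineages[rng.choice(len(lineages), p=weights / weights.sum())]
    min_len = params.min_focal_length
    if n <= min_len:
        start, length = 0, n
    else:
        start = int(rng.integers(0, n - min_len + 1))
        excess = params.mean_focal_length - min_len
        if excess > 0:
            # geometric on {0, 1, ...} with mean `excess`
            length = min_len + int(rng.geometric(1.0 / (1.0 + excess))) - 1
        else:
            length = min_len
        length = min(length, n - start)
    etype = GAIN if rng.random() < params.p_gain else LOSS
    magnitude: int | None = int(rng.geometric(params.p_mag)) if etype == GAIN else None
    if rng.random() < params.p_cnloh:
        seq = genome.alleles[chrom][allele]
        segment = seq[start : start + length]
        if _cnloh_donor(genome, chrom, allele, segment) is not None:
            etype, magnitude = CNLOH, None
    return CNAEvent(node=node, order=order, scale=FOCAL, type=etype, chrom=chrom,
                    allele=allele, start=start, length=length, magnitude=magnitude)


def draw_chromosomal_event(
    genome: CellGenome,
    template: GenomeTemplate,
    params: EventModelParams,
    rng: np.random.Generator,
    node: int = -1,
    order: int = 0,
) -> CNAEvent | None:
    """Draw one chromosome-arm or whole-chromosome event.

    Chromosome uniform; arm-level with probability p_arm (p or q uniform)
    else whole-chromosome; gain with probability p_chrom_gain.  The acting
    allele is uniform among lineages carrying at least one region of the
    target arm; if none does, the event is skipped (returns None).
    """
    chrom = template.chromosomes[rng.integers(0, len(template.chromosomes))]
    if rng.random() < params.p_arm:
        arm = "p" if rng.random() < 0.5 else "q"
        scale = ARM
    else:
        arm, scale = "whole", CHROMOSOME
    etype = GAIN if rng.random() < params.p_chrom_gain else LOSS
    lo, hi = template.arm_region_range(chrom, arm)
    carriers = [
        label
        for label, seq in genome.alleles[chrom].items()
        if any(lo <= r < hi for r in seq)
    ]
    if not carriers:
        logger.warning("%s %s %s on %s skipped: no carrier allele", scale, arm, etype, chrom)
        return None
    allele = carriers[rng.integers(0, len(carriers))]
    return CNAEvent(node=node, order=order, scale=scale, type=etype, chrom=chrom,
                    arm=arm, allele=allele, magnitude=1 if etype == GAIN else None)


# ---------------------------------------------------------------------------
# Applying events
# ---------------------------------------------------------------------------

def _cnloh_donor(genome: CellGenome, chrom: str, allele: str, segment: list[int]) -> str | None:
    """Deterministic CNLOH donor: lexicographically smallest other lineage
    whose region set contains every region of the segment."""
    needed = set(segment)
    for label in sorted(genome.alleles[chrom]):
        if label == allele:
            continue
        if needed <= set(genome.alleles[chrom][label]):
            return label
    return None


def apply_focal_event(genome: CellGenome, event: CNAEvent) -> CellGenome:
    """Apply a focal gain, loss or CNLOH in place and return the genome."""
    if event.scale != FOCAL:
        raise ParameterError("apply_focal_event expects a focal event")
    seq = genome.alleles[event.chrom].get(event.allele)
    if seq is None or event.start + event.length > len(seq):
        raise ContractViolationError(
            f"focal event out of bounds: {event.chrom}/{event.allele} "
            f"[{event.start}, {event.start + event.length}) on length "
            f"{0 if seq is None else len(seq)}"
        )
    lo, hi = event.start, event.start + event.length
    if event.type == LOSS:
        del seq[lo:hi]
    elif event.type == GAIN:
        segment = seq[lo:hi]
        seq[hi:hi] = segment * event.magnitude
    elif event.type == CNLOH:
        segment = seq[lo:hi]
        donor = _cnloh_donor(genome, event.chrom, event.allele, segment)
        if donor is None:
            raise ContractViolationError("CNLOH has no homologous donor lineage")
        del seq[lo:hi]
        donor_seq = genome.alleles[event.chrom][donor]
        # Duplicate each lost copy next to the donor's own occurrence, so
        # per-region total copy number is conserved exactly.
        for region in segment:
            idx = donor_seq.index(region)
            donor_seq.insert(idx + 1, region)
    else:
        raise ParameterError(f"unknown focal event type {event.type!r}")
    return genome


def _fresh_label(existing, base: str, suffix: str) -> str:
    i = 1
    while f"{base}.{suffix}{i}" in existing:
        i += 1
    return f"{base}.{suffix}{i}"


def apply_chromosomal_event(
    genome: CellGenome, event: CNAEvent, template: GenomeTemplate
) -> CellGenome:
    """Apply an arm or whole-chromosome gain/loss in place.

    Losses remove the arm's regions from the acting allele (a whole-
    chromosome loss removes the entire lineage).  Arm gains append the
    arm's regions in tandem on the acting allele; whole-chromosome gains
    create a new allele lineage carrying a copy of the acting allele.
    """
    if event.scale not in (ARM, CHROMOSOME):
        raise ParameterError("expected an arm or chromosome scale event")
    lineages = genome.alleles[event.chrom]
    seq = lineages.get(event.allele)
    if seq is None:
        raise ContractViolationError(f"allele {event.allele} absent on {event.chrom}")
    lo, hi = template.arm_region_range(event.chrom, event.arm)
    if event.type == LOSS:
        if event.scale == CHROMOSOME:
            del lineages[event.allele]
        else:
            lineages[event.allele] = [r for r in seq if not lo <= r < hi]
    elif event.type == GAIN:
        if event.scale == CHROMOSOME:
            label = _fresh_label(lineages, event.allele, "dup")
            lineages[label] = list(seq)
        else:
            idx = [i for i, r in enumerate(seq) if lo <= r < hi]
            if not idx:
                raise ContractViolationError("arm gain on allele not carrying the arm")
            segment = [seq[i] for i in idx]
            pos = idx[-1] + 1
            seq[pos:pos] = segment
    else:
        raise ParameterError(f"unknown chromosomal event type {event.type!r}")
    return genome


def apply_wgd(genome: CellGenome) -> CellGenome:
    """Duplicate every allele lineage into a new '.wgd'-suffixed lineage;
    total copy number doubles at every region."""
    for lineages in genome.alleles.values():
        snapshot = list(lineages.items())
        for label, seq in snapshot:
            new = label + ".wgd"
            k = 2
            while new in lineages:  # repeated WGDs: A -> A.wgd -> A.wgd2 ...
                new = f"{label}.wgd{k}"
                k += 1
            lineages[new] = list(seq)
    return genome


def apply_event(genome: CellGenome, event: CNAEvent, template: GenomeTemplate) -> CellGenome:
    if event.scale == FOCAL:
        return apply_focal_event(genome, event)
    if event.scale == WGD:
        return apply_wgd(genome)
    return apply_chromosomal_event(genome, event, template)


# ---------------------------------------------------------------------------
# Tree traversal
# ---------------------------------------------------------------------------

def _edge_focal_count(params: EventModelParams, branch_length: float,
                      rng: np.random.Generator) -> int:
    if params.events_per_edge is not None:
        return params.events_per_edge
    return int(rng.poisson(params.focal_rate * branch_length))


def _apply_focal_burst(genome, params, rng, node, count, order, log):
    """Draw and immediately apply `count` focal events on one edge."""
    for _ in range(count):
        event = draw_focal_event(genome, params, rng, node=node, order=order)
        if event is None:
            continue
        apply_focal_event(genome, event)
        log.append(event)
        order += 1
    return order


def _chromosomal_signature(events) -> tuple:
    return tuple(sorted((e.chrom, e.arm, e.type) for e in events))


def evolve_tree(
    tree: "_lineage.CellLineageTree",
    template: GenomeTemplate,
    params: EventModelParams,
    rng: np.random.Generator,
) -> tuple[dict[int, CellGenome], list[CNAEvent]]:
    """Evolve genomes down the tree; return genomes for every node + event log.

    The root carries a fresh diploid genome.  Edges inside the tumor clade
    draw Poisson(focal_rate x branch length) focal events.  The edge into
    the tumor founder first applies the optional WGD, then
    Poisson(founder_event_mean) chromosomal events, then its focal events.
    Each edge into a subclone root draws 1 + Poisson(subclone_event_mean)
    chromosomal events, resampled (up to 100 attempts) until the multiset of
    (chromosome, arm, type) differs from every other subclone's.  Stem edges
    above the founder and normal leaves receive no events; pseudo-normal
    leaves draw Poisson(pseudo_normal_event_mean) focal events on their
    pendant edge.
    """
    founder = tree.founder()
    in_tumor = {nid for nid in tree.preorder() if tree.is_ancestor(founder, nid)}
    genomes: dict[int, CellGenome] = {}
    log: list[CNAEvent] = []
    subclone_signatures: list[tuple] = []
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            genomes[nid] = init_diploid_genome(template)
            continue
        genome = genomes[node.parent].copy()
        genomes[nid] = genome
        order = 0
        if nid in in_tumor:
            if nid == founder:
                if params.wgd:
                    event = CNAEvent(node=nid, order=order, scale=WGD, type=GAIN)
                    apply_wgd(genome)
                    log.append(event)
                    order += 1
                n_chrom_events = int(rng.poisson(params.founder_event_mean))
                for _ in range(n_chrom_events):
                    event = draw_chromosomal_event(
                        genome, template, params, rng, node=nid, order=order
                    )
                    if event is None:
                        continue
                    apply_chromosomal_event(genome, event, template)
                    log.append(event)
                    order += 1
            if node.subclone_id is not None:
                order = _apply_subclone_events(
                    genome, template, params, rng, nid, order, log, subclone_signatures
                )
            count = _edge_focal_count(params, node.length, rng)
            order = _apply_focal_burst(genome, params, rng, nid, count, order, log)
        elif node.node_class == _lineage.PSEUDO_NORMAL_LEAF:
            count = int(rng.poisson(params.pseudo_normal_event_mean))
            order = _apply_focal_burst(genome, params, rng, nid, count, order, log)
        # stem nodes and normal leaves: no events, genome inherited as-is
    return genomes, log


def _apply_subclone_events(genome, template, params, rng, nid, order, log, signatures):
    for _attempt in range(100):
        count = 1 + int(rng.poisson(params.subclone_event_mean))
        trial = genome.copy()
        events = []
        o = order
        for _ in range(count):
            event = draw_chromosomal_event(trial, template, params, rng, node=nid, order=o)
            if event is None:
                continue
            apply_chromosomal_event(trial, event, template)
            events.append(event)
            o += 1
        sig = _chromosomal_signature(events)
        if events and sig not in signatures:
            signatures.append(sig)
            genome.alleles = trial.alleles
            log.extend(events)
            return o
    raise ParameterError(
        "could not draw a unique chromosomal-event signature for a subclone "
        "after 100 attempts; increase subclone_event_mean or chromosome count"
    )


def make_pseudo_normal(
    template: GenomeTemplate,
    mu_pn: float,
    params: EventModelParams,
    rng: np.random.Generator,
    log: list[CNAEvent] | None = None,
) -> CellGenome:
    """Near-diploid genome: fresh diploid plus Poisson(mu_pn) focal events.

    Pseudo-normal cells never receive chromosomal events or WGD.  Applied
    events are appended to ``log`` when given.
    """
    genome = init_diploid_genome(template)
    count = int(rng.poisson(mu_pn))
    sink: list[CNAEvent] = []
    _apply_focal_burst(genome, params, rng, -1, count, 0, sink)
    if log is not None:
        log.extend(sink)
    return genome


def replay_event_log(
    tree: "_lineage.CellLineageTree",
    template: GenomeTemplate,
    log: list[CNAEvent],
) -> dict[int, CellGenome]:
    """Re-derive every node's genome from the event log alone.

    All stochastic choices are resolved in the log and the remaining rules
    (CNLOH donor, duplicate labels) are deterministic, so this reproduces
    :func:`evolve_tree`'s genomes exactly.
    """
    by_node: dict[int, list[CNAEvent]] = {}
    for event in log:
        by_node.setdefault(event.node, []).append(event)
    genomes: dict[int, CellGenome] = {}
    for nid in tree.preorder():
        node = tree.nodes[nid]
        if node.parent is None:
            genomes[nid] = init_diploid_genome(template)
        else:
            genomes[nid] = genomes[node.parent].copy()
        for event in sorted(by_node.get(nid, []), key=lambda e: e.order):
            apply_event(genomes[nid], event, template)
    return genomes


# ---------------------------------------------------------------------------
# Event log I/O
# ---------------------------------------------------------------------------

_LOG_COLUMNS = ("edge_child_id", "order", "scale", "type", "chrom", "arm",
                "allele", "start_region", "length", "magnitude")


def write_event_log(log: list[CNAEvent], path) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(_LOG_COLUMNS) + "\n")
        for e in log:
            row = (e.node, e.order, e.scale, e.type, e.chrom, e.arm, e.allele,
                   e.start, e.length, e.magnitude)
            handle.write("\t".join("" if v is None else str(v) for v in row) + "\n")


def read_event_log(path) -> list[CNAEvent]:
    events = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if tuple(header) != _LOG_COLUMNS:
            raise ParameterError(f"{path}: unexpected event-log header")
        for line in handle:
            vals = line.rstrip("\n").split("\t")
            get = lambda i: vals[i] if vals[i] != "" else None
            events.append(
                CNAEvent(
                    node=int(vals[0]),
                    order=int(vals[1]),
                    scale=vals[2],
                    type=vals[3],
                    chrom=get(4),
                    arm=get(5),
                    allele=get(6),
                    start=None if get(7) is None else int(vals[7]),
                    length=None if get(8) is None else int(vals[8]),
                    magnitude=None if get(9) is None else int(vals[9]),
                )
            )
    return events
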