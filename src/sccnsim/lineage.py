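"""Timed single-cell genealogies.

The tumor sample is modeled as n cells drawn from a large exponentially
growing population under the neutral coalescent: looking backward in time
with k ancestral lineages, pairs coalesce at rate k(k-1)/2 scaled by the
inverse (relative) population size.  Time is measured in coalescent units,
so the constant-size neutral case (growth rate 0) has E[TMRCA] = 2(1 - 1/n).
Selective sweeps are modeled as instantaneous bottlenecks: at the sweep
time the backward-time population size is multiplied by a severity in
(0, 1], which produces a burst of coalescences.

Normal and pseudo-normal cells sampled alongside the tumor are attached as
outgroups on a stem added above the tumor MRCA (the *founder* cell), and
diverging subclonal populations are represented by disjoint clades within
the tumor lineage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import msprime
import numpy as np

from .exceptions import InfeasibleSubcloneError, ParameterError

__all__ = [
    "PopulationParams",
    "Node",
    "CellLineageTree",
    "simulate_tumor_lineage",
    "attach_outgroup_cells",
    "select_subclones",
    "write_newick",
    "write_leaf_metadata",
]

TUMOR_LEAF = "tumor_leaf"
NORMAL_LEAF = "normal_leaf"
PSEUDO_NORMAL_LEAF = "pseudo_normal_leaf"
ANCESTRAL = "ancestral"

LEAF_CLASSES = (TUMOR_LEAF, NORMAL_LEAF, PSEUDO_NORMAL_LEAF)

LEAF_NAME_RE = re.compile(
    r"^(tumor_\d{4}(_sc\d+)?|normal_\d{4}|pseudonormal_\d{4})$"
)


@dataclass(frozen=True)
class PopulationParams:
    """Population model of the tumor sample.

    Parameters
    ----------
    n
        Number of sampled tumor cells (>= 1).
    growth_rate
        Exponential growth rate alpha per coalescent time unit (>= 0);
        backward in time the population size shrinks as exp(-alpha * t).
    sweeps
        Sequence of (time, severity) pairs; at each sweep time the
        instantaneous population size is multiplied by severity in (0, 1].
        A sweep older than the sample's TMRCA has no effect.
    normal_count, pseudo_normal_count
        Numbers of diluting outgroup cells (>= 0).
    seed
        Seed for the coalescent simulation.
    """

    n: int
    growth_rate: float = 0.0
    sweeps: tuple[tuple[float, float], ...] = ()
    normal_count: int = 0
    pseudo_normal_count: int = 0
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ParameterError("tumor sample size n must be >= 1")
        if self.growth_rate < 0:
            raise ParameterError("growth_rate must be >= 0")
        if self.normal_count < 0 or self.pseudo_normal_count < 0:
            raise ParameterError("cell counts must be >= 0")
        for time, severity in self.sweeps:
            if time < 0:
                raise ParameterError("sweep times must be >= 0")
            if not 0 < severity <= 1:
                raise ParameterError("sweep severity must be in (0, 1]")


@dataclass
class Node:
    id: int
    parent: int | None
    length: float  # branch length to parent, coalescent units
    node_class: str
    is_founder: bool = False
    subclone_id: int | None = None


class CellLineageTree:
    """Rooted, timed genealogy of observed and ancestral cells."""

    def __init__(self, nodes: dict[int, Node], root: int):
        self.nodes = nodes
        self.root = root
        self._children: dict[int, list[int]] = {nid: [] for nid in nodes}
        for node in nodes.values():
            if node.parent is not None:
                self._children[node.parent].append(node.id)
        for kids in self._children.values():
            kids.sort()
        self._validate()

    # -- structure ---------------------------------------------------------
    def _validate(self):
        if self.nodes[self.root].parent is not None:
            raise ParameterError("root must have no parent")
        seen = set()
        for nid in self.preorder():
            if nid in seen:
                raise ParameterError("cycle detected in tree")
            seen.add(nid)
        if seen != set(self.nodes):
            raise ParameterError("disconnected nodes in tree")

    def children(self, nid: int) -> list[int]:
        return self._children[nid]

    def preorder(self) -> list[int]:
        out, stack = [], [self.root]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self._children[nid]))
        return out

    def postorder(self) -> list[int]:
        return list(reversed(self.preorder()))

    def leaves(self) -> list[int]:
        return [nid for nid in self.preorder() if not self._children[nid]]

    def leaves_of(self, nid: int) -> list[int]:
        out, stack = [], [nid]
        while stack:
            u = stack.pop()
            kids = self._children[u]
            if kids:
                stack.extend(kids)
            else:
                out.append(u)
        return out

    def tumor_leaves(self) -> list[int]:
        return [nid for nid in self.leaves() if self.nodes[nid].node_class == TUMOR_LEAF]

    def founder(self) -> int:
        for nid, node in self.nodes.items():
            if node.is_founder:
                return nid
        raise ParameterError("tree has no tumor-founder node")

    def is_ancestor(self, anc: int, nid: int) -> bool:
        cur = nid
        while cur is not None:
            if cur == anc:
                return True
            cur = self.nodes[cur].parent
        return False

    # -- times -------------------------------------------------------------
    def times(self) -> dict[int, float]:
        """Node times (leaves at 0), from branch lengths by postorder."""
        t: dict[int, float] = {}
        for nid in self.postorder():
            kids = self._children[nid]
            if not kids:
                t[nid] = 0.0
            else:
                t[nid] = max(t[c] + self.nodes[c].length for c in kids)
        return t

    def tmrca(self) -> float:
        """Time of the tumor MRCA (the founder node)."""
        return self.times()[self.founder()]

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.nodes.values() if n.parent is not None)

    # -- naming ------------------------------------------------------------
    def leaf_subclone(self, nid: int) -> int | None:
        """Subclone id inherited from the nearest subclone-root ancestor."""
        cur = nid
        while cur is not None:
            sid = self.nodes[cur].subclone_id
            if sid is not None:
                return sid
            cur = self.nodes[cur].parent
        return None

    def leaf_names(self) -> dict[int, str]:
        names: dict[int, str] = {}
        counters = {TUMOR_LEAF: 0, NORMAL_LEAF: 0, PSEUDO_NORMAL_LEAF: 0}
        prefixes = {TUMOR_LEAF: "tumor", NORMAL_LEAF: "normal", PSEUDO_NORMAL_LEAF: "pseudonormal"}
        for nid in sorted(self.leaves()):
            cls = self.nodes[nid].node_class
            counters[cls] += 1
            name = f"{prefixes[cls]}_{counters[cls]:04d}"
            if cls == TUMOR_LEAF:
                sid = self.leaf_subclone(nid)
                if sid is not None:
                    name += f"_sc{sid}"
            names[nid] = name
        return names


def _sweep_demography(params: PopulationParams) -> msprime.Demography:
    """Haploid population of relative size 1 with exponential growth and
    multiplicative instantaneous bottlenecks at the sweep times."""
    demography = msprime.Demography()
    demography.add_population(name="tumor", initial_size=1.0,
                              growth_rate=params.growth_rate)
    size, last_time = 1.0, 0.0
    for time, severity in sorted(params.sweeps):
        size = size * np.exp(-params.growth_rate * (time - last_time)) * severity
        demography.add_population_parameters_change(
            time=time, initial_size=size, growth_rate=params.growth_rate,
            population="tumor",
        )
        last_time = time
    return demography


def simulate_tumor_lineage(params: PopulationParams) -> CellLineageTree:
    """Simulate the timed genealogy of the n tumor cells.

    With growth_rate 0 and no sweeps this is the standard Kingman
    coalescent (pairwise rate k(k-1)/2 while k lineages remain).  The tumor
    MRCA is marked as the tumor founder.
    """
    if params.n == 1:
        nodes = {0: Node(0, None, 0.0, TUMOR_LEAF, is_founder=True)}
        return CellLineageTree(nodes, root=0)
    seed = None if params.seed is None else params.seed % (2**31 - 2) + 1
    ts = msprime.sim_ancestry(
        samples=params.n,
        ploidy=1,
        demography=_sweep_demography(params),
        random_seed=seed,
    )
    tree = ts.first()
    nodes: dict[int, Node] = {}
    for u in tree.nodes():
        parent = tree.parent(u)
        is_root = parent == -1
        nodes[u] = Node(
            id=u,
            parent=None if is_root else parent,
            length=0.0 if is_root else tree.branch_length(u),
            node_class=TUMOR_LEAF if ts.node(u).is_sample() else ANCESTRAL,
        )
    root = tree.root
    nodes[root].is_founder = True
    return CellLineageTree(nodes, root=root)


def attach_outgroup_cells(
    tree: CellLineageTree,
    normal_count: int,
    pseudo_normal_count: int,
    root_stem_length: float = 1.0,
    rng: np.random.Generator | None = None,
    random_spacing: bool = False,
) -> CellLineageTree:
    """Attach normal and pseudo-normal outgroup leaves above the tumor MRCA.

    A stem of ``root_stem_length`` is added above the founder; the outgroup
    leaves attach at evenly spaced points along it (normals closest to the
    new root, pseudo-normals between the normals and the founder).  With
    ``random_spacing`` the attachment times are instead drawn uniformly on
    the stem (sorted), using ``rng``.
    """
    if normal_count < 0 or pseudo_normal_count < 0:
        raise ParameterError("outgroup cell counts must be >= 0")
    if root_stem_length <= 0:
        raise ParameterError("root_stem_length must be > 0")
    founder = tree.founder()
    founder_time = tree.times()[founder]
    nodes = {nid: Node(n.id, n.parent, n.length, n.node_class, n.is_founder, n.subclone_id)
             for nid, n in tree.nodes.items()}
    next_id = max(nodes) + 1
    m = normal_count + pseudo_normal_count
    if random_spacing:
        if rng is None:
            raise ParameterError("random_spacing requires an rng")
        offsets = np.sort(rng.uniform(0.0, root_stem_length, size=m))
    else:
        offsets = np.array([root_stem_length * (j + 1) / (m + 1) for j in range(m)])
    # Build the chain bottom-up: pseudo-normals attach nearest the founder,
    # normals above them, new root at founder_time + root_stem_length.
    attach_classes = [PSEUDO_NORMAL_LEAF] * pseudo_normal_count + [NORMAL_LEAF] * normal_count
    below, below_time = founder, founder_time
    for offset, leaf_class in zip(offsets, attach_classes):
        attach_time = founder_time + offset
        attach_id, leaf_id = next_id, next_id + 1
        next_id += 2
        nodes[below].parent = attach_id
        nodes[below].length = attach_time - below_time
        nodes[attach_id] = Node(attach_id, None, 0.0, ANCESTRAL)
        nodes[leaf_id] = Node(leaf_id, attach_id, attach_time, leaf_class)
        below, below_time = attach_id, attach_time
    root_id = next_id
    nodes[below].parent = root_id
    nodes[below].length = founder_time + root_stem_length - below_time
    nodes[root_id] = Node(root_id, None, 0.0, ANCESTRAL)
    return CellLineageTree(nodes, root=root_id)


def _max_disjoint_clades(tree: CellLineageTree, founder: int, min_size: int) -> int:
    """Maximum number of disjoint tumor clades of >= min_size leaves, by
    bottom-up dynamic programming over the founder subtree (the founder
    itself is not a candidate)."""
    best: dict[int, int] = {}
    leaf_count: dict[int, int] = {}
    for nid in tree.postorder():
        if not tree.is_ancestor(founder, nid):
            continue
        kids = tree.children(nid)
        leaf_count[nid] = 1 if not kids else sum(leaf_count[c] for c in kids)
        child_sum = sum(best.get(c, 0) for c in kids)
        own = 1 if (kids and nid != founder and leaf_count[nid] >= min_size) else 0
        best[nid] = max(child_sum, own)
    return best.get(founder, 0)


def select_subclones(
    tree: CellLineageTree,
    k: int,
    min_size: int,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> CellLineageTree:
    """Mark k disjoint tumor-internal clades as subclone roots.

    Selection is greedy-random: candidate internal nodes (strictly inside
    the tumor clade, with at least ``min_size`` tumor-leaf descendants) are
    shuffled and accepted while leaf-disjoint from those already accepted;
    the shuffle is retried until k are found.  Raises
    :class:`InfeasibleSubcloneError` when no k disjoint clades exist.
    """
    if k < 0:
        raise ParameterError("k must be >= 0")
    if min_size < 1:
        raise ParameterError("min_size must be >= 1")
    for node in tree.nodes.values():
        node.subclone_id = None
    if k == 0:
        return tree
    founder = tree.founder()
    achievable = _max_disjoint_clades(tree, founder, min_size)
    if achievable < k:
        raise InfeasibleSubcloneError(k, achievable)
    candidates = [
        nid
        for nid in tree.preorder()
        if tree.children(nid)
        and nid != founder
        and tree.is_ancestor(founder, nid)
        and len(tree.leaves_of(nid)) >= min_size
    ]
    for _ in range(max_attempts):
        order = list(candidates)
        rng.shuffle(order)
        accepted: list[int] = []
        taken: set[int] = set()
        for nid in order:
            leaves = set(tree.leaves_of(nid))
            if leaves.isdisjoint(taken):
                accepted.append(nid)
                taken |= leaves
                if len(accepted) == k:
                    break
        if len(accepted) == k:
            for sid, nid in enumerate(accepted, start=1):
                tree.nodes[nid].subclone_id = sid
            return tree
    raise InfeasibleSubcloneError(k, achievable)  # pragma: no cover


def _format_length(x: float) -> str:
    if x == int(x):
        return f"{x:.1f}"
    return f"{x:.12g}"


def write_newick(tree: CellLineageTree) -> str:
    """Newick string with branch lengths; leaf names encode class and
    subclone id (tumor_0007_sc1, normal_0001, ...)."""
    names = tree.leaf_names()
    parts: dict[int, str] = {}
    for nid in tree.postorder():
        kids = tree.children(nid)
        node = tree.nodes[nid]
        if kids:
            label = "(" + ",".join(parts[c] for c in kids) + ")"
        else:
            label = names[nid]
        if node.parent is not None:
            label += ":" + _format_length(node.length)
        parts[nid] = label
    return parts[tree.root] + ";"


def write_leaf_metadata(tree: CellLineageTree, path) -> None:
    """TSV of leaf name, class and subclone id."""
    names = tree.leaf_names()
    with open(path, "w") as handle:
        handle.write("leaf\tclass\tsubclone\n")
        for nid in sorted(tree.leaves()):
            node = tree.nodes[nid]
            sid = tree.leaf_subclone(nid) if node.node_class == TUMOR_LEAF else None
            handle.write(f"{names[nid]}\t{node.node_class}\t{'' if sid is None else sid}\n")
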