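import numpy as np
import pytest

from sccnsim.genome import GenomeTemplate
from sccnsim.lineage import (
    ANCESTRAL,
    TUMOR_LEAF,
    CellLineageTree,
    Node,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_template(n_regions=10, n_chromosomes=1, region_size=1000,
                  bins_per_chrom=None, arm_boundary_region=None):
    """Toy template with whole-region chromosomes (no short last region)."""
    length = n_regions * region_size
    if bins_per_chrom is None:
        bin_size = length  # one bin per chromosome
    else:
        assert n_regions % bins_per_chrom == 0
        bin_size = length // bins_per_chrom
    boundary_region = arm_boundary_region if arm_boundary_region is not None \
        else n_regions // 2
    chroms = tuple(f"chr{i + 1}" for i in range(n_chromosomes))
    return GenomeTemplate(
        chromosomes=chroms,
        lengths={c: length for c in chroms},
        arm_boundaries={c: boundary_region * region_size for c in chroms},
        region_size=region_size,
        bin_size=bin_size,
    )


@pytest.fixture
def toy_template():
    return make_template()


def balanced_tumor_tree(depth=3, branch_length=1.0):
    """Perfectly balanced binary tumor tree with 2**depth leaves."""
    nodes = {}
    counter = [0]

    def build(parent, d):
        nid = counter[0]
        counter[0] += 1
        nodes[nid] = Node(nid, parent, branch_length if parent is not None else 0.0,
                          ANCESTRAL if d < depth else TUMOR_LEAF)
        if d < depth:
            build(nid, d + 1)
            build(nid, d + 1)
        return nid

    root = build(None, 0)
    nodes[root].is_founder = True
    return CellLineageTree(nodes, root=root)
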