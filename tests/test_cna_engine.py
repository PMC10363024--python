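"""Event drawing, application semantics, tree evolution, log replay."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sccnsim.cna_engine import (
    CNAEvent,
    EventModelParams,
    apply_chromosomal_event,
    apply_focal_event,
    apply_wgd,
    draw_chromosomal_event,
    draw_focal_event,
    evolve_tree,
    make_pseudo_normal,
    read_event_log,
    replay_event_log,
    write_event_log,
)
from sccnsim.exceptions import ContractViolationError, ParameterError
from sccnsim.genome import init_diploid_genome
from sccnsim.lineage import PopulationParams, select_subclones, simulate_tumor_lineage

from conftest import balanced_tumor_tree, make_template
from naive_oracles import counter_cn_from_log


def focal(type_, start, length, allele="A", magnitude=None, chrom="chr1"):
    return CNAEvent(node=0, order=0, scale="focal", type=type_, chrom=chrom,
                    allele=allele, start=start, length=length, magnitude=magnitude)


class TestApplyFocal:
    def test_loss_splices_out_segment(self, toy_template):
        genome = init_diploid_genome(toy_template)
        apply_focal_event(genome, focal("loss", 3, 2))
        assert genome.alleles["chr1"]["A"] == [0, 1, 2, 5, 6, 7, 8, 9]

    def test_gain_inserts_tandem_copies(self, toy_template):
        genome = init_diploid_genome(toy_template)
        apply_focal_event(genome, focal("gain", 3, 2, magnitude=2))
        expected = [0, 1, 2, 3, 4, 3, 4, 3, 4, 5, 6, 7, 8, 9]
        assert genome.alleles["chr1"]["A"] == expected
        assert len(genome.alleles["chr1"]["A"]) == 14

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        start=st.integers(0, 9),
        length=st.integers(1, 10),
        magnitude=st.integers(1, 4),
        kind=st.sampled_from(["gain", "loss"]),
    )
    def test_matches_list_splice_oracle(self, start, length, magnitude, kind):
        template = make_template(n_regions=10)
        genome = init_diploid_genome(template)
        length = min(length, 10 - start)
        naive = list(range(10))
        segment = naive[start : start + length]
        if kind == "loss":
            expected = naive[:start] + naive[start + length :]
            event = focal("loss", start, length)
        else:
            expected = (naive[: start + length] + segment * magnitude
                        + naive[start + length :])
            event = focal("gain", start, length, magnitude=magnitude)
        apply_focal_event(genome, event)
        assert genome.alleles["chr1"]["A"] == expected

    def test_cnloh_conserves_total_cn(self, toy_template, rng):
        genome = init_diploid_genome(toy_template)
        # prior gain so the genome is not flat
        apply_focal_event(genome, focal("gain", 2, 3, magnitude=1))
        before = genome.total_copy_number(toy_template, "chr1").copy()
        apply_focal_event(genome, focal("cnloh", 4, 3))
        after = genome.total_copy_number(toy_template, "chr1")
        assert (before == after).all()
        # but the allele-specific split moved
        a, b = genome.allele_copy_number(toy_template, "chr1")
        assert (a != b).any()

    def test_out_of_bounds_rejected(self, toy_template):
        genome = init_diploid_genome(toy_template)
        with pytest.raises(ContractViolationError):
            apply_focal_event(genome, focal("loss", 8, 5))


class TestDrawFocal:
    def test_degenerate_distributions_give_unit_gain(self, toy_template, rng):
        params = EventModelParams(p_gain=1.0, p_cnloh=0.0, p_mag=1.0,
                                  mean_focal_length=2.0, min_focal_length=1)
        genome = init_diploid_genome(toy_template)
        for _ in range(50):
            event = draw_focal_event(genome, params, rng)
            assert event.type == "gain"
            assert event.magnitude == 1

    def test_length_mean_matches_construction(self, rng):
        # truncated-geometric lengths: sample mean within 2% of the target
        template = make_template(n_regions=10_000)
        genome = init_diploid_genome(template)
        params = EventModelParams(mean_focal_length=5.0, min_focal_length=1,
                                  p_cnloh=0.0)
        draws = [draw_focal_event(genome, params, rng).length for _ in range(50_000)]
        assert abs(np.mean(draws) - 5.0) < 0.1

    def test_cnloh_impossible_on_single_allele(self, toy_template, rng):
        genome = init_diploid_genome(toy_template)
        del genome.alleles["chr1"]["B"]
        params = EventModelParams(p_cnloh=1.0, min_focal_length=1,
                                  mean_focal_length=2.0)
        for _ in range(30):
            event = draw_focal_event(genome, params, rng)
            assert event.type in ("gain", "loss")

    def test_empty_genome_skips(self, toy_template, rng):
        genome = init_diploid_genome(toy_template)
        genome.alleles["chr1"]["A"].clear()
        genome.alleles["chr1"]["B"].clear()
        assert draw_focal_event(genome, EventModelParams(), rng) is None

    def test_allele_choice_weighted_by_length(self, rng):
        template = make_template(n_regions=100)
        genome = init_diploid_genome(template)
        genome.alleles["chr1"]["B"] = genome.alleles["chr1"]["B"][:10]  # 10 vs 100
        params = EventModelParams(min_focal_length=1, mean_focal_length=2.0,
                                  p_cnloh=0.0)
        picks = [draw_focal_event(genome, params, rng).allele for _ in range(3000)]
        frac_a = picks.count("A") / len(picks)
        assert abs(frac_a - 100 / 110) < 0.03


def chromosomal(scale, type_, arm, allele="A", chrom="chr1"):
    return CNAEvent(node=0, order=0, scale=scale, type=type_, chrom=chrom,
                    arm=arm, allele=allele,
                    magnitude=1 if type_ == "gain" else None)


class TestChromosomalAndWgd:
    def test_p_arm_loss(self):
        template = make_template(n_regions=10, arm_boundary_region=4)
        genome = init_diploid_genome(template)
        apply_chromosomal_event(genome, chromosomal("arm", "loss", "p"), template)
        assert genome.alleles["chr1"]["A"] == [4, 5, 6, 7, 8, 9]
        assert genome.alleles["chr1"]["B"] == list(range(10))

    def test_whole_chromosome_gain_creates_new_lineage(self, toy_template):
        genome = init_diploid_genome(toy_template)
        apply_chromosomal_event(
            genome, chromosomal("chromosome", "gain", "whole"), toy_template
        )
        assert set(genome.alleles["chr1"]) == {"A", "B", "A.dup1"}
        assert (genome.total_copy_number(toy_template, "chr1") == 3).all()

    def test_arm_gain_is_tandem(self):
        template = make_template(n_regions=6, arm_boundary_region=3)
        genome = init_diploid_genome(template)
        apply_chromosomal_event(genome, chromosomal("arm", "gain", "q"), template)
        assert genome.alleles["chr1"]["A"] == [0, 1, 2, 3, 4, 5, 3, 4, 5]

    def test_nullisomy_then_skip(self, toy_template, rng):
        genome = init_diploid_genome(toy_template)
        apply_chromosomal_event(
            genome, chromosomal("chromosome", "loss", "whole", "A"), toy_template
        )
        apply_chromosomal_event(
            genome, chromosomal("chromosome", "loss", "whole", "B"), toy_template
        )
        assert genome.alleles["chr1"] == {}
        params = EventModelParams(p_arm=0.0, p_chrom_gain=0.0)
        assert draw_chromosomal_event(genome, toy_template, params, rng) is None

    def test_wgd_doubles_everything(self, toy_template):
        genome = init_diploid_genome(toy_template)
        apply_wgd(genome)
        assert set(genome.alleles["chr1"]) == {"A", "B", "A.wgd", "B.wgd"}
        assert (genome.total_copy_number(toy_template, "chr1") == 4).all()

    def test_wgd_copies_prior_deletion(self, toy_template):
        genome = init_diploid_genome(toy_template)
        apply_focal_event(genome, focal("loss", 0, 3))
        apply_wgd(genome)
        assert genome.alleles["chr1"]["A.wgd"] == genome.alleles["chr1"]["A"]

    def test_double_wgd_quadruples(self, toy_template):
        genome = init_diploid_genome(toy_template)
        apply_wgd(apply_wgd(genome))
        assert (genome.total_copy_number(toy_template, "chr1") == 8).all()
        assert len(genome.alleles["chr1"]) == 8


def random_event_burst(genome, template, params, rng, n_events):
    """Draw-and-apply a mixed burst, recording the log."""
    log = []
    for i in range(n_events):
        if rng.random() < 0.3:
            event = draw_chromosomal_event(genome, template, params, rng, order=i)
            if event is None:
                continue
            apply_chromosomal_event(genome, event, template)
        else:
            event = draw_focal_event(genome, params, rng, order=i)
            if event is None:
                continue
            apply_focal_event(genome, event)
        log.append(event)
    return log


class TestBookkeepingOracle:
    def test_total_cn_matches_counter_oracle(self, rng):
        # allele-sequence occurrence counts vs. independent event arithmetic
        params = EventModelParams(min_focal_length=1, mean_focal_length=4.0,
                                  p_cnloh=0.2, p_mag=0.5)
        for trial in range(40):
            template = make_template(
                n_regions=int(rng.integers(10, 51)),
                arm_boundary_region=int(rng.integers(2, 8)),
            )
            genome = init_diploid_genome(template)
            log = random_event_burst(
                genome, template, params, rng, int(rng.integers(1, 21))
            )
            expected = counter_cn_from_log(template, log)
            got = genome.total_copy_number(template, "chr1")
            assert got.tolist() == expected["chr1"], f"trial {trial}"


class TestEvolveTree:
    def test_no_events_means_all_diploid(self, toy_template, rng):
        tree = balanced_tumor_tree(depth=3)
        params = EventModelParams(focal_rate=0.0, founder_event_mean=0.0)
        genomes, log = evolve_tree(tree, toy_template, params, rng)
        assert log == []
        diploid = init_diploid_genome(toy_template)
        assert all(g == diploid for g in genomes.values())

    def test_wgd_hits_all_tumor_cells(self, toy_template, rng):
        from sccnsim.lineage import attach_outgroup_cells

        tree = simulate_tumor_lineage(PopulationParams(n=6, seed=4))
        tree = attach_outgroup_cells(tree, 2, 0, root_stem_length=0.5)
        params = EventModelParams(focal_rate=0.0, founder_event_mean=0.0, wgd=True)
        genomes, log = evolve_tree(tree, toy_template, params, rng)
        assert [e.scale for e in log] == ["wgd"]
        for nid in tree.leaves():
            cn = genomes[nid].total_copy_number(toy_template, "chr1")
            if tree.nodes[nid].node_class == "tumor_leaf":
                assert (cn == 4).all()
            else:
                assert (cn == 2).all()

    def test_normal_leaves_stay_diploid_under_heavy_mutation(self, rng):
        from sccnsim.lineage import attach_outgroup_cells

        template = make_template(n_regions=30, n_chromosomes=2)
        tree = simulate_tumor_lineage(PopulationParams(n=8, seed=9))
        tree = attach_outgroup_cells(tree, 2, 2, root_stem_length=1.0)
        params = EventModelParams(focal_rate=5.0, founder_event_mean=3.0, wgd=True,
                                  min_focal_length=1, mean_focal_length=3.0,
                                  pseudo_normal_event_mean=2.0)
        genomes, _ = evolve_tree(tree, template, params, rng)
        diploid = init_diploid_genome(template)
        for nid in tree.leaves():
            if tree.nodes[nid].node_class == "normal_leaf":
                assert genomes[nid] == diploid

    def test_subclone_signatures_unique(self, rng):
        template = make_template(n_regions=20, n_chromosomes=4)
        tree = simulate_tumor_lineage(PopulationParams(n=24, seed=13))
        select_subclones(tree, 3, 4, rng)
        params = EventModelParams(focal_rate=0.0, founder_event_mean=0.0,
                                  subclone_event_mean=1.0)
        _, log = evolve_tree(tree, template, params, rng)
        subclone_nodes = {n.id for n in tree.nodes.values() if n.subclone_id}
        assert {e.node for e in log} == subclone_nodes
        sigs = []
        for nid in subclone_nodes:
            sigs.append(tuple(sorted(
                (e.chrom, e.arm, e.type) for e in log if e.node == nid
            )))
        assert len(set(sigs)) == len(sigs)
        # each subclone edge got at least 1 + Poisson(mu) >= 1 events
        assert all(len(s) >= 1 for s in sigs)

    def test_replay_reproduces_leaf_genomes(self, rng):
        template = make_template(n_regions=25, n_chromosomes=2)
        tree = simulate_tumor_lineage(PopulationParams(n=10, seed=30))
        params = EventModelParams(focal_rate=3.0, founder_event_mean=2.0, wgd=True,
                                  min_focal_length=1, mean_focal_length=3.0,
                                  p_cnloh=0.2)
        genomes, log = evolve_tree(tree, template, params, rng)
        replayed = replay_event_log(tree, template, log)
        for nid in tree.leaves():
            assert replayed[nid] == genomes[nid]

    def test_determinism_under_seed(self, toy_template):
        tree = balanced_tumor_tree(depth=3)
        params = EventModelParams(focal_rate=2.0, min_focal_length=1,
                                  mean_focal_length=3.0)
        logs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            _, log = evolve_tree(tree, toy_template, params, rng)
            logs.append(log)
        assert logs[0] == logs[1]


class TestPseudoNormal:
    def test_zero_rate_exact_diploid(self, toy_template, rng):
        genome = make_pseudo_normal(toy_template, 0.0, EventModelParams(), rng)
        assert genome == init_diploid_genome(toy_template)

    def test_poisson_event_mean(self, rng):
        template = make_template(n_regions=50)
        params = EventModelParams(min_focal_length=1, mean_focal_length=3.0)
        counts = []
        for _ in range(4000):
            log = []
            make_pseudo_normal(template, 3.0, params, rng, log=log)
            counts.append(len(log))
        se = np.sqrt(3.0 / len(counts))
        assert abs(np.mean(counts) - 3.0) < 3 * se
        assert all(e.scale == "focal" for e in log)

    def test_never_chromosomal(self, toy_template, rng):
        log = []
        for _ in range(200):
            make_pseudo_normal(toy_template, 2.0,
                               EventModelParams(min_focal_length=1,
                                                mean_focal_length=2.0),
                               rng, log=log)
        assert {e.scale for e in log} == {"focal"}


class TestEventLogIO:
    def test_round_trip(self, tmp_path, rng):
        template = make_template(n_regions=20)
        genome = init_diploid_genome(template)
        params = EventModelParams(min_focal_length=1, mean_focal_length=3.0,
                                  p_cnloh=0.3)
        log = random_event_burst(genome, template, params, rng, 15)
        path = tmp_path / "events.tsv"
        write_event_log(log, path)
        assert read_event_log(path) == log

    def test_invalid_event_fields_rejected(self):
        with pytest.raises(ParameterError):
            CNAEvent(node=0, order=0, scale="focal", type="gain", chrom="chr1",
                     allele="A", start=-1, length=2, magnitude=1)
        with pytest.raises(ParameterError):
            CNAEvent(node=0, order=0, scale="arm", type="cnloh", chrom="chr1",
                     arm="p", allele="A")
        with pytest.raises(ParameterError):
            CNAEvent(node=0, order=0, scale="wgd", type="gain", chrom="chr1")
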