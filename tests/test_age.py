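import numpy as np
import pytest

from _oracles import brute_force_msn
from l1diversity.age import (
    age_table_wide,
    build_mj_network,
    component_age_table,
    estimate_age_consensus,
    estimate_age_rho,
    pairwise_divergence,
)
from l1diversity.consensus import ColumnAlignment, majority_consensus


class TestPairwiseDivergence:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGA", (1, 4, 0.25)),
            ("ACGT", "ACGT", (0, 4, 0.0)),
            ("AC-T", "ACGT", (0, 3, 0.0)),
            ("NCGT", "ACGT", (0, 3, 0.0)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert pairwise_divergence(a, b) == expected

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            pairwise_divergence("ACG", "ACGT")

    def test_no_evaluable_sites_rejected(self):
        with pytest.raises(ValueError):
            pairwise_divergence("--", "AC")


class TestConsensusAge:
    def test_identical_copies_age_zero(self):
        aln = ColumnAlignment(["a", "b"], ["ACGT", "ACGT"])
        est = estimate_age_consensus(aln, "ACGT")
        assert est.age_myr == 0.0

    def test_divergence_to_age_arithmetic(self):
        # mean divergence 0.01485 at rate 0.0015/site/myr => 9.90 myr
        assert 0.01485 / 0.0015 == pytest.approx(9.90)

    def test_single_copy_sd_undefined(self):
        aln = ColumnAlignment(["a"], ["ACGT"])
        est = estimate_age_consensus(aln, "ACGA")
        assert est.sd_myr is None
        assert est.age_myr == pytest.approx(0.25 / 0.0015)

    def test_simulation_recovery_within_three_se(self):
        # 200 copies, 897 bp, true age 10 myr, uniform clock
        from l1diversity.simulate import (
            ComponentSpec,
            SimulationConfig,
            SubfamilySpec,
            expected_mismatch_fraction,
            generate_ancestral_consensus,
            evolve_copies,
        )

        cfg = SimulationConfig(
            components=[ComponentSpec("5UTR", 897, 1.0, 1.0)],
            subfamilies=[SubfamilySpec("s", 200, 10.0)],
            cpg_rate_multiplier=1.0,
            seed=17,
        )
        anc, _ = generate_ancestral_consensus(cfg)
        copies = evolve_copies(anc, cfg.subfamilies[0], cfg)
        aln = ColumnAlignment([c.id for c in copies], [c.sequence for c in copies])
        est = estimate_age_consensus(aln, majority_consensus(aln))
        truth = expected_mismatch_fraction(0.015, 0, 1.0, "A") / 0.0015
        assert abs(est.age_myr - truth) < 3 * est.sd_myr


class TestMJNetwork:
    def test_star_through_existing_median(self):
        net = build_mj_network(["AAA", "AAT", "ATA"])
        assert sorted(net.graph.edges(data="weight")) == [
            ("AAA", "AAT", 1),
            ("AAA", "ATA", 1),
        ]

    def test_single_haplotype(self):
        net = build_mj_network(["ACGT"])
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0

    def test_four_haplotype_cycle_equals_brute_force_msn(self):
        haps = ["AAAA", "AATT", "TTAA", "TTTT"]
        net = build_mj_network(haps, epsilon=0)
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {tuple(sorted(e)) for e in brute_force_msn(haps)}

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            build_mj_network(["AA", "AAA"])

    def test_duplicate_collapse_with_multiplicity(self):
        net = build_mj_network(["AAA", "AAA", "AAT"])
        assert net.multiplicity("AAA") == 2

    def test_added_median_creates_star(self):
        # three haplotypes pairwise 2 apart share the median ATA
        net = build_mj_network(["AAA", "TTA", "ATT"])
        assert "ATA" in net.graph
        assert net.graph.nodes["ATA"]["median"]

    @pytest.mark.parametrize("seed", range(10))
    def test_contains_msn_and_spans_observed_random(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 7)
        L = rng.integers(3, 13)
        haps = [
            "".join("ACGT"[i] for i in rng.integers(0, 4, size=L)) for _ in range(n)
        ]
        net = build_mj_network(haps, epsilon=0)
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert {tuple(sorted(e)) for e in brute_force_msn(haps)} <= edges
        assert set(haps) <= set(net.graph.nodes)
        import networkx as nx

        assert nx.is_connected(net.graph)

    def test_input_order_invariance(self):
        haps = ["AAAA", "AATT", "TTAA", "GTTT", "ACGT"]
        a = build_mj_network(haps)
        b = build_mj_network(haps[::-1])
        assert set(a.graph.nodes) == set(b.graph.nodes)
        assert {tuple(sorted(e)) for e in a.graph.edges} == {
            tuple(sorted(e)) for e in b.graph.edges
        }


class TestRhoAge:
    def test_star_closed_form(self):
        # 3 copies each 2 steps from the root: rho = 2
        root = "AAAAAA"
        leaves = ["TTAAAA", "AATTAA", "AAAATT"]
        net = build_mj_network([root] + leaves, multiplicities=[0, 1, 1, 1])
        est = estimate_age_rho(net, root, L=6, rate=0.0015)
        assert est.age_myr == pytest.approx(2 / (6 * 0.0015))

    def test_root_only_network(self):
        net = build_mj_network(["ACGT"])
        est = estimate_age_rho(net, "ACGT", L=4)
        assert est.age_myr == 0.0

    def test_missing_root_rejected(self):
        net = build_mj_network(["AAA", "AAT"])
        with pytest.raises(ValueError):
            estimate_age_rho(net, "TTT", L=3)

    def test_cross_method_agreement_on_star_genealogy(self, small_family):
        members = small_family.by_subfamily()["old"]
        seqs = [el.component_seq("ORF1") for el in members]
        aln = ColumnAlignment([el.id for el in members], seqs)
        cons = majority_consensus(aln)
        cons_est = estimate_age_consensus(aln, cons)
        haps, mults = list(seqs), [1] * len(seqs)
        if cons not in haps:
            haps.append(cons)
            mults.append(0)
        net = build_mj_network(haps, multiplicities=mults)
        rho_est = estimate_age_rho(net, cons, L=len(cons))
        assert abs(rho_est.age_myr - cons_est.age_myr) < 3 * cons_est.sd_myr


class TestAgeTable:
    def test_average_row_is_unweighted_mean(self, small_family):
        df = component_age_table(small_family.elements, include_network=False)
        body = df[(df["subfamily"] != "Average") & (df["method"] == "consensus-divergence")]
        avg = df[(df["subfamily"] == "Average") & (df["method"] == "consensus-divergence")]
        for comp in body["component"].unique():
            expected = body[body["component"] == comp]["age_myr"].mean()
            got = avg[avg["component"] == comp]["age_myr"].iloc[0]
            assert got == pytest.approx(expected)

    def test_single_subfamily_average_equals_itself(self, small_family):
        members = small_family.by_subfamily()["young"]
        df = component_age_table(members, include_network=False, combined_component=None)
        wide = age_table_wide(df)
        assert np.allclose(wide.loc["young"], wide.loc["Average"])

    def test_scaling_age_scales_estimate(self):
        # doubling the simulated age about doubles the estimated age
        from l1diversity.simulate import (
            ComponentSpec,
            SimulationConfig,
            SubfamilySpec,
            simulate_family,
        )

        ages = {}
        for age in (5.0, 10.0):
            cfg = SimulationConfig(
                components=[ComponentSpec("5UTR", 800, 1.0, 1.0)],
                subfamilies=[SubfamilySpec("s", 250, age)],
                cpg_rate_multiplier=1.0,
                seed=23,
            )
            fam = simulate_family(cfg)
            df = component_age_table(
                fam.elements, include_network=False, combined_component=None
            )
            ages[age] = df[df["subfamily"] == "s"]["age_myr"].iloc[0]
        assert ages[10.0] / ages[5.0] == pytest.approx(2.0, rel=0.15)
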