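import numpy as np
import pytest

from l1diversity.io import read_fasta
from l1diversity.simulate import (
    ComponentSpec,
    SimulationConfig,
    SubfamilySpec,
    count_cpg_positions,
    default_config,
    evolve_copies,
    expected_mismatch_fraction,
    generate_ancestral_consensus,
    load_config,
    save_config,
    simulate_family,
    write_simulation,
)


def _single_component_config(length, cpg_density=0.0, seed=0, **kwargs):
    return SimulationConfig(
        components=[ComponentSpec("5UTR", length, 1.0, cpg_density)],
        subfamilies=kwargs.pop("subfamilies", [SubfamilySpec("s", 1, 0.0)]),
        seed=seed,
        **kwargs,
    )


class TestAncestralConsensus:
    def test_default_total_length(self):
        seq, comps = generate_ancestral_consensus(default_config(seed=0))
        assert len(seq) == 5944 == 897 + 1017 + 3828 + 202
        assert comps["ORF2"] == (1914, 5742)

    def test_zero_density_means_no_cpg(self):
        cfg = _single_component_config(10, cpg_density=0.0, seed=3)
        seq, _ = generate_ancestral_consensus(cfg)
        assert len(seq) == 10
        assert "CG" not in seq

    def test_determinism(self):
        cfg = default_config(seed=42)
        a, _ = generate_ancestral_consensus(cfg)
        b, _ = generate_ancestral_consensus(default_config(seed=42))
        assert a == b

    def test_only_acgt(self):
        seq, _ = generate_ancestral_consensus(default_config(seed=1))
        assert set(seq) <= set("ACGT")

    @pytest.mark.parametrize("density", [0.5, 2.0, 5.0, 20.0])
    def test_cpg_count_within_ten_percent(self, density):
        cfg = _single_component_config(1000, cpg_density=density, seed=7)
        seq, _ = generate_ancestral_consensus(cfg)
        target = density * 1000 / 100
        assert abs(len(count_cpg_positions(seq)) - target) <= 0.1 * target

    def test_impossible_density_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            ComponentSpec("x", 100, 1.0, cpg_density=60)


class TestEvolveCopies:
    def test_age_zero_is_ancestor_plus_diagnostics(self):
        cfg = _single_component_config(
            50, subfamilies=[SubfamilySpec("s", 5, 0.0, diagnostic_subs=[(5, "T")])], seed=2
        )
        anc, _ = generate_ancestral_consensus(cfg)
        copies = evolve_copies(anc, cfg.subfamilies[0], cfg)
        expected = anc[:5] + "T" + anc[6:]
        assert all(c.sequence == expected for c in copies)

    def test_diagnostics_present_in_every_copy_at_depth(self):
        cfg = _single_component_config(
            200,
            subfamilies=[SubfamilySpec("s", 50, 20.0, diagnostic_subs=[(7, "T"), (100, "A")])],
            seed=4,
        )
        anc, _ = generate_ancestral_consensus(cfg)
        for c in evolve_copies(anc, cfg.subfamilies[0], cfg):
            assert c.sequence[7] == "T" and c.sequence[100] == "A"

    def test_poisson_mean_divergence(self):
        # 1000 copies of a CpG-free 1000-bp component at age 10, rate 0.0015:
        # expected mismatch fraction 3/4(1-exp(-4*0.015/3)) ~ 0.01485,
        # checked within 3 standard errors of the mean over copies.
        cfg = _single_component_config(
            1000,
            cpg_density=0.0,
            subfamilies=[SubfamilySpec("s", 1000, 10.0)],
            cpg_rate_multiplier=1.0,
            seed=9,
        )
        anc, _ = generate_ancestral_consensus(cfg)
        copies = evolve_copies(anc, cfg.subfamilies[0], cfg)
        divs = np.array(
            [sum(a != b for a, b in zip(c.sequence, anc)) / 1000 for c in copies]
        )
        expected = expected_mismatch_fraction(0.015, 0, 1.0, "A")
        se = divs.std(ddof=1) / np.sqrt(len(divs))
        assert abs(divs.mean() - expected) < 3 * se

    def test_cpg_multiplier_monotonicity(self):
        # CpG-dense component: higher multiplier => strictly more divergence
        means = []
        for mult in (1.0, 10.0, 50.0):
            cfg = SimulationConfig(
                components=[ComponentSpec("5UTR", 500, 1.0, cpg_density=10.0)],
                subfamilies=[SubfamilySpec("s", 300, 10.0)],
                cpg_rate_multiplier=mult,
                seed=13,
            )
            anc, _ = generate_ancestral_consensus(cfg)
            copies = evolve_copies(anc, cfg.subfamilies[0], cfg)
            means.append(
                np.mean([sum(a != b for a, b in zip(c.sequence, anc)) for c in copies])
            )
        assert means[0] < means[1] < means[2]

    def test_protected_intervals_stay_pristine(self):
        cfg = SimulationConfig(
            components=[ComponentSpec("5UTR", 300, 1.0, 0.0)],
            subfamilies=[SubfamilySpec("s", 40, 50.0)],
            protected_intervals=[(100, 150)],
            cpg_rate_multiplier=1.0,
            seed=21,
        )
        anc, _ = generate_ancestral_consensus(cfg)
        for c in evolve_copies(anc, cfg.subfamilies[0], cfg):
            assert c.sequence[100:150] == anc[100:150]

    def test_no_indels_and_components_attached(self, small_family):
        L = small_family.config.total_length
        assert all(len(el.sequence) == L for el in small_family.elements)
        assert all(set(el.components) == {"5UTR", "ORF1", "ORF2", "3UTR"} for el in small_family.elements)


class TestFamilySimulation:
    def test_fasta_output_deterministic(self, tmp_path, small_config):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_simulation(simulate_family(small_config), d1)
        write_simulation(simulate_family(small_config), d2)
        assert (d1 / "all_subfamilies.fasta").read_bytes() == (
            d2 / "all_subfamilies.fasta"
        ).read_bytes()

    def test_written_fasta_reads_back(self, tmp_path, small_family):
        write_simulation(small_family, tmp_path)
        back = read_fasta(tmp_path / "all_subfamilies.fasta")
        assert len(back) == len(small_family.elements)
        assert back[0].sequence == small_family.elements[0].sequence

    def test_ground_truth_structure(self, small_family):
        gt = small_family.ground_truth
        assert set(gt["subfamilies"]) == {"young", "mid", "old"}
        per = gt["subfamilies"]["old"]["per_component"]["5UTR"]
        assert per["effective_age_myr"] == pytest.approx(10.0 * 1.8)
        # saturation keeps the clock estimand slightly below the raw product
        assert 0 < per["expected_age_estimate_myr"] < per["effective_age_myr"]

    def test_config_yaml_round_trip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        save_config(small_config, p)
        back = load_config(p)
        assert back == small_config
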