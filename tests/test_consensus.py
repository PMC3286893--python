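import pytest

from l1diversity.consensus import (
    ColumnAlignment,
    DiagnosticSet,
    align_to_reference,
    classify,
    majority_consensus,
    read_diagnostics,
)
from l1diversity.io import L1Element
from l1diversity.simulate import default_diagnostics


def _els(*seqs):
    return [L1Element(f"e{i}", None, s) for i, s in enumerate(seqs)]


class TestAlignToReference:
    def test_identity(self):
        aln = align_to_reference(_els("ACGTACGT"), "ACGTACGT")
        assert aln.rows == ["ACGTACGT"]

    def test_single_mismatch_column(self):
        aln = align_to_reference(_els("ACGAACGT"), "ACGTACGT")
        mismatches = [
            i for i, (a, b) in enumerate(zip(aln.rows[0], "ACGTACGT")) if a != b
        ]
        assert mismatches == [3]

    def test_internal_deletion_gives_gaps_in_reference_frame(self):
        # reference 10-mer, element missing 2 internal bases: the row keeps
        # reference length with exactly 2 gap characters
        ref = "ACGTACGTAC"
        aln = align_to_reference(_els("ACGTGTAC"), ref)
        row = aln.rows[0]
        assert len(row) == len(ref)
        assert row.count("-") == 2
        assert row.replace("-", "") == "ACGTGTAC"

    def test_insertion_columns_dropped(self):
        ref = "ACGTACGT"
        aln = align_to_reference(_els("ACGTTTACGT"), ref)
        assert len(aln.rows[0]) == len(ref)

    def test_short_element_warns(self):
        with pytest.warns(UserWarning, match="50%"):
            align_to_reference(_els("ACG"), "ACGTACGTACGT")

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            align_to_reference(_els("ACGT"), "")

    def test_indel_free_simulator_output_is_identity(self, small_family):
        els = small_family.elements[:10]
        aln = align_to_reference(els, small_family.consensus)
        assert aln.rows == [el.sequence for el in els]


class TestMajorityConsensus:
    def test_simple_majority(self):
        aln = ColumnAlignment(["a", "b", "c"], ["ACGT", "ACGT", "ACGA"])
        assert majority_consensus(aln) == "ACGT"

    def test_gap_and_n_never_vote(self):
        aln = ColumnAlignment(["a", "b"], ["A-", "AN"])
        assert majority_consensus(aln) == "AN"

    def test_tie_breaks_by_base_order(self):
        aln = ColumnAlignment(["a", "b"], ["A", "G"])
        assert majority_consensus(aln) == "A"

    def test_true_ancestor_at_majority_recovered_exactly(self, small_family):
        # ancestor + diagnostics occurs at multiplicity > n/2 => consensus
        anc = small_family.consensus
        rows = [anc] * 5 + [anc[:-1] + ("A" if anc[-1] != "A" else "C")] * 2
        aln = ColumnAlignment([f"r{i}" for i in range(7)], rows)
        assert majority_consensus(aln) == anc


class TestClassify:
    DIAGS = [
        DiagnosticSet("old", ((2, "T"),)),
        DiagnosticSet("young", ((2, "T"), (5, "A"))),
    ]

    def test_full_match_wins(self):
        res = classify("AATAAC", self.DIAGS)  # matches old only
        assert (res.subfamily, res.ambiguous) == ("old", False)

    def test_most_derived_among_full_matches(self):
        res = classify("AATAAA", self.DIAGS)  # matches both
        assert res.subfamily == "young"
        assert not res.ambiguous

    def test_no_full_match_flags_ambiguous(self):
        res = classify("AACAAA", self.DIAGS)  # young: 1/2, old: 0/1
        assert res.subfamily == "young"
        assert res.ambiguous
        assert res.matched_fraction == pytest.approx(0.5)

    def test_empty_diagnostics_rejected(self):
        with pytest.raises(ValueError):
            classify("ACGT", [])

    def test_simulator_round_trip_classification(self):
        # at ages <= 5 myr, diagnostic-based classification recovers the
        # generating subfamily for at least 99% of copies (a copy can still
        # hit a site that is diagnostic for a more derived subfamily)
        from l1diversity.simulate import (
            ComponentSpec,
            SimulationConfig,
            SubfamilySpec,
            simulate_family,
        )

        cfg = SimulationConfig(
            components=[ComponentSpec("5UTR", 1400, 1.0, 1.0)],
            subfamilies=[
                SubfamilySpec("young", 100, 2.0, [(800, "T")]),
                SubfamilySpec("mid", 100, 3.5, [(800, "T"), (850, "A")]),
                SubfamilySpec("old", 100, 5.0, [(800, "T"), (850, "A"), (900, "C")]),
            ],
            cpg_rate_multiplier=1.0,
            seed=29,
        )
        family = simulate_family(cfg)
        diags = [
            DiagnosticSet(s.name, tuple(s.diagnostic_subs)) for s in cfg.subfamilies
        ]
        correct = sum(
            classify(el.sequence, diags).subfamily == el.subfamily
            for el in family.elements
        )
        assert correct / len(family.elements) >= 0.99

    def test_round_trip_classification_exact_at_age_zero(self, small_family):
        diags = [
            DiagnosticSet(s.name, tuple(s.diagnostic_subs))
            for s in small_family.config.subfamilies
        ]
        from l1diversity.simulate import evolve_copies, SubfamilySpec

        spec = SubfamilySpec("mid", 10, 0.0, [(800, "T"), (850, "A")])
        copies = evolve_copies(small_family.consensus, spec, small_family.config)
        assert all(classify(c.sequence, diags).subfamily == "mid" for c in copies)

    def test_default_taxonomy_file_matches_simulator(self):
        from importlib import resources

        path = resources.files("l1diversity").joinpath("data/synthetic_diagnostics.tsv")
        sets = {d.subfamily: dict(d.sites) for d in read_diagnostics(path)}
        assert sets == {k: dict(v) for k, v in default_diagnostics().items()}
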