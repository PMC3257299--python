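"""Generator contracts: determinism, intervention semantics, design shape."""

import numpy as np
import pytest

from rootgrn import synthetic_data as sd
from rootgrn.core_data import Site, Treatment


class TestGenerateTruth:
    def test_zero_edges_gives_parentless_marginals(self):
        t = sd.generate_truth(5, 0, seed=3)
        assert all(not p for p in t.parents.values())
        for node in t.nodes:
            assert t.cpts[node.name].shape == (node.arity,)

    def test_same_seed_identical_truths(self):
        a = sd.generate_truth(8, 12, n_hormones=1, n_phenotypes=1, seed=7)
        b = sd.generate_truth(8, 12, n_hormones=1, n_phenotypes=1, seed=7)
        assert a.parents == b.parents
        for k in a.cpts:
            assert np.array_equal(a.cpts[k], b.cpts[k])

    def test_acyclic_by_independent_cycle_check(self):
        import networkx as nx

        t = sd.generate_truth(15, 20, seed=7)
        g = nx.DiGraph(list(t.edges()))
        assert nx.is_directed_acyclic_graph(g)

    def test_infeasible_edge_count_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            sd.generate_truth(3, 100, seed=0)

    def test_role_constraints_in_random_truths(self):
        t = sd.generate_truth(10, 25, n_hormones=2, n_phenotypes=2, seed=11)
        for p, c in t.edges():
            assert t.node(c).kind != sd.HORMONE
            assert t.node(p).kind != sd.PHENOTYPE
        # each phenotype received a designated gene driver
        for phen in t.phenotype_nodes:
            assert t.parents[phen]


class TestDefaultDesign:
    def test_learning_structure_counts(self, default_design):
        untreated = [
            l for l in default_design.lines if l.treatment is Treatment.NONE
        ]
        assert sum(l.n_replicates for l in untreated) == 66
        both_sites = [l for l in untreated if l.site is Site.SITE_B]
        assert sum(l.n_replicates for l in both_sites) == 12  # 4 lines x 3
        genotypes = {l.genotype for l in default_design.lines if l.genotype}
        assert len(genotypes) == 7  # distinct knockout lines

    def test_hormone_transfer_series_present(self, default_design):
        treatments = {l.treatment for l in default_design.lines}
        assert {Treatment.MS, Treatment.IAA, Treatment.ACC} <= treatments

    def test_design_yaml_round_trip(self, default_design, tmp_path):
        p = tmp_path / "design.yaml"
        default_design.to_yaml(p)
        back = sd.DesignConfig.from_yaml(p)
        assert back == default_design


class TestSimulateDataset:
    def test_same_seed_identical_study(self, default_truth, default_design):
        a = sd.simulate_dataset(default_truth, default_design, seed=3)
        b = sd.simulate_dataset(default_truth, default_design, seed=3)
        assert np.array_equal(a.expression.values, b.expression.values)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.sections, b.sections)

    def test_clamped_nodes_always_state_zero(self, default_study):
        names = default_study.node_names
        for j, s in enumerate(default_study.samples):
            for g in s.genotype:
                i = names.index(g)
                assert default_study.clamped[i, j]
                assert default_study.states[i, j] == 0

    def test_zero_noise_expression_equals_state_means(self, default_design):
        from dataclasses import replace

        t = sd.default_truth()
        t = replace(t, state_sd=0.0, site_shift={Site.SITE_A: 0.0, Site.SITE_B: 0.0})
        study = sd.simulate_dataset(t, default_design, seed=0, with_sections=False)
        names = study.node_names
        for g in t.gene_nodes:
            r = study.expression.gene_ids.index(g)
            means = t.state_means[g][study.states[names.index(g)]]
            assert np.allclose(study.expression.values[r], means)
        for g in t.background_means:
            r = study.expression.gene_ids.index(g)
            assert np.allclose(
                study.expression.values[r], t.background_means[g]
            )

    def test_root_state_frequencies_match_cpt(self):
        """Law of large numbers: wild-type root-node state frequencies track
        the marginal CPT."""
        t = sd.default_truth()
        design = sd.DesignConfig(
            lines=[sd.LineSpec("wt", frozenset(), Site.SITE_A, 10_000)],
            hairy_line_genotypes=[],
            hairless_line_genotype=frozenset(),
        )
        study = sd.simulate_dataset(t, design, seed=42, with_sections=False)
        root = study.state_row("G01")
        freqs = np.bincount(root, minlength=3) / len(root)
        assert np.allclose(freqs, t.cpts["G01"], atol=0.02)

    def test_unknown_design_node_is_inert_external(self, default_truth):
        design = sd.DesignConfig(
            lines=[
                sd.LineSpec("x", frozenset({"NOT_ON_CHIP"}), Site.SITE_A, 2),
                sd.LineSpec("wt", frozenset(), Site.SITE_A, 2),
            ],
            hairy_line_genotypes=[],
            hairless_line_genotype=frozenset(),
        )
        study = sd.simulate_dataset(default_truth, design, seed=1, with_sections=False)
        assert study.expression.external_knockouts(study.samples) == {
            "NOT_ON_CHIP"
        }

    def test_hormone_transfer_activates_hormone_and_targets(self, default_study):
        names = default_study.node_names
        t = default_study.truth
        for j, s in enumerate(default_study.samples):
            iaa = default_study.states[names.index("IAA"), j]
            assert iaa == int(s.treatment is Treatment.IAA)
            if s.treatment is Treatment.IAA and s.genotype == t.rescue.background:
                for target in t.rescue.targets["IAA"]:
                    assert default_study.states[names.index(target), j] == 2

    def test_phenotype_values_track_driver_inversely(self, default_study):
        lengths = default_study.phenotypes["P_LEN"]
        driver = default_study.state_row(sd.DEFAULT_LENGTH_DRIVER)
        lo = lengths[driver == 0].mean()
        hi = lengths[driver == 2].mean()
        assert lo > hi  # high driver expression -> short hairs


class TestSectionProfiles:
    def test_zone1_gene_peaks_in_first_band(self):
        t = sd.default_truth()
        secs = sd.simulate_section_profiles(t, noise_sd=0.0, seed=0)
        for r, g in enumerate(t.gene_nodes):
            if t.zone_of[g] == 1:
                assert secs[r, :12].argmax() in (0, 1)

    def test_six_peak_bands_recoverable_by_argmax(self):
        t = sd.default_truth()
        secs = sd.simulate_section_profiles(t, noise_sd=0.0, seed=0)
        peaks = secs[:, :12].argmax(axis=1) + 1
        bands = {(p + 1) // 2 for p in peaks}
        assert bands == {1, 2, 3, 4, 5, 6}
        order = np.argsort([t.zone_of[g] for g in t.gene_nodes], kind="stable")
        assert np.all(np.diff(peaks[order]) >= 0)

    def test_same_seed_identical_profiles(self, default_truth):
        a = sd.simulate_section_profiles(default_truth, seed=5)
        b = sd.simulate_section_profiles(default_truth, seed=5)
        assert np.array_equal(a, b)


class TestOracles:
    def test_truth_serialization_round_trip(self, default_truth, tmp_path):
        p = tmp_path / "truth.json"
        default_truth.to_json(p)
        back = sd.SyntheticTruth.from_json(p)
        assert back.parents == default_truth.parents
        for k in default_truth.cpts:
            assert np.allclose(back.cpts[k], default_truth.cpts[k])
        assert back.zone_of == default_truth.zone_of
        assert back.rescue == default_truth.rescue

    def test_expected_states_propagate_knockouts(self, default_truth):
        wt = sd.expected_states(default_truth)
        ko = sd.expected_states(default_truth, frozenset({"G05"}))
        assert ko["G05"] == 0
        assert ko["G09"] == 2  # repressed target derepressed
        assert ko["G01"] == wt["G01"]  # upstream untouched

    def test_truth_core_set_is_the_ten_pathway_genes(
        self, default_truth, default_design
    ):
        core = sd.truth_core_genes(default_truth, default_design)
        assert set(core) == {
            "G03", "G05", "G06", "G07", "G08", "G09", "G10", "G11", "G14", "G15",
        }
        assert {g for g, c in core.items() if c == "HAIR"} == {
            "G09", "G10", "G11", "G15",
        }
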