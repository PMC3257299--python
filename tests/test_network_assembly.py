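"""Signatures, clusters, enrichment, MDS and the promoter motif scan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist
from scipy.special import comb

from rootgrn.core_data import ExpressionMatrix
from rootgrn.differential_expression import SamResult
from rootgrn.network_assembly import (
    Response,
    build_clusters,
    classical_mds,
    fisher_enrichment,
    perturbation_signature,
    rhe_scan,
)
from rootgrn.temporal_zones import CollapsedZone, ZoneAssignment, collapse_zones


def sam_result(genes, fc, q):
    n = len(genes)
    return SamResult(
        gene_ids=list(genes),
        d=np.zeros(n),
        s=np.ones(n),
        fc=np.asarray(fc, dtype=float),
        s0=0.0,
        q=np.asarray(q, dtype=float),
    )


class TestPerturbationSignature:
    def test_threshold_gates(self):
        res = {
            "m1": sam_result(["g1", "g2", "g3"], [3.0, 3.0, 0.4], [0.01, 0.2, 0.001])
        }
        sig = perturbation_signature(res)
        assert sig.of("g1", "m1") is Response.UP
        assert sig.of("g2", "m1") is Response.NONE  # q gate
        assert sig.of("g3", "m1") is Response.DOWN

    def test_hormone_comparisons_use_stricter_fdr(self):
        res = {
            "IAA": sam_result(["g"], [3.0], [0.01]),
            "m1": sam_result(["g"], [3.0], [0.01]),
        }
        sig = perturbation_signature(res, hormone_perturbations={"IAA"})
        assert sig.of("g", "m1") is Response.UP
        assert sig.of("g", "IAA") is Response.NONE  # 0.01 >= 0.005

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(50)]
        res = {
            "m": sam_result(
                genes, np.exp(rng.normal(0, 1.5, 50)), rng.uniform(0, 0.2, 50)
            )
        }
        loose = perturbation_signature(res, fc_min=2.0, q_max=0.05)
        tight = perturbation_signature(res, fc_min=3.0, q_max=0.01)
        for g in genes:
            if tight.of(g, "m") is not Response.NONE:
                assert loose.of(g, "m") is tight.of(g, "m")

    def test_universe_mismatch_rejected(self):
        res = {
            "a": sam_result(["g1"], [1.0], [1.0]),
            "b": sam_result(["g2"], [1.0], [1.0]),
        }
        with pytest.raises(ValueError, match="universe"):
            perturbation_signature(res)


class TestBuildClusters:
    @staticmethod
    def _zones(genes, zones):
        z = ZoneAssignment(
            list(genes), np.asarray(zones), np.ones(len(genes), dtype=int)
        )
        return collapse_zones(z)

    def _signature(self, table):
        """table: gene -> list of fc over perturbations p1..pn."""
        genes = sorted(table)
        perts = [f"p{i+1}" for i in range(len(next(iter(table.values()))))]
        res = {
            p: sam_result(
                genes,
                [table[g][i] for g in genes],
                [0.001] * len(genes),
            )
            for i, p in enumerate(perts)
        }
        return perturbation_signature(res)

    def test_identical_signature_same_zone_clusters_together(self):
        sig = self._signature({"a": [3.0, 0.3], "b": [3.0, 0.3]})
        clusters = build_clusters(sig, self._zones("ab", [1, 2]), [])
        assert len(clusters) == 1 and clusters[0].members == ["a", "b"]

    def test_same_signature_different_zone_splits(self):
        sig = self._signature({"a": [3.0, 0.3], "b": [3.0, 0.3]})
        clusters = build_clusters(sig, self._zones("ab", [1, 5]), [])
        assert len(clusters) == 2

    def test_partition_is_exact(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        table = {g: list(np.exp(rng.normal(0, 1.5, 4))) for g in genes}
        sig = self._signature(table)
        zones = self._zones(genes, rng.integers(1, 7, 30))
        clusters = build_clusters(sig, zones, [])
        all_members = [g for c in clusters for g in c.members]
        assert sorted(all_members) == sorted(genes)

    def test_robust_flag_requires_six_of_panel(self):
        # gene 'a' responds in 6 of 9 panel perturbations, 'b' in 5
        fcs_a = [3.0] * 6 + [1.0] * 3
        fcs_b = [3.0] * 5 + [1.0] * 4
        sig = self._signature({"a": fcs_a, "b": fcs_b})
        panel = [f"p{i+1}" for i in range(9)]
        clusters = build_clusters(
            sig, self._zones("ab", [1, 1]), panel, robust_min=6
        )
        flags = {c.members[0]: c.robust_flag for c in clusters}
        assert flags == {"a": True, "b": False}


class TestFisherEnrichment:
    def test_worked_hypergeometric_example(self):
        universe = {f"g{i}" for i in range(20)}
        selected = {f"g{i}" for i in range(5)}
        term = {f"g{i}" for i in range(1, 6)}  # overlap 4
        frame = fisher_enrichment(selected, universe, {"T": term})
        assert frame.p[0] == pytest.approx(76 / 15504, rel=1e-12)

    def test_term_covering_universe_has_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        frame = fisher_enrichment({"g1", "g2"}, universe, {"all": universe})
        assert frame.p[0] == pytest.approx(1.0)

    def test_selected_equals_universe_p_one_everywhere(self):
        universe = {f"g{i}" for i in range(10)}
        ann = {"a": {"g1", "g2"}, "b": {"g3"}}
        frame = fisher_enrichment(universe, universe, ann)
        assert np.allclose(frame.p, 1.0)

    @settings(max_examples=200, deadline=None)
    @given(
        big_n=st.integers(5, 40),
        data=st.data(),
    )
    def test_matches_hypergeometric_tail_sum(self, big_n, data):
        n = data.draw(st.integers(1, big_n))
        big_k = data.draw(st.integers(0, big_n))
        universe = [f"g{i}" for i in range(big_n)]
        selected = set(universe[:n])
        term = set(universe[big_n - big_k :])
        frame = fisher_enrichment(selected, universe, {"T": term})
        k_obs = len(term & selected)
        tail = sum(
            comb(big_k, k, exact=True) * comb(big_n - big_k, n - k, exact=True)
            for k in range(k_obs, min(big_k, n) + 1)
        ) / comb(big_n, n, exact=True)
        assert frame.p[0] == pytest.approx(tail, rel=1e-9)

    def test_empty_universe_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrichment(set(), set(), {})


class TestClassicalMds:
    def test_3_4_5_triangle_exact(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        coords = classical_mds(d, 2)
        got = np.sort(pdist(coords))
        assert np.allclose(got, [3, 4, 5], atol=1e-9)

    def test_duplicated_sample_coincides(self):
        m = ExpressionMatrix(
            ["g1", "g2"],
            ["a", "b", "c"],
            np.array([[0.0, 5.0, 5.0], [1.0, 2.0, 2.0]]),
        )
        coords = classical_mds(m, 1)
        assert np.allclose(coords[1], coords[2])

    def test_translation_invariance_of_embedding_shape(self, rng):
        x = rng.normal(8, 2, size=(10, 6))
        m1 = ExpressionMatrix([f"g{i}" for i in range(10)],
                              [f"s{j}" for j in range(6)], x)
        m2 = ExpressionMatrix([f"g{i}" for i in range(10)],
                              [f"s{j}" for j in range(6)], x + 4.2)
        d1 = pdist(classical_mds(m1, 2))
        d2 = pdist(classical_mds(m2, 2))
        assert np.allclose(d1, d2, atol=1e-8)

    def test_insufficient_dimensions_error(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="positive eigenvalues"):
            classical_mds(d, 2)


class TestRheScan:
    def test_absent_motif_no_matches(self):
        res = rhe_scan({"g": "TTTTTTTTTT"}, "ACGT", window=10)
        assert res.count("g") == 0

    def test_planted_motif_position(self):
        # upstream region of 20 nt; motif ends 5 nt before the start codon
        seq = "A" * 10 + "GCGC" + "TTTCA"[:5] + "A"
        seq = "AAAAAAAAAAGCGCTTTCAA"
        res = rhe_scan({"g": seq}, "GCGC", window=20)
        positions = {(h.position, h.strand) for h in res.hits["g"]}
        # plus-strand hit at offset 10 of 20 -> position -10; GCGC is its own
        # reverse complement here
        assert (-10, "+") in positions
        assert (-10, "-") in positions

    def test_window_restricts_scan(self):
        seq = "GGGG" + "A" * 16  # motif outside the 10-nt proximal window
        res = rhe_scan({"g": seq}, "GGGG", window=10)
        assert res.count("g") == 0

    def test_degenerate_n_matches_everywhere(self):
        res = rhe_scan({"g": "ACGTACGTAC"}, "N", window=10)
        assert res.count("g") == 20  # both strands

    def test_iupac_codes_expand(self):
        res = rhe_scan({"g": "AAAAAGAAAA"}, "R", window=10)  # R = A or G
        plus = [h for h in res.hits["g"] if h.strand == "+"]
        assert len(plus) == 10

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            rhe_scan({"g": "ACGT"}, "ACGX")

    def test_fasta_file_input(self, tmp_path):
        p = tmp_path / "prom.fa"
        p.write_text(">gene1\nAAGCGCAA\n>gene2\nTTTTTTTT\n")
        res = rhe_scan(p, "GCGC", window=8)
        assert res.genes_with_hit() == {"gene1"}
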