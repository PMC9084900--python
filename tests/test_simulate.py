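"""Synthetic-data generators: planted structure, validity, seed determinism."""

import numpy as np
import pytest

from symbioscan.dnds import ng86_pair
from symbioscan.simulate import (
    PanelCategory,
    SimPanelSpec,
    simulate_codon_pair,
    simulate_community_matrix,
    simulate_contig_set,
    simulate_go_universe,
    simulate_ortholog_panel,
)


class TestCodonPair:
    def test_zero_dnds_introduces_no_nonsynonymous_changes(self):
        aln = simulate_codon_pair(400, 0.0, 0.3, seed=7)
        est = ng86_pair(aln.seq_a, aln.seq_b)
        assert est.nd == pytest.approx(0.0)
        assert est.ka == 0.0

    def test_zero_divergence_gives_identical_sequences(self):
        aln = simulate_codon_pair(200, 0.1, 0.0, seed=1)
        assert aln.seq_a == aln.seq_b
        assert ng86_pair(aln.seq_a, aln.seq_b).ks == 0.0

    def test_monte_carlo_recovery_of_planted_ratio(self):
        ests = []
        for seed in range(50):
            aln = simulate_codon_pair(2000, 0.2, 0.5, seed=seed)
            ests.append(ng86_pair(aln.seq_a, aln.seq_b).ratio)
        assert abs(np.mean(ests) - 0.2) < 0.05

    def test_alignments_satisfy_estimator_preconditions(self):
        for seed in range(5):
            aln = simulate_codon_pair(100, 0.3, 0.8, seed=seed)
            assert len(aln.seq_a) == len(aln.seq_b) == 300
            assert "-" not in aln.seq_a
            ng86_pair(aln.seq_a, aln.seq_b)  # raises on stops/frame issues

    def test_seed_determinism(self):
        a = simulate_codon_pair(150, 0.2, 0.4, seed=99)
        b = simulate_codon_pair(150, 0.2, 0.4, seed=99)
        assert (a.seq_a, a.seq_b) == (b.seq_a, b.seq_b)

    def test_near_saturation_warns_but_generates(self):
        with pytest.warns(UserWarning, match="saturation"):
            aln = simulate_codon_pair(200, 0.1, 5.0, seed=2)
        assert len(aln.seq_a) == 600


class TestOrthologPanel:
    def _two_cat_spec(self, seed=0):
        return SimPanelSpec(
            n_genes=40,
            codons_per_gene=400,
            categories=[
                PanelCategory("low", frozenset({"GO:0000002"}), 0.02, 0.4),
                PanelCategory("high", frozenset({"GO:0000003"}), 0.5, 0.4),
            ],
            seed=seed,
        )

    def test_high_category_scores_above_low(self):
        panel = simulate_ortholog_panel(self._two_cat_spec())
        by_cat = {"low": [], "high": []}
        for gene_id, aln in panel.alignments.items():
            est = ng86_pair(aln.seq_a, aln.seq_b)
            by_cat[panel.category_of[gene_id]].append(est.ratio)
        assert np.mean(by_cat["high"]) > np.mean(by_cat["low"])

    def test_single_gene_panel(self):
        spec = SimPanelSpec(
            n_genes=1,
            codons_per_gene=50,
            categories=[PanelCategory("only", frozenset(), 0.1, 0.2)],
            seed=4,
        )
        panel = simulate_ortholog_panel(spec)
        assert len(panel.alignments) == 1

    def test_seed_determinism(self):
        p1 = simulate_ortholog_panel(self._two_cat_spec(seed=5))
        p2 = simulate_ortholog_panel(self._two_cat_spec(seed=5))
        assert {g: (a.seq_a, a.seq_b) for g, a in p1.alignments.items()} == {
            g: (a.seq_a, a.seq_b) for g, a in p2.alignments.items()
        }

    def test_category_weights_apportion_genes(self):
        spec = SimPanelSpec(
            n_genes=10,
            codons_per_gene=20,
            categories=[
                PanelCategory("a", frozenset(), 0.1, 0.1, weight=1),
                PanelCategory("b", frozenset(), 0.1, 0.1, weight=3),
            ],
            seed=1,
        )
        panel = simulate_ortholog_panel(spec)
        counts = {"a": 0, "b": 0}
        for cat in panel.category_of.values():
            counts[cat] += 1
        assert counts == {"a": 3, "b": 7}  # largest-remainder on 2.5/7.5

    def test_annotations_and_truth_recorded(self):
        panel = simulate_ortholog_panel(self._two_cat_spec())
        for gene_id, terms in panel.annotations.items():
            cat = panel.category_of[gene_id]
            assert terms == ({"GO:0000002"} if cat == "low" else {"GO:0000003"})
            assert panel.truth[gene_id][0] == (0.02 if cat == "low" else 0.5)


class TestGoUniverse:
    def test_single_term_is_root(self):
        dag, ids = simulate_go_universe(1, max_depth=3, seed=0)
        assert ids == ["GO:0000001"]
        assert dag.parents["GO:0000001"] == set()

    def test_acyclic_by_topological_sort(self):
        import networkx as nx

        dag, _ = simulate_go_universe(20, max_depth=4, seed=3)
        g = nx.DiGraph(
            [(c, p) for c, ps in dag.parents.items() for p in ps]
        )
        assert nx.is_directed_acyclic_graph(g)
        list(nx.topological_sort(g))

    def test_every_term_reaches_root(self):
        dag, ids = simulate_go_universe(100, max_depth=5, seed=9)
        root = ids[0]
        for t in ids:
            assert root in dag.ancestors(t)

    def test_depth_bounded(self):
        dag, ids = simulate_go_universe(60, max_depth=3, seed=2)
        assert max(dag.depth(t) for t in ids) <= 3


class TestCommunityMatrix:
    def test_perfect_association_gives_rho_one(self):
        from symbioscan.association import spearman_midrank

        m = simulate_community_matrix(12, 5, host_index=2, corr_strength=1.0,
                                      noise_sd=0.0, seed=8)
        rho, _, _ = spearman_midrank(m.values["taxon_003"], m.values["symbiont_16S"])
        assert rho == pytest.approx(1.0)

    def test_null_association_centred_on_zero(self):
        from symbioscan.association import spearman_midrank

        rhos = []
        for seed in range(200):
            m = simulate_community_matrix(10, 4, host_index=0, corr_strength=0.0,
                                          noise_sd=1.0, seed=seed)
            rho, _, _ = spearman_midrank(m.values["taxon_001"], m.values["symbiont_16S"])
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1

    def test_seed_determinism_and_nonnegativity(self):
        m1 = simulate_community_matrix(12, 6, 1, 0.8, seed=5)
        m2 = simulate_community_matrix(12, 6, 1, 0.8, seed=5)
        assert m1.values.equals(m2.values)
        assert (m1.values.values >= 0).all()


class TestContigSet:
    def test_all_target_when_no_background(self):
        records, truth = simulate_contig_set(10, 0, seed=1)
        assert len(records) == 10
        assert set(truth.values()) == {"target"}

    def test_gc_band_separates_classes(self):
        records, truth = simulate_contig_set(
            200, 200, target_gc=(0.33, 0.02), background_gc=(0.55, 0.03), seed=6
        )
        inside = {
            c.contig_id: 0.24 <= c.gc <= 0.42 for c in records
        }
        target_in = np.mean([inside[c] for c, lab in truth.items() if lab == "target"])
        background_in = np.mean(
            [inside[c] for c, lab in truth.items() if lab == "background"]
        )
        assert target_in > 0.95
        assert background_in < 0.05

    def test_bounds_and_determinism(self):
        r1, t1 = simulate_contig_set(20, 20, seed=3)
        r2, t2 = simulate_contig_set(20, 20, seed=3)
        assert [(c.contig_id, c.length, c.gc, c.mean_coverage) for c in r1] == [
            (c.contig_id, c.length, c.gc, c.mean_coverage) for c in r2
        ]
        for c in r1:
            assert 500 <= c.length <= 60000
            assert 0 <= c.gc <= 1
            assert c.mean_coverage > 0
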