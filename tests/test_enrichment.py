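"""GO DAG loading, annotation propagation, and classic/elim enrichment."""

import math

import pytest

from symbioscan.enrichment import (
    GoDag,
    fisher_tail,
    load_obo,
    propagate_annotations,
    run_enrichment,
    significant_terms,
)


class TestLoadObo:
    def _write(self, tmp_path, text):
        path = tmp_path / "test.obo"
        path.write_text(text)
        return path

    CHAIN = """format-version: 1.2

[Term]
id: GO:0000001
name: root
namespace: biological_process

[Term]
id: GO:0000002
name: A
namespace: biological_process
is_a: GO:0000001 ! root

[Term]
id: GO:0000003
name: B
namespace: biological_process
alt_id: GO:0000099
is_a: GO:0000002 ! A
"""

    def test_chain_parsed(self, tmp_path):
        dag = load_obo(self._write(tmp_path, self.CHAIN))
        assert len(dag.terms) == 3
        assert dag.parents["GO:0000003"] == {"GO:0000002"}
        assert sum(len(p) for p in dag.parents.values()) == 2

    def test_alt_id_resolves_to_primary(self, tmp_path):
        dag = load_obo(self._write(tmp_path, self.CHAIN))
        assert dag.resolve("GO:0000099") == "GO:0000003"

    def test_obsolete_terms_skipped(self, tmp_path):
        text = self.CHAIN + (
            "\n[Term]\nid: GO:0000004\nname: gone\n"
            "namespace: biological_process\nis_obsolete: true\n"
        )
        dag = load_obo(self._write(tmp_path, text))
        assert "GO:0000004" not in dag.terms

    def test_simulated_dag_round_trips(self, tmp_path):
        from symbioscan.io import write_obo
        from symbioscan.simulate import simulate_go_universe

        dag, _ = simulate_go_universe(30, max_depth=4, seed=12)
        path = tmp_path / "sim.obo"
        write_obo(dag, path)
        back = load_obo(path)
        assert back.terms == dag.terms
        assert {t: set(p) for t, p in back.parents.items()} == {
            t: set(p) for t, p in dag.parents.items()
        }

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            GoDag(
                terms={
                    "GO:1": ("a", "biological_process"),
                    "GO:2": ("b", "biological_process"),
                },
                parents={"GO:1": {"GO:2"}, "GO:2": {"GO:1"}},
            )


class TestPropagation:
    def test_root_only(self, chain_dag):
        amap = propagate_annotations({"g1": {"GO:0000001"}}, chain_dag)
        assert amap.propagated["g1"] == {"GO:0000001"}

    def test_leaf_closes_over_chain(self, chain_dag):
        amap = propagate_annotations({"g1": {"GO:0000003"}}, chain_dag)
        assert amap.propagated["g1"] == {"GO:0000001", "GO:0000002", "GO:0000003"}

    def test_diamond_closure(self, diamond_dag):
        amap = propagate_annotations({"g1": {"GO:0000004"}}, diamond_dag)
        assert amap.propagated["g1"] == {
            "GO:0000001",
            "GO:0000002",
            "GO:0000003",
            "GO:0000004",
        }

    def test_idempotent(self, diamond_dag):
        amap = propagate_annotations({"g1": {"GO:0000004"}}, diamond_dag)
        again = propagate_annotations(amap.propagated, diamond_dag)
        assert again.propagated == amap.propagated

    def test_unknown_terms_listed(self, chain_dag):
        with pytest.raises(ValueError, match="GO:9999999"):
            propagate_annotations({"g1": {"GO:9999999"}}, chain_dag)


class TestFisherTail:
    def test_full_study_probability_one(self):
        assert fisher_tail(5, 10, 5, 10) == pytest.approx(1.0)

    def test_exact_value(self):
        # P(X >= 4) drawing 5 from 20 with 5 successes = 76/15504
        assert fisher_tail(4, 5, 5, 20) == pytest.approx(76 / 15504, rel=1e-12)

    def test_zero_count_probability_one(self):
        assert fisher_tail(0, 5, 5, 20) == pytest.approx(1.0)

    def test_impossible_counts_rejected(self):
        with pytest.raises(ValueError, match="impossible"):
            fisher_tail(6, 5, 5, 20)

    def test_matches_log_factorial_oracle_sample(self):
        def oracle(k, n, K, N):
            def logc(a, b):
                return (
                    math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)
                )

            total = 0.0
            for j in range(k, min(n, K) + 1):
                if n - j > N - K:
                    continue
                total += math.exp(logc(K, j) + logc(N - K, n - j) - logc(N, n))
            return total

        for args in [(2, 6, 8, 25), (1, 3, 3, 9), (5, 12, 9, 28), (0, 4, 10, 30)]:
            assert fisher_tail(*args) == pytest.approx(oracle(*args), rel=1e-10)


class TestRunEnrichment:
    def _planted(self, chain_dag):
        # universe of 100 genes: 20 on leaf B (implies A, root),
        # 30 on A directly, 50 on root only
        direct = {}
        for i in range(20):
            direct[f"b{i}"] = {"GO:0000003"}
        for i in range(30):
            direct[f"a{i}"] = {"GO:0000002"}
        for i in range(50):
            direct[f"r{i}"] = {"GO:0000001"}
        amap = propagate_annotations(direct, chain_dag)
        universe = set(direct)
        study = {f"b{i}" for i in range(20)} | {f"r{i}" for i in range(5)}
        return study, universe, amap

    def test_elim_no_op_when_nothing_significant(self, chain_dag):
        direct = {f"g{i}": {"GO:0000003" if i % 2 else "GO:0000002"} for i in range(10)}
        amap = propagate_annotations(direct, chain_dag)
        universe = set(direct)
        study = {"g0", "g1"}
        records = run_enrichment(study, universe, amap, chain_dag, method="elim",
                                 elim_alpha=1e-9)
        for r in records:
            assert r.p_elim == pytest.approx(r.p_classic)

    def test_planted_leaf_decorrelates_parent(self, chain_dag):
        study, universe, amap = self._planted(chain_dag)
        records = {
            r.term_id: r
            for r in run_enrichment(study, universe, amap, chain_dag, method="elim")
        }
        leaf, parent = records["GO:0000003"], records["GO:0000002"]
        assert leaf.p_classic < 0.05 and leaf.p_elim < 0.05
        assert parent.p_classic < 0.05  # inherits the leaf signal
        assert parent.p_elim > 0.05  # elim strips it

    def test_classic_counts_recorded(self, chain_dag):
        study, universe, amap = self._planted(chain_dag)
        records = {
            r.term_id: r
            for r in run_enrichment(study, universe, amap, chain_dag, method="classic")
        }
        leaf = records["GO:0000003"]
        assert (leaf.study_count, leaf.study_total) == (20, 25)
        assert (leaf.universe_count, leaf.universe_total) == (20, 100)

    def test_empty_study_rejected(self, chain_dag):
        amap = propagate_annotations({"g1": {"GO:0000001"}}, chain_dag)
        with pytest.raises(ValueError, match="empty study"):
            run_enrichment(set(), {"g1"}, amap, chain_dag)

    def test_study_outside_universe_rejected(self, chain_dag):
        amap = propagate_annotations({"g1": {"GO:0000001"}}, chain_dag)
        with pytest.raises(ValueError, match="outside universe"):
            run_enrichment({"g2"}, {"g1"}, amap, chain_dag)

    def test_unannotated_genes_dropped_from_totals(self, chain_dag):
        direct = {f"g{i}": {"GO:0000002"} for i in range(5)}
        amap = propagate_annotations(direct, chain_dag)
        universe = set(direct) | {"naked1", "naked2"}
        records = run_enrichment({"g0", "naked1"}, universe, amap, chain_dag)
        assert records[0].universe_total == 5
        assert records[0].study_total == 1


class TestSignificantTerms:
    def test_strict_threshold(self, chain_dag):
        from symbioscan.enrichment import EnrichmentRecord

        records = [
            EnrichmentRecord("GO:0000002", "A", 1, 2, 3, 4, 0.05, 0.05),
            EnrichmentRecord("GO:0000003", "B", 1, 2, 3, 4, 0.01, 0.01),
        ]
        assert significant_terms(records, alpha=0.05) == ["GO:0000003"]

    def test_empty_records(self):
        assert significant_terms([]) == []
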