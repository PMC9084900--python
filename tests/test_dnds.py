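"""Sliding-window Ka/Ks machinery: estimator, windows, assignment, quantiles."""

import pytest

from symbioscan import dnds
from symbioscan.dnds import (
    GeneInterval,
    GeneScore,
    PartitionSpec,
    Window,
    assign_genes_to_windows,
    calibrate_divergence_time,
    gene_level_dnds,
    make_windows,
    ng86_pair,
    partition_quantiles,
    scan_alignment,
)


class TestNG86:
    def test_identical_sequences(self):
        est = ng86_pair("ATGAAA", "ATGAAA")
        assert est.ka == 0.0 and est.ks == 0.0
        assert est.ratio is None  # 0/0 cannot be ranked

    def test_single_synonymous_difference_saturates_jc(self):
        # TTT->TTC is synonymous (Phe); S = 1/3 (TTT) + 1 (GGG) = 4/3,
        # ps = 1/(4/3) = 0.75 puts the JC correction exactly at its pole.
        est = ng86_pair("TTTGGG", "TTCGGG")
        assert est.sd == pytest.approx(1.0)
        assert est.nd == pytest.approx(0.0)
        assert est.s_sites == pytest.approx(4 / 3)
        assert est.n_sites == pytest.approx(6 - 4 / 3)
        assert est.ka == 0.0
        assert est.ks is None
        assert est.ratio is None

    def test_two_position_difference_averages_pathways(self):
        # TTT (Phe) vs GTA (Val) differ at positions 1 and 3; both orders
        # visit a Val or Leu intermediate, never a stop:
        #   TTT->GTT(V)->GTA(V): nonsyn then syn
        #   TTT->TTA(L)->GTA(V): nonsyn then nonsyn
        # average sd = 0.5, nd = 1.5; pad with an invariant codon.
        est = ng86_pair("TTTGGG", "GTAGGG")
        assert est.sd == pytest.approx(0.5)
        assert est.nd == pytest.approx(1.5)

    def test_symmetric_in_sequences(self):
        a, b = "ATGCGTTTAGAACAT", "ATGAGAGTAGAGCAC"
        e1, e2 = ng86_pair(a, b), ng86_pair(b, a)
        assert e1.sd == pytest.approx(e2.sd)
        assert e1.nd == pytest.approx(e2.nd)
        assert e1.s_sites == pytest.approx(e2.s_sites)

    def test_sites_sum_to_window_length(self):
        est = ng86_pair("ATGCGTTTAGAACAT", "ATGAGAGTAGAGCAC")
        assert est.s_sites + est.n_sites == pytest.approx(15.0)

    def test_ambiguous_codons_excluded(self):
        full = ng86_pair("ATGAAA", "ATGAAG")
        with_n = ng86_pair("ATGAAANNN", "ATGAAGAAA")
        assert with_n.sd == pytest.approx(full.sd)
        assert with_n.s_sites == pytest.approx(full.s_sites)

    @pytest.mark.parametrize(
        "a,b,message",
        [
            ("ATG", "ATGAAA", "length mismatch"),
            ("ATGA", "ATGC", "not divisible by 3"),
            ("ATGTAAAAA", "ATGAAAAAA", "codon 1"),
        ],
    )
    def test_input_errors(self, a, b, message):
        with pytest.raises(ValueError, match=message):
            ng86_pair(a, b)


class TestWindows:
    def test_single_full_window(self):
        assert make_windows(1200) == [Window(0, 1200)]

    def test_overlapping_windows_enumeration(self):
        assert make_windows(3000) == [
            Window(0, 1200),
            Window(600, 1800),
            Window(1200, 2400),
            Window(1800, 3000),
        ]

    def test_tail_window_kept_above_min_tail(self):
        assert make_windows(1500) == [Window(0, 1200), Window(600, 1500)]

    def test_too_short_alignment_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no windows"):
            assert make_windows(150) == []

    def test_frame_violation_rejected(self):
        with pytest.raises(ValueError, match="not divisible by 3"):
            make_windows(1000)


class TestGeneAssignment:
    WINDOWS = [Window(0, 1200), Window(600, 1800)]

    def test_overlap_at_least_threshold_assigns(self):
        genes = [GeneInterval("g1", 300, 900)]
        assert assign_genes_to_windows([Window(0, 1200)], genes) == {
            "g1": [Window(0, 1200)]
        }

    def test_overlap_just_below_threshold_skipped(self):
        genes = [GeneInterval("g1", 901, 1200)]
        assert assign_genes_to_windows([Window(0, 1200)], genes) == {}

    def test_gene_split_across_windows(self):
        genes = [GeneInterval("g1", 1100, 1700)]
        assert assign_genes_to_windows(self.WINDOWS, genes) == {
            "g1": [Window(600, 1800)]
        }


class TestGeneScores:
    def _estimates(self, ratios):
        out = []
        for i, r in enumerate(ratios):
            w = Window(i * 600, i * 600 + 1200)
            out.append(
                dnds.WindowEstimate(
                    window=w, ka=r, ks=1.0, ratio=r, s_sites=300, n_sites=900, sd=1, nd=1
                )
            )
        return out

    def test_mean_over_assigned_windows(self):
        ests = self._estimates([0.1, 0.3])
        assignments = {"g1": [e.window for e in ests]}
        scores = gene_level_dnds(assignments, ests)
        assert scores[0].dnds == pytest.approx(0.2)
        assert scores[0].n_windows == 2

    def test_gene_with_only_filtered_windows_dropped(self):
        ests = self._estimates([0.1])
        assignments = {"g1": [Window(6000, 7200)]}  # not among estimates
        assert gene_level_dnds(assignments, ests) == []


class TestPartition:
    def _scores(self, values):
        return [GeneScore(f"g{i:02d}", v, 1) for i, v in enumerate(values)]

    def test_ceiling_sizes_and_membership(self):
        scores = self._scores([round(0.01 * (i + 1), 2) for i in range(10)])
        parts = partition_quantiles(scores, PartitionSpec())
        assert parts["top10"] == {"g09"}
        assert parts["bottom25"] == {"g00", "g01", "g02"}
        assert parts["top10"] <= parts["top25"]
        assert parts["bottom10"] <= parts["bottom25"]

    def test_ties_broken_by_gene_id(self):
        scores = self._scores([0.1] * 8)
        parts = partition_quantiles(scores, PartitionSpec())
        assert parts["top10"] == {"g00"}  # ceil(0.8) = 1, id ascending wins
        assert len(parts["top25"]) == 2

    def test_minimum_four_genes(self):
        scores = self._scores([0.1, 0.2, 0.3, 0.4])
        parts = partition_quantiles(scores, PartitionSpec())
        assert len(parts["top10"]) == 1  # ceil(0.4)
        with pytest.raises(ValueError, match="at least 4"):
            partition_quantiles(scores[:3], PartitionSpec())

    def test_raising_a_gene_never_demotes_it(self):
        values = [0.01, 0.05, 0.08, 0.12, 0.2, 0.3, 0.35, 0.5]
        base = partition_quantiles(self._scores(values), PartitionSpec())
        assert "g01" in base["bottom25"]
        bumped = list(values)
        bumped[1] = 0.4  # raise g01 to second largest
        after = partition_quantiles(self._scores(bumped), PartitionSpec())
        assert "g01" in after["top25"]
        assert "g01" not in after["bottom25"] and "g01" not in after["bottom10"]


class TestScan:
    def test_moderate_divergence_keeps_all_windows(self):
        from symbioscan.simulate import simulate_codon_pair

        aln = simulate_codon_pair(1000, 0.1, 0.4, seed=11)  # 3000 bp
        scan = scan_alignment(aln, PartitionSpec(ks_cutoff=2.0))
        assert len(scan.raw) == 4
        assert len(scan.usable) == 4

    def test_saturated_alignment_fully_filtered(self):
        from symbioscan.simulate import simulate_codon_pair

        with pytest.warns(UserWarning, match="saturation"):
            aln = simulate_codon_pair(1000, 0.05, 3.0, seed=3)
        scan = scan_alignment(aln, PartitionSpec(ks_cutoff=2.0))
        assert len(scan.raw) == 4
        assert scan.usable == []

    def test_exact_window_alignment_single_estimate(self):
        from symbioscan.simulate import simulate_codon_pair

        aln = simulate_codon_pair(400, 0.1, 0.3, seed=5)  # 1200 bp
        scan = scan_alignment(aln, PartitionSpec())
        assert len(scan.raw) == 1


class TestClockCalibration:
    def test_calibration_identity(self):
        assert calibrate_divergence_time(2.8) == pytest.approx(216.0)

    def test_clade_divergence_estimate(self):
        assert round(calibrate_divergence_time(3.934)) == 303

    def test_linear_in_divergence(self):
        assert calibrate_divergence_time(4.211) == pytest.approx(324.849, abs=0.01)
        assert calibrate_divergence_time(0.0) == 0.0
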