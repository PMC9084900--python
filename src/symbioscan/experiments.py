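"""Planted-truth recovery experiments on synthetic data.

Each experiment wires generators to the corresponding analysis stage and
scores the result against the generator's truth table: dN/dS recovery,
quantile/enrichment recovery of planted rate categories, contig-triage
precision/recall against emulated two-step hit evidence, host-association
ranking, and the false-discovery rate on null community matrices.

These drive both the analysis scripts and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .association import association_screen
from .dnds import PartitionSpec, ng86_pair
from .enrichment import GoDag, propagate_annotations, run_enrichment, significant_terms
from .simulate import (
    PanelCategory,
    SimPanelSpec,
    concatenate_panel,
    simulate_codon_pair,
    simulate_community_matrix,
    simulate_contig_set,
    simulate_ortholog_panel,
)
from .transitions import PairBundle
from .triage import HitRecord, classify_best_hit, triage_contigs


def dnds_recovery(
    target_dnds: float,
    target_ks: float = 0.4,
    codons: int = 2000,
    n_seeds: int = 50,
    seed: int = 0,
) -> dict[str, float]:
    """Mean estimate and mean absolute error of NG86 against a planted ratio."""
    rng = np.random.default_rng(seed)
    estimates = []
    for _ in range(n_seeds):
        child = int(rng.integers(0, 2**31 - 1))
        aln = simulate_codon_pair(codons, target_dnds, target_ks, seed=child)
        est = ng86_pair(aln.seq_a, aln.seq_b)
        estimates.append(est.ratio)
    estimates = np.asarray(estimates, dtype=float)
    return {
        "target": target_dnds,
        "mean_estimate": float(estimates.mean()),
        "mae": float(np.abs(estimates - target_dnds).mean()),
        "bias": float(estimates.mean() - target_dnds),
        "n_seeds": n_seeds,
    }


#: GO term ids used by the planted enrichment design.
TERM_ROOT = "GO:0000001"
TERM_LOW = "GO:0000002"
TERM_MID = "GO:0000003"
TERM_HIGH = "GO:0000004"
TERM_RANDOM = "GO:0000005"


def _flat_dag() -> GoDag:
    terms = {
        TERM_ROOT: ("root", "biological_process"),
        TERM_LOW: ("planted low-dN/dS process", "biological_process"),
        TERM_MID: ("background process", "biological_process"),
        TERM_HIGH: ("planted high-dN/dS process", "biological_process"),
        TERM_RANDOM: ("unrelated process", "biological_process"),
    }
    parents = {t: ({TERM_ROOT} if t != TERM_ROOT else set()) for t in terms}
    return GoDag(terms=terms, parents=parents)


@dataclass
class PartitionEnrichmentResult:
    high_sensitivity: float
    low_sensitivity: float
    high_term_recovered: bool
    low_term_recovered: bool
    random_term_flagged: bool


def partition_enrichment_trial(
    seed: int,
    n_genes: int = 100,
    codons_per_gene: int = 1000,
    low_dnds: float = 0.02,
    high_dnds: float = 0.5,
    target_ks: float = 0.4,
) -> PartitionEnrichmentResult:
    """One planted-category recovery trial.

    Panel design: 20% of genes in a low-dN/dS category, 60% in a mid
    background, 20% in a high category (the flank categories must each fit
    inside a 25% quantile set for full sensitivity to be attainable). A
    decoy term is annotated to a size-matched random gene subset; it should
    not come out enriched.
    """
    categories = [
        PanelCategory("low", frozenset({TERM_LOW}), low_dnds, target_ks, weight=1),
        PanelCategory("mid", frozenset({TERM_MID}), 0.1, target_ks, weight=3),
        PanelCategory("high", frozenset({TERM_HIGH}), high_dnds, target_ks, weight=1),
    ]
    spec = SimPanelSpec(
        n_genes=n_genes, codons_per_gene=codons_per_gene, categories=categories, seed=seed
    )
    panel = simulate_ortholog_panel(spec)
    rng = np.random.default_rng(seed + 1)
    gene_ids = sorted(panel.alignments)
    decoy_genes = set(rng.choice(gene_ids, size=len(gene_ids) // 5, replace=False))
    direct = {g: set(terms) for g, terms in panel.annotations.items()}
    for g in decoy_genes:
        direct[g].add(TERM_RANDOM)
    dag = _flat_dag()
    amap = propagate_annotations(direct, dag)

    alignment, genes = concatenate_panel(panel, shuffle_seed=seed + 2)
    bundle = PairBundle(alignment=alignment, genes=genes, ks_cutoff=2.0)
    from .dnds import assign_genes_to_windows, gene_level_dnds, partition_quantiles, scan_alignment

    pspec = PartitionSpec(ks_cutoff=bundle.ks_cutoff)
    scan = scan_alignment(alignment, pspec)
    assignment = assign_genes_to_windows([e.window for e in scan.raw], genes)
    scores = gene_level_dnds(assignment, scan.usable)
    partitions = partition_quantiles(scores, pspec)
    universe = {s.gene_id for s in scores}

    high_genes = {g for g, c in panel.category_of.items() if c == "high"} & universe
    low_genes = {g for g, c in panel.category_of.items() if c == "low"} & universe
    high_sens = len(high_genes & partitions["top25"]) / len(high_genes)
    low_sens = len(low_genes & partitions["bottom25"]) / len(low_genes)

    def enriched(study):
        records = run_enrichment(study, universe, amap, dag, method="elim")
        return set(significant_terms(records, alpha=0.05, field="p_elim"))

    top = enriched(partitions["top25"])
    bottom = enriched(partitions["bottom25"])
    return PartitionEnrichmentResult(
        high_sensitivity=high_sens,
        low_sensitivity=low_sens,
        high_term_recovered=TERM_HIGH in top,
        low_term_recovered=TERM_LOW in bottom,
        random_term_flagged=TERM_RANDOM in top or TERM_RANDOM in bottom,
    )


def triage_recovery(
    seed: int,
    n_target: int = 200,
    n_background: int = 200,
    hit_fraction: float = 0.8,
    label_error: float = 0.02,
) -> dict[str, float]:
    """Triage precision/recall against the contig truth table.

    Hit tables are emulated from the truth labels: a ``hit_fraction`` of
    contigs carries two-step evidence whose label is wrong with probability
    ``label_error``; the rest are unclassified and face only the GC and
    coverage rules.
    """
    records, truth = simulate_contig_set(n_target, n_background, seed=seed)
    rng = np.random.default_rng(seed + 1)
    hits1, hits2 = [], []
    for c in records:
        if rng.random() >= hit_fraction:
            continue
        true_label = "Wolbachia_PPN" if truth[c.contig_id] == "target" else "Nematoda"
        label = true_label
        if rng.random() < label_error:
            label = "Nematoda" if true_label == "Wolbachia_PPN" else "Wolbachia_PPN"
        hits1.append(HitRecord(c.contig_id, "custom16S", "Wolbachia_16S", 100.0, 1e-30))
        hits2.append(HitRecord(c.contig_id, "ntdb", label, 500.0, 1e-60))
    classification = classify_best_hit(hits1, hits2, {"Wolbachia_PPN", "Wolbachia_16S"})
    report = triage_contigs(records, classification=classification)
    kept = set(report.kept)
    target_ids = {cid for cid, lab in truth.items() if lab == "target"}
    tp = len(kept & target_ids)
    precision = tp / len(kept) if kept else 0.0
    recall = tp / len(target_ids) if target_ids else 0.0
    return {"precision": precision, "recall": recall, "n_kept": len(kept)}


def host_ranking_rate(
    n_seeds: int = 50,
    n_samples: int = 30,
    n_taxa: int = 20,
    corr_strength: float = 0.9,
    seed: int = 0,
) -> float:
    """Fraction of seeds in which the planted host tops the symbiont screen."""
    rng = np.random.default_rng(seed)
    host_index = 4
    wins = 0
    for _ in range(n_seeds):
        child = int(rng.integers(0, 2**31 - 1))
        m = simulate_community_matrix(
            n_samples, n_taxa, host_index, corr_strength, noise_sd=1.0, seed=child
        )
        top = association_screen(m, "symbiont_16S")[0]
        wins += f"taxon_{host_index + 1:03d}" in top.pair
    return wins / n_seeds


def fdr_null_rate(
    n_seeds: int = 200, n_samples: int = 12, n_taxa: int = 10, seed: int = 0
) -> float:
    """Mean fraction of symbiont pairs passing BH at 0.05 when all columns
    are mutually independent (should stay at or below the nominal level)."""
    rng = np.random.default_rng(seed)
    fractions = []
    for _ in range(n_seeds):
        child = int(rng.integers(0, 2**31 - 1))
        m = simulate_community_matrix(
            n_samples, n_taxa, host_index=0, corr_strength=0.0, noise_sd=1.0, seed=child
        )
        results = association_screen(m, "symbiont_16S")
        sym = [r for r in results if "symbiont_16S" in r.pair]
        fractions.append(np.mean([r.p_adj < 0.05 for r in sym]))
    return float(np.mean(fractions))
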