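#!/usr/bin/env python
"""Generate the synthetic study inputs every later stage consumes.

Writes (to scratch/simdata/, regenerable at will): a contig population with
truth labels and emulated two-step hit tables, a community abundance matrix
with one planted host, an ortholog panel as an AXT alignment block plus BED
gene intervals, a simulated GO DAG as OBO with a gene->term annotation TSV.
A small summary of what was generated lands in results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from symbioscan import io as sio
from symbioscan.experiments import TERM_HIGH, TERM_LOW, TERM_MID, _flat_dag
from symbioscan.simulate import (
    PanelCategory,
    SimPanelSpec,
    concatenate_panel,
    simulate_community_matrix,
    simulate_contig_set,
    simulate_ortholog_panel,
)

SEED = 20220425
OUT = Path(__file__).resolve().parents[1] / "scratch" / "simdata"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    # contig population: low-GC symbiont class vs high-GC background
    records, truth = simulate_contig_set(200, 200, seed=SEED)
    with open(OUT / "contigs.tsv", "w") as fh:
        fh.write("contig_id\tlength\tgc\tmean_coverage\ttruth\n")
        for c in records:
            fh.write(
                f"{c.contig_id}\t{c.length}\t{c.gc:.4f}\t{c.mean_coverage:.2f}"
                f"\t{truth[c.contig_id]}\n"
            )

    # community matrix: 30 samples, 20 COI taxa, symbiont tracking taxon_005
    matrix = simulate_community_matrix(
        30, 20, host_index=4, corr_strength=0.9, noise_sd=1.0, seed=SEED + 1
    )
    sio.write_abundance_tsv(matrix, OUT / "community_matrix.tsv")

    # ortholog panel: 20% low-dN/dS, 60% background, 20% high-dN/dS genes
    categories = [
        PanelCategory("low", frozenset({TERM_LOW}), 0.02, 0.4, weight=1),
        PanelCategory("mid", frozenset({TERM_MID}), 0.1, 0.4, weight=3),
        PanelCategory("high", frozenset({TERM_HIGH}), 0.5, 0.4, weight=1),
    ]
    spec = SimPanelSpec(n_genes=100, codons_per_gene=1000, categories=categories,
                        seed=SEED + 2)
    panel = simulate_ortholog_panel(spec)
    alignment, genes = concatenate_panel(panel, id="wA-wB", shuffle_seed=SEED + 3)
    sio.write_axt([alignment], OUT / "panel_wA_wB.axt")
    sio.write_bed({"wA-wB": genes}, OUT / "panel_wA_wB.bed")
    sio.write_annotation_tsv(
        {g: set(t) for g, t in panel.annotations.items()}, OUT / "annotations.tsv"
    )

    # GO DAG used by the enrichment stages
    sio.write_obo(_flat_dag(), OUT / "go_universe.obo")

    summary = RESULTS / "01_simulated_inputs.tsv"
    with open(summary, "w") as fh:
        fh.write("input\tdescription\tsize\n")
        fh.write(f"contigs.tsv\tcontig mixture (target+background)\t{len(records)}\n")
        fh.write(
            f"community_matrix.tsv\tsamples x taxa abundance\t"
            f"{matrix.values.shape[0]}x{matrix.values.shape[1]}\n"
        )
        fh.write(f"panel_wA_wB.axt\tortholog alignment block (bp)\t{alignment.length}\n")
        fh.write(f"panel_wA_wB.bed\tgene intervals\t{len(genes)}\n")
    print(f"wrote synthetic inputs to {OUT}")
    print(f"summary: {summary}")


if __name__ == "__main__":
    main()
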