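#!/usr/bin/env python
"""Selection-signature transitions along a 5-strain chain.

Simulates one ortholog panel per adjacent strain pair with a low-dN/dS
process planted in every pair (a universally conserved function) and a
second process planted as low only in the first pair (a clade-specific
conservation), runs the scan->partition->enrichment pipeline per pair, and
classifies enriched terms as universal, shared, or unique per branch.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from symbioscan.enrichment import GoDag, propagate_annotations
from symbioscan.simulate import (
    PanelCategory,
    SimPanelSpec,
    concatenate_panel,
    simulate_ortholog_panel,
)
from symbioscan.transitions import (
    PairBundle,
    StrainChain,
    chain_pairs,
    classify_transition_terms,
    transition_enrichment,
)

SEED = 20220425
RESULTS = Path(__file__).resolve().parents[1] / "results"

UNIVERSAL_TERM = "GO:0000002"  # low dN/dS in every pair
CLADE_TERM = "GO:0000003"  # low dN/dS only in the first pair
BACKGROUND = "GO:0000004"
HIGH_TERM = "GO:0000005"


def build_dag() -> GoDag:
    terms = {
        "GO:0000001": ("root", "biological_process"),
        UNIVERSAL_TERM: ("universally conserved process", "biological_process"),
        CLADE_TERM: ("clade-specific conserved process", "biological_process"),
        BACKGROUND: ("background process", "biological_process"),
        HIGH_TERM: ("relaxed process", "biological_process"),
    }
    parents = {t: ({"GO:0000001"} if t != "GO:0000001" else set()) for t in terms}
    return GoDag(terms=terms, parents=parents)


def pair_panel(seed: int, first_pair: bool):
    low_terms = frozenset(
        {UNIVERSAL_TERM, CLADE_TERM} if first_pair else {UNIVERSAL_TERM}
    )
    categories = [
        PanelCategory("low", low_terms, 0.02, 0.4, weight=1),
        PanelCategory("mid", frozenset({BACKGROUND}), 0.1, 0.4, weight=3),
        PanelCategory("high", frozenset({HIGH_TERM}), 0.5, 0.4, weight=1),
    ]
    spec = SimPanelSpec(n_genes=60, codons_per_gene=600, categories=categories,
                        seed=seed)
    return simulate_ortholog_panel(spec)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    dag = build_dag()
    strains = ["wTex", "wPpe", "wPni", "wFol", "wCfeT"]
    pairs = list(zip(strains, strains[1:]))
    bundles, panels = {}, {}
    for i, pair in enumerate(pairs):
        panel = pair_panel(SEED + i, first_pair=(i == 0))
        alignment, genes = concatenate_panel(panel, id="-".join(pair),
                                             shuffle_seed=SEED + 50 + i)
        # saturation cutoff 2.5 within the closely related first pair, 2.0 after
        bundles[pair] = PairBundle(alignment=alignment, genes=genes,
                                   ks_cutoff=2.5 if i == 0 else 2.0)
        panels[pair] = panel
    chain = StrainChain(strains=strains, bundles=bundles)

    per_pair_bottom10 = {}
    per_pair_all = {}
    for pair in chain_pairs(chain):
        amap = propagate_annotations(panels[pair].annotations, dag)
        enriched = transition_enrichment(bundles[pair], amap, dag)
        pair_id = "-".join(pair)
        per_pair_all[pair_id] = enriched
        per_pair_bottom10[pair_id] = enriched["bottom10"]
        named = [f"{t} ({dag.terms[t][0]})" for t in enriched["bottom10"]]
        print(f"{pair_id} bottom10 enriched: {named or 'none'}")

    labels = classify_transition_terms(per_pair_bottom10)
    out = RESULTS / "07_transitions.tsv"
    with open(out, "w") as fh:
        fh.write("class\tpair\tterm_id\tname\n")
        for pair_id, sets in per_pair_all.items():
            for cls, terms in sets.items():
                for t in terms:
                    fh.write(f"{cls}\t{pair_id}\t{t}\t{dag.terms[t][0]}\n")
        fh.write("\n# bottom10 classification\n")
        for t, lab in sorted(labels.items()):
            fh.write(f"bottom10_label\t{lab}\t{t}\t{dag.terms[t][0]}\n")

    print("\nbottom10 classification:")
    for t, lab in sorted(labels.items()):
        print(f"  {t} ({dag.terms[t][0]}): {lab}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
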