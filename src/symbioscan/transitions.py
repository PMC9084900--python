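"""Selection-signature transitions along an ordered chain of strains.

For each adjacent strain pair the pipeline composes the sliding-window
dN/dS scan with GO enrichment of the quantile gene sets, then classifies
each enriched term as unique to one pair, shared by a subset, or universal
across the chain — the comparison used to read functional change off a
series of host transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .dnds import (
    GeneInterval,
    PairAlignment,
    PartitionSpec,
    assign_genes_to_windows,
    gene_level_dnds,
    partition_quantiles,
    scan_alignment,
)
from .enrichment import AnnotationMap, GoDag, run_enrichment, significant_terms


@dataclass
class PairBundle:
    """Everything needed to score one adjacent strain pair."""

    alignment: PairAlignment
    genes: list[GeneInterval]
    ks_cutoff: float = 2.0


@dataclass
class StrainChain:
    """Ordered strains with one alignment bundle per adjacent pair."""

    strains: list[str]
    bundles: dict[tuple[str, str], PairBundle]

    def __post_init__(self):
        if len(self.strains) < 2:
            raise ValueError("a chain needs at least 2 strains")
        for pair in chain_pairs(self):
            if pair not in self.bundles:
                raise ValueError(f"missing alignment bundle for pair {pair}")


def chain_pairs(chain: StrainChain) -> list[tuple[str, str]]:
    """The n-1 adjacent pairs of an n-strain chain, in chain order."""
    if len(chain.strains) < 2:
        raise ValueError("a chain needs at least 2 strains")
    return list(zip(chain.strains, chain.strains[1:]))


def transition_enrichment(
    bundle: PairBundle,
    annotations: AnnotationMap,
    dag: GoDag,
    spec: PartitionSpec | None = None,
    alpha: float = 0.05,
    min_overlap: int = 300,
    window: int = 1200,
    step: int = 600,
) -> dict[str, list[str]]:
    """Significantly enriched terms per quantile class for one strain pair.

    Scans the pair's alignment, scores genes, partitions them into quantile
    sets, and tests each set (study) against all scored genes (universe)
    with the elim method at the given alpha.
    """
    spec = spec or PartitionSpec()
    spec = PartitionSpec(fractions=spec.fractions, ks_cutoff=bundle.ks_cutoff)
    scan = scan_alignment(bundle.alignment, spec, window=window, step=step)
    windows = [e.window for e in scan.raw]
    assignment = assign_genes_to_windows(windows, bundle.genes, min_overlap=min_overlap)
    scores = gene_level_dnds(assignment, scan.usable)
    partitions = partition_quantiles(scores, spec)
    universe = {s.gene_id for s in scores}
    enriched: dict[str, list[str]] = {}
    for cls, study in partitions.items():
        records = run_enrichment(study, universe, annotations, dag, method="elim")
        enriched[cls] = significant_terms(records, alpha=alpha, field="p_elim")
    return enriched


def classify_transition_terms(
    per_pair_sets: Mapping[str, Iterable[str]]
) -> dict[str, str]:
    """Label each term by its presence pattern across pairs.

    "universal" if present in every pair's set, "unique:<pair>" if in
    exactly one, otherwise "shared:<pair,pair,...>" (pairs sorted).
    """
    if len(per_pair_sets) < 2:
        raise ValueError("need at least 2 pairs to classify")
    sets = {pid: set(terms) for pid, terms in per_pair_sets.items()}
    all_terms = set().union(*sets.values()) if sets else set()
    labels: dict[str, str] = {}
    for term in all_terms:
        where = sorted(pid for pid, s in sets.items() if term in s)
        if len(where) == len(sets):
            labels[term] = "universal"
        elif len(where) == 1:
            labels[term] = f"unique:{where[0]}"
        else:
            labels[term] = "shared:" + ",".join(where)
    return labels


@dataclass
class TransitionReport:
    """Per-pair enriched term sets and per-class term classifications."""

    per_pair: dict[str, dict[str, list[str]]]
    classified: dict[str, dict[str, str]] = field(default_factory=dict)


def run_chain(
    chain: StrainChain,
    annotations: AnnotationMap,
    dag: GoDag,
    spec: PartitionSpec | None = None,
    alpha: float = 0.05,
) -> TransitionReport:
    """Enrichment for every adjacent pair plus classification per class."""
    per_pair: dict[str, dict[str, list[str]]] = {}
    for a, b in chain_pairs(chain):
        pair_id = f"{a}-{b}"
        per_pair[pair_id] = transition_enrichment(
            chain.bundles[(a, b)], annotations, dag, spec=spec, alpha=alpha
        )
    classes = sorted({cls for sets in per_pair.values() for cls in sets})
    classified = {
        cls: classify_transition_terms(
            {pid: sets.get(cls, []) for pid, sets in per_pair.items()}
        )
        for cls in classes
    }
    return TransitionReport(per_pair=per_pair, classified=classified)
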