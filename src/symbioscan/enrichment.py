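"""GO-DAG gene-set enrichment.

Loads an OBO ontology into an is_a DAG, propagates gene annotations to
ancestors (true-path rule), and tests a study set against a universe per
term with the hypergeometric upper tail, either directly ("classic") or
with the elim decorrelation, which removes genes of significantly enriched
child terms from their ancestors' tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import obonet
from scipy import stats


@dataclass
class GoDag:
    """Ontology terms linked by is_a edges (child -> parents), acyclic,
    rooted once per namespace."""

    terms: dict[str, tuple[str, str]]
    parents: dict[str, set[str]]
    alt_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise ValueError(f"term {child} has unknown parent {p}")
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"cycle in is_a graph: {cycle}")
        self._graph = g
        self.roots = {
            ns: [t for t in self.terms if self.terms[t][1] == ns and not self.parents.get(t)]
            for ns in {v[1] for v in self.terms.values()}
        }
        for ns, roots in self.roots.items():
            for t, (name, tns) in self.terms.items():
                if tns == ns and not any(
                    r in self.ancestors(t) for r in roots
                ):
                    raise ValueError(f"term {t} does not reach a root of namespace {ns}")

    def resolve(self, term_id: str) -> str:
        """Map an alt_id to its primary id (identity for primary ids)."""
        return self.alt_ids.get(term_id, term_id)

    def ancestors(self, term_id: str) -> set[str]:
        """Ancestors of a term including the term itself."""
        return {term_id} | nx.descendants(self._graph, term_id)

    def depth(self, term_id: str) -> int:
        """Longest is_a path length from the term up to a root."""
        return self._depth(term_id)

    def _depth(self, term_id: str) -> int:
        cache = getattr(self, "_depth_cache", None)
        if cache is None:
            cache = self._depth_cache = {}
        if term_id in cache:
            return cache[term_id]
        ps = self.parents.get(term_id) or set()
        d = 0 if not ps else 1 + max(self._depth(p) for p in ps)
        cache[term_id] = d
        return d


def load_obo(path) -> GoDag:
    """Parse an OBO 1.2 file into a GoDag.

    Obsolete terms are skipped; alt_ids map to their primary term; only
    is_a relations are kept. Missing namespaces and cycles are errors.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, set[str]] = {}
    alt_ids: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        namespace = data.get("namespace")
        if namespace is None:
            raise ValueError(f"term {node} has no namespace")
        terms[node] = (data.get("name", node), namespace)
        parents[node] = set(data.get("is_a", []))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = node
    for child, ps in parents.items():
        unknown = ps - set(terms)
        if unknown:
            raise ValueError(f"term {child} has is_a parents not in file: {sorted(unknown)}")
    return GoDag(terms=terms, parents=parents, alt_ids=alt_ids)


@dataclass
class AnnotationMap:
    """Direct gene->terms mapping plus its ancestral closure."""

    direct: dict[str, set[str]]
    propagated: dict[str, set[str]]


def propagate_annotations(direct: Mapping[str, Iterable[str]], dag: GoDag) -> AnnotationMap:
    """Close each gene's annotation set under is_a ancestry (true-path rule)."""
    unknown = sorted(
        {t for ts in direct.values() for t in ts if dag.resolve(t) not in dag.terms}
    )
    if unknown:
        raise ValueError(f"unknown term ids in annotations: {unknown}")
    prop: dict[str, set[str]] = {}
    clean: dict[str, set[str]] = {}
    for gene, ts in direct.items():
        resolved = {dag.resolve(t) for t in ts}
        clean[gene] = resolved
        closed: set[str] = set()
        for t in resolved:
            closed |= dag.ancestors(t)
        prop[gene] = closed
    return AnnotationMap(direct=clean, propagated=prop)


def fisher_tail(
    study_count: int, study_total: int, universe_count: int, universe_total: int
) -> float:
    """Hypergeometric upper tail P(X >= study_count) for a 2x2 table:
    drawing study_total genes from universe_total of which universe_count
    carry the term."""
    k, n, K, N = study_count, study_total, universe_count, universe_total
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K and n - k <= N - K):
        raise ValueError(
            f"impossible counts: study {k}/{n}, universe {K}/{N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class EnrichmentRecord:
    term_id: str
    name: str
    study_count: int
    study_total: int
    universe_count: int
    universe_total: int
    p_classic: float
    p_elim: float


def run_enrichment(
    study: set[str],
    universe: set[str],
    annotations: AnnotationMap,
    dag: GoDag,
    method: str = "classic",
    elim_alpha: float = 0.01,
) -> list[EnrichmentRecord]:
    """Per-term enrichment of ``study`` against ``universe``.

    Genes without any propagated annotation are dropped from both totals
    (only "feasible" genes form the sampling frame). The classic p-value is
    always reported; with method="elim", terms are processed children-first
    (decreasing DAG depth) and whenever a term's current p falls below
    ``elim_alpha`` its study genes are removed from all ancestors' gene
    sets before those are tested. Terms annotating no universe gene are
    skipped.
    """
    if method not in {"classic", "elim"}:
        raise ValueError(f"unknown method {method!r}")
    if not study:
        raise ValueError("empty study set")
    extra = study - universe
    if extra:
        raise ValueError(f"study genes outside universe: {sorted(extra)[:5]}")
    feasible = {g for g in universe if annotations.propagated.get(g)}
    study_f = study & feasible
    term_genes: dict[str, set[str]] = {}
    for gene in feasible:
        for t in annotations.propagated[gene]:
            term_genes.setdefault(t, set()).add(gene)
    study_total = len(study_f)
    universe_total = len(feasible)

    order = sorted(term_genes, key=lambda t: (-dag.depth(t), t))
    removed: dict[str, set[str]] = {}
    records: dict[str, EnrichmentRecord] = {}
    for t in order:
        genes_t = term_genes[t]
        p_classic = fisher_tail(
            len(study_f & genes_t), study_total, len(genes_t), universe_total
        )
        if method == "elim":
            current = genes_t - removed.get(t, set())
            p_elim = fisher_tail(
                len(study_f & current), study_total, len(current), universe_total
            ) if current else 1.0
            if p_elim < elim_alpha:
                eliminated = study_f & current
                for anc in dag.ancestors(t) - {t}:
                    removed.setdefault(anc, set()).update(eliminated)
        else:
            p_elim = p_classic
        records[t] = EnrichmentRecord(
            term_id=t,
            name=dag.terms[t][0],
            study_count=len(study_f & genes_t),
            study_total=study_total,
            universe_count=len(genes_t),
            universe_total=universe_total,
            p_classic=p_classic,
            p_elim=p_elim,
        )
    return [records[t] for t in sorted(records)]


def significant_terms(
    records: Iterable[EnrichmentRecord], alpha: float = 0.05, field: str = "p_elim"
) -> list[str]:
    """Term ids with the chosen p strictly below alpha, ordered by p then id."""
    if field not in {"p_classic", "p_elim"}:
        raise ValueError(f"unknown p-value field {field!r}")
    hits = [(getattr(r, field), r.term_id) for r in records if getattr(r, field) < alpha]
    return [t for _, t in sorted(hits)]
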