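"""Synthetic inputs with the statistical structure the downstream analyses assume.

Generators for: pairwise codon alignments with planted synonymous divergence
and dN/dS; ortholog panels with per-category GO labels; small rooted GO DAGs;
sample-by-taxon community abundance matrices with one planted host-symbiont
association; and contig populations with distinct GC/coverage distributions.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import AbundanceMatrix
from .dnds import (
    NUCLEOTIDES,
    DEFAULT_CODE_TABLE,
    PairAlignment,
    is_stop,
    synonymous_sites,
    translate_codon,
    _code,
)
from .enrichment import GoDag
from .triage import ContigRecord

# fraction of the saturation proportion (3/4) beyond which the Jukes-Cantor
# correction of the planted divergence becomes numerically unreliable
_SATURATION_WARN = 0.95


def _inverse_jukes_cantor(d: float) -> float:
    """Expected proportion of differing sites for a JC distance d."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def _sense_codons(code_table: int) -> list[str]:
    forward, _ = _code(code_table)
    return sorted(forward)


def simulate_codon_pair(
    codons: int,
    target_dnds: float,
    target_ks: float,
    seed: int,
    code_table: int = DEFAULT_CODE_TABLE,
    id: str = "pair",
) -> PairAlignment:
    """Pair of codon sequences descended from a random common ancestor.

    Differences are planted per NG86 site class: the number of synonymous
    (nonsynonymous) single-nucleotide differences is Poisson with mean equal
    to the inverse-Jukes-Cantor proportion of the target divergence times the
    ancestor's synonymous (nonsynonymous) site count, each difference placed
    at a not-yet-mutated position so the planted class counts are what the
    estimator observes. No stop codons are ever introduced.
    """
    if codons < 1:
        raise ValueError("codons must be >= 1")
    if target_dnds < 0 or target_ks < 0:
        raise ValueError("target_dnds and target_ks must be nonnegative")
    rng = np.random.default_rng(seed)
    sense = _sense_codons(code_table)
    ancestor = [sense[i] for i in rng.integers(0, len(sense), size=codons)]
    target_ka = target_dnds * target_ks
    p_syn = _inverse_jukes_cantor(target_ks)
    p_non = _inverse_jukes_cantor(target_ka)
    if max(p_syn, p_non) > 0.75 * _SATURATION_WARN:
        warnings.warn(
            "planted divergence is near Jukes-Cantor saturation; "
            "estimates may be undefined in short windows",
            stacklevel=2,
        )
    s_sites = sum(synonymous_sites(c, code_table) for c in ancestor)
    n_sites = 3.0 * codons - s_sites
    n_syn = int(rng.poisson(p_syn * s_sites))
    n_non = int(rng.poisson(p_non * n_sites))

    derived = list(ancestor)
    touched: set[int] = set()

    def place(count: int, synonymous: bool) -> None:
        placed = 0
        attempts = 0
        max_attempts = 200 * 3 * codons
        while placed < count and attempts < max_attempts:
            attempts += 1
            flat = int(rng.integers(0, 3 * codons))
            if flat in touched:
                continue
            ci, pos = divmod(flat, 3)
            codon = derived[ci]
            aa = translate_codon(codon, code_table)
            options = []
            for nt in NUCLEOTIDES:
                if nt == codon[pos]:
                    continue
                alt = codon[:pos] + nt + codon[pos + 1 :]
                if is_stop(alt, code_table):
                    continue
                same = translate_codon(alt, code_table) == aa
                if same == synonymous:
                    options.append(alt)
            if not options:
                continue
            derived[ci] = options[int(rng.integers(0, len(options)))]
            touched.add(flat)
            placed += 1
        if placed < count:
            warnings.warn(
                f"could only place {placed}/{count} "
                f"{'synonymous' if synonymous else 'nonsynonymous'} differences",
                stacklevel=3,
            )

    place(n_syn, synonymous=True)
    place(n_non, synonymous=False)
    return PairAlignment(id=id, seq_a="".join(ancestor), seq_b="".join(derived))


@dataclass(frozen=True)
class PanelCategory:
    label: str
    go_terms: frozenset
    target_dnds: float
    target_ks: float
    weight: float = 1.0

    def __post_init__(self):
        if self.target_dnds < 0 or self.target_ks < 0:
            raise ValueError(f"category {self.label}: negative rate")
        if self.weight <= 0:
            raise ValueError(f"category {self.label}: weight must be positive")


@dataclass
class SimPanelSpec:
    """Blueprint for an ortholog panel: genes split across rate categories."""

    n_genes: int
    codons_per_gene: int
    categories: Sequence[PanelCategory]
    seed: int

    def __post_init__(self):
        if self.n_genes < 1 or self.codons_per_gene < 1:
            raise ValueError("n_genes and codons_per_gene must be >= 1")
        if not self.categories:
            raise ValueError("need at least one category")
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate category labels")


@dataclass
class SimulatedPanel:
    alignments: dict[str, PairAlignment]
    annotations: dict[str, frozenset]
    truth: dict[str, tuple[float, float]]
    category_of: dict[str, str]


def _allocate(n: int, weights: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n genes across category weights."""
    total = sum(weights)
    quotas = [n * w / total for w in weights]
    counts = [int(q) for q in quotas]
    remainders = sorted(
        range(len(weights)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return counts


def simulate_ortholog_panel(spec: SimPanelSpec) -> SimulatedPanel:
    """One pairwise alignment per gene; genes carry their category's GO terms.

    Genes are apportioned to categories by the category weights (equal by
    default); gene ids encode the category for readability.
    """
    rng = np.random.default_rng(spec.seed)
    alignments: dict[str, PairAlignment] = {}
    annotations: dict[str, frozenset] = {}
    truth: dict[str, tuple[float, float]] = {}
    category_of: dict[str, str] = {}
    counts = _allocate(spec.n_genes, [c.weight for c in spec.categories])
    i = 0
    for cat, count in zip(spec.categories, counts):
        for _ in range(count):
            gene_id = f"g{i:04d}_{cat.label}"
            if gene_id in alignments:
                raise ValueError(f"duplicate gene id {gene_id}")
            child_seed = int(rng.integers(0, 2**31 - 1))
            alignments[gene_id] = simulate_codon_pair(
                spec.codons_per_gene, cat.target_dnds, cat.target_ks, child_seed, id=gene_id
            )
            annotations[gene_id] = frozenset(cat.go_terms)
            truth[gene_id] = (cat.target_dnds, cat.target_ks)
            category_of[gene_id] = cat.label
            i += 1
    return SimulatedPanel(
        alignments=alignments, annotations=annotations, truth=truth, category_of=category_of
    )


def concatenate_panel(panel: SimulatedPanel, id: str = "block",
                      shuffle_seed: Optional[int] = None):
    """Join a panel's per-gene alignments into one alignment block plus the
    gene intervals locating each gene on it (the shape the window scan and
    gene assignment consume).

    Genes are laid out in id order unless ``shuffle_seed`` is given, which
    permutes them so rate categories are not contiguous blocks (adjacent
    genes share overlap windows, so block layout correlates the scores of
    same-category neighbours).
    """
    from .dnds import GeneInterval

    order = sorted(panel.alignments)
    if shuffle_seed is not None:
        order = list(np.random.default_rng(shuffle_seed).permutation(order))
    parts_a: list[str] = []
    parts_b: list[str] = []
    genes: list[GeneInterval] = []
    offset = 0
    for gene_id in order:
        aln = panel.alignments[gene_id]
        parts_a.append(aln.seq_a)
        parts_b.append(aln.seq_b)
        genes.append(
            GeneInterval(
                gene_id=gene_id,
                start=offset,
                end=offset + aln.length,
                go_terms=frozenset(panel.annotations.get(gene_id, ())),
            )
        )
        offset += aln.length
    return PairAlignment(id=id, seq_a="".join(parts_a), seq_b="".join(parts_b)), genes


def simulate_go_universe(
    n_terms: int, max_depth: int = 4, seed: int = 0
) -> tuple[GoDag, list[str]]:
    """Rooted is_a DAG of ``n_terms`` biological-process terms.

    Term 1 is the root; every later term gets one parent drawn among terms of
    depth < max_depth plus, with probability 0.3, a second parent of no
    greater depth, keeping the graph acyclic by construction. Returns the DAG
    and term ids in creation order (leaf-most last), usable as an annotation
    template.
    """
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = np.random.default_rng(seed)
    ids = [f"GO:{i + 1:07d}" for i in range(n_terms)]
    terms = {ids[0]: (f"simulated term 1", "biological_process")}
    parents: dict[str, set[str]] = {ids[0]: set()}
    depth = {ids[0]: 0}
    for i in range(1, n_terms):
        tid = ids[i]
        eligible = [t for t in ids[:i] if depth[t] < max_depth]
        if not eligible:
            eligible = [ids[0]]
        parent = eligible[int(rng.integers(0, len(eligible)))]
        chosen = {parent}
        if rng.random() < 0.3:
            extra_pool = [t for t in ids[:i] if depth[t] <= depth[parent] and t != parent]
            if extra_pool:
                chosen.add(extra_pool[int(rng.integers(0, len(extra_pool)))])
        terms[tid] = (f"simulated term {i + 1}", "biological_process")
        parents[tid] = chosen
        depth[tid] = max(depth[p] for p in chosen) + 1
    return GoDag(terms=terms, parents=parents), ids


def simulate_community_matrix(
    n_samples: int,
    n_taxa: int,
    host_index: int,
    corr_strength: float,
    noise_sd: float = 1.0,
    seed: int = 0,
    symbiont_id: str = "symbiont_16S",
) -> AbundanceMatrix:
    """Sample-by-taxon abundance matrix with one appended symbiont column.

    Taxon abundances are independent lognormals; the symbiont column is an
    affine-monotone transform of the host column's standardized values mixed
    with Gaussian noise scaled by (1 - corr_strength) * noise_sd, then
    floored at zero. corr_strength=1 with noise_sd=0 gives an exactly
    monotone symbiont-host relation; corr_strength=0 gives independence.
    """
    if not (0 <= host_index < n_taxa):
        raise ValueError("host_index out of range")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    if not (0 <= corr_strength <= 1):
        raise ValueError("corr_strength must be in [0,1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(mean=1.0, sigma=1.0, size=(n_samples, n_taxa))
    host = values[:, host_index]
    hs = host.std()
    z = (host - host.mean()) / (hs if hs > 0 else 1.0)
    noise = rng.normal(0.0, 1.0, size=n_samples)
    raw = corr_strength * z + (1.0 - corr_strength) * noise_sd * noise
    symbiont = np.maximum(0.0, 3.0 + raw)
    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    taxa = [f"taxon_{j + 1:03d}" for j in range(n_taxa)]
    df = pd.DataFrame(values, index=samples, columns=taxa)
    df[symbiont_id] = symbiont
    read_totals = pd.Series(
        rng.integers(1_000_000, 5_000_000, size=n_samples), index=samples, dtype=float
    )
    return AbundanceMatrix(values=df, read_totals=read_totals)


def simulate_contig_set(
    n_target: int,
    n_background: int,
    target_gc: tuple[float, float] = (0.33, 0.02),
    background_gc: tuple[float, float] = (0.55, 0.03),
    target_cov: tuple[float, float] = (16.0, 3.0),
    background_cov: tuple[float, float] = (60.0, 15.0),
    seed: int = 0,
) -> tuple[list[ContigRecord], dict[str, str]]:
    """Contig population mixing a symbiont-like class and a background class.

    GC is normal (clipped to [0,1]) and coverage normal (floored just above
    0) per class; lengths are log-uniform in [500, 60000] bp. Returns the
    records plus a truth table mapping contig id to "target"/"background".
    """
    if n_target < 0 or n_background < 0:
        raise ValueError("counts must be nonnegative")
    for sd in (target_gc[1], background_gc[1], target_cov[1], background_cov[1]):
        if sd < 0:
            raise ValueError("standard deviations must be nonnegative")
    rng = np.random.default_rng(seed)
    records: list[ContigRecord] = []
    truth: dict[str, str] = {}
    specs = [("target", n_target, target_gc, target_cov),
             ("background", n_background, background_gc, background_cov)]
    idx = 0
    for label, n, gc_params, cov_params in specs:
        for _ in range(n):
            idx += 1
            cid = f"contig_{idx:05d}"
            length = int(round(math.exp(rng.uniform(math.log(500), math.log(60000)))))
            gc = float(np.clip(rng.normal(*gc_params), 0.0, 1.0))
            cov = float(max(rng.normal(*cov_params), 0.01))
            records.append(
                ContigRecord(contig_id=cid, length=length, gc=gc, mean_coverage=cov)
            )
            truth[cid] = label
    return records, truth
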