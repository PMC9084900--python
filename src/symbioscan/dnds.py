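"""Pairwise sliding-window dN/dS analysis.

Implements the Nei-Gojobori (1986) counting estimator with Jukes-Cantor
multiple-hit correction on codon-preserving overlapping windows, saturation
(Ks) filtering, gene-to-window assignment by minimum overlap, per-gene
aggregation, quantile partitioning of gene scores, and a linear molecular
clock calibration for 16S rRNA divergence.

All coordinates are 0-based half-open base-pair offsets on the alignment.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"

#: NCBI translation table 11 (bacterial/archaeal/plastid). Sense-codon amino
#: acid assignments are identical to the standard table; stops are TAA/TAG/TGA.
DEFAULT_CODE_TABLE = 11


@lru_cache(maxsize=None)
def _code(table_id: int):
    table = CodonTable.unambiguous_dna_by_id[table_id]
    forward = dict(table.forward_table)
    stops = frozenset(table.stop_codons)
    return forward, stops


def translate_codon(codon: str, code_table: int = DEFAULT_CODE_TABLE) -> str:
    """Amino acid for a sense codon, ``*`` for a stop."""
    forward, stops = _code(code_table)
    if codon in stops:
        return "*"
    return forward[codon]


def is_stop(codon: str, code_table: int = DEFAULT_CODE_TABLE) -> bool:
    return codon in _code(code_table)[1]


@lru_cache(maxsize=None)
def synonymous_sites(codon: str, code_table: int = DEFAULT_CODE_TABLE) -> float:
    """NG86 synonymous site count of one codon.

    Each position contributes the fraction of its three possible single
    nucleotide changes that preserve the amino acid. Changes creating a stop
    codon count in the denominator but never as synonymous.
    """
    aa = translate_codon(codon, code_table)
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no NG86 site decomposition")
    s = 0.0
    for pos in range(3):
        for nt in NUCLEOTIDES:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if not is_stop(alt, code_table) and translate_codon(alt, code_table) == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def pathway_differences(
    codon_a: str, codon_b: str, code_table: int = DEFAULT_CODE_TABLE
) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two sense codons.

    Averages over all minimal substitution pathways with equal weights;
    pathways passing through a stop codon are excluded. If every pathway is
    blocked by stops (not observed for sense-codon pairs under table 11, but
    guarded) the average falls back to all pathways, classing stop-crossing
    steps as nonsynonymous.
    """
    diff_positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_positions:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool):
        sd = nd = 0
        current = codon_a
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if is_stop(nxt, code_table) and nxt != codon_b:
                if not allow_stops:
                    return None
                nd += 1
            elif translate_codon(current, code_table) == translate_codon(nxt, code_table):
                sd += 1
            else:
                nd += 1
            current = nxt
        return sd, nd

    orders = list(itertools.permutations(diff_positions))
    counted = [w for w in (walk(o, allow_stops=False) for o in orders) if w is not None]
    if not counted:
        counted = [walk(o, allow_stops=True) for o in orders]
    sd = sum(c[0] for c in counted) / len(counted)
    nd = sum(c[1] for c in counted) / len(counted)
    return sd, nd


def jukes_cantor(p: float) -> Optional[float]:
    """JC69 multiple-hit correction d = -(3/4) ln(1 - 4p/3); None if undefined."""
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    if p == 0:
        return 0.0
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0:
        return None
    return -0.75 * math.log(x)


@dataclass(frozen=True)
class Window:
    """Half-open interval [start, end) on an alignment, codon-aligned."""

    start: int
    end: int

    def __post_init__(self):
        if self.start % 3 or (self.end - self.start) % 3:
            raise ValueError(f"window [{self.start},{self.end}) breaks codon frame")
        if self.end <= self.start:
            raise ValueError("empty window")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class NG86Estimate:
    """Ka/Ks estimate for one sequence stretch; None marks an undefined value."""

    ka: Optional[float]
    ks: Optional[float]
    ratio: Optional[float]
    s_sites: float
    n_sites: float
    sd: float
    nd: float


@dataclass
class WindowEstimate(NG86Estimate):
    window: Window = None  # type: ignore[assignment]


@dataclass
class PairAlignment:
    """Gap-free pairwise codon alignment (gap columns dropped codon-wise)."""

    id: str
    seq_a: str
    seq_b: str

    def __post_init__(self):
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"{self.id}: aligned sequences differ in length "
                f"({len(self.seq_a)} vs {len(self.seq_b)})"
            )
        if len(self.seq_a) % 3:
            raise ValueError(f"{self.id}: length {len(self.seq_a)} not divisible by 3")

    @property
    def length(self) -> int:
        return len(self.seq_a)

    @classmethod
    def from_aligned(cls, id: str, seq_a: str, seq_b: str) -> "PairAlignment":
        """Build from aligned sequences, removing codon columns with gaps."""
        seq_a = seq_a.upper()
        seq_b = seq_b.upper()
        if len(seq_a) != len(seq_b):
            raise ValueError(f"{id}: aligned sequences differ in length")
        if len(seq_a) % 3:
            raise ValueError(f"{id}: aligned length not divisible by 3")
        kept_a, kept_b = [], []
        for i in range(0, len(seq_a), 3):
            ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            kept_a.append(ca)
            kept_b.append(cb)
        return cls(id, "".join(kept_a), "".join(kept_b))


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    start: int
    end: int
    go_terms: frozenset = frozenset()

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: bad interval [{self.start},{self.end})")


@dataclass
class GeneScore:
    gene_id: str
    dnds: float
    n_windows: int


@dataclass
class PartitionSpec:
    """Quantile fractions and the saturation cutoff applied before ranking."""

    fractions: Mapping[str, float] = field(
        default_factory=lambda: {
            "top10": 0.10,
            "top25": 0.25,
            "bottom10": 0.10,
            "bottom25": 0.25,
        }
    )
    ks_cutoff: float = 2.0

    def __post_init__(self):
        for name, f in self.fractions.items():
            if not (0 < f < 1):
                raise ValueError(f"fraction {name}={f} outside (0,1)")


def ng86_pair(
    seq_a: str, seq_b: str, code_table: int = DEFAULT_CODE_TABLE
) -> NG86Estimate:
    """Nei-Gojobori (1986) Ka/Ks for a pair of codon sequences.

    Codons containing characters outside ACGT in either sequence are excluded
    from both site and difference counting. Internal stop codons are an error.
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError(f"length mismatch: {len(seq_a)} vs {len(seq_b)}")
    if len(seq_a) % 3:
        raise ValueError(f"length {len(seq_a)} not divisible by 3")
    s1 = s2 = 0.0
    sd = nd = 0.0
    counted = 0
    for idx in range(0, len(seq_a), 3):
        ca, cb = seq_a[idx : idx + 3], seq_b[idx : idx + 3]
        if any(c not in NUCLEOTIDES for c in ca + cb):
            continue
        for name, codon in (("first", ca), ("second", cb)):
            if is_stop(codon, code_table):
                raise ValueError(
                    f"internal stop codon {codon} in {name} sequence at codon {idx // 3}"
                )
        s1 += synonymous_sites(ca, code_table)
        s2 += synonymous_sites(cb, code_table)
        d = pathway_differences(ca, cb, code_table)
        sd += d[0]
        nd += d[1]
        counted += 1
    s_sites = (s1 + s2) / 2.0
    n_sites = 3.0 * counted - s_sites
    ks = jukes_cantor(sd / s_sites) if s_sites > 0 else None
    ka = jukes_cantor(nd / n_sites) if n_sites > 0 else None
    if ka is None or ks is None or ks == 0:
        ratio = None
    else:
        ratio = ka / ks
    return NG86Estimate(ka=ka, ks=ks, ratio=ratio, s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd)


def make_windows(
    alignment_length: int, window: int = 1200, step: int = 600, min_tail: int = 300
) -> list[Window]:
    """Overlapping codon-preserving windows over [0, alignment_length).

    Windows start at multiples of ``step``; the final window ends at the
    alignment end and a trailing window shorter than ``window`` is emitted
    only if it spans at least ``min_tail`` bp.
    """
    for name, value in (("alignment_length", alignment_length), ("window", window), ("step", step)):
        if value % 3:
            raise ValueError(f"{name}={value} not divisible by 3")
    if alignment_length < min_tail:
        warnings.warn(
            f"alignment of {alignment_length} bp shorter than min_tail={min_tail}; no windows",
            stacklevel=2,
        )
        return []
    windows: list[Window] = []
    start = 0
    while start < alignment_length:
        end = min(start + window, alignment_length)
        span = end - start
        if span < window and span < min_tail:
            break
        windows.append(Window(start, end))
        if end == alignment_length:
            break
        start += step
    return windows


@dataclass
class ScanResult:
    """All window estimates plus the subset usable for ranking."""

    raw: list[WindowEstimate]
    usable: list[WindowEstimate]


def scan_alignment(alignment: PairAlignment, spec: PartitionSpec,
                   window: int = 1200, step: int = 600, min_tail: int = 300,
                   code_table: int = DEFAULT_CODE_TABLE) -> ScanResult:
    """Estimate Ka/Ks per window; drop saturated (ks > cutoff) and undefined
    ratios from the usable set while keeping everything in the raw report."""
    raw: list[WindowEstimate] = []
    usable: list[WindowEstimate] = []
    for w in make_windows(alignment.length, window=window, step=step, min_tail=min_tail):
        est = ng86_pair(alignment.seq_a[w.start : w.end], alignment.seq_b[w.start : w.end],
                        code_table=code_table)
        we = WindowEstimate(window=w, **est.__dict__)
        raw.append(we)
        if we.ratio is None:
            continue
        if we.ks is not None and we.ks > spec.ks_cutoff:
            continue
        usable.append(we)
    return ScanResult(raw=raw, usable=usable)


def assign_genes_to_windows(
    windows: Iterable[Window], genes: Iterable[GeneInterval], min_overlap: int = 300
) -> dict[str, list[Window]]:
    """Assign each gene to every window it overlaps by >= min_overlap bp."""
    windows = list(windows)
    assignment: dict[str, list[Window]] = {}
    for gene in genes:
        hits = [
            w
            for w in windows
            if min(gene.end, w.end) - max(gene.start, w.start) >= min_overlap
        ]
        if hits:
            assignment[gene.gene_id] = hits
    return assignment


def gene_level_dnds(
    assignments: Mapping[str, list[Window]], estimates: Iterable[WindowEstimate]
) -> list[GeneScore]:
    """Per-gene dN/dS = unweighted mean over the gene's surviving windows.

    Genes whose every assigned window was filtered (saturated or undefined
    ratio) are dropped with a logged reason.
    """
    by_window = {(e.window.start, e.window.end): e for e in estimates if e.ratio is not None}
    scores: list[GeneScore] = []
    for gene_id, windows in assignments.items():
        ratios = [
            by_window[(w.start, w.end)].ratio
            for w in windows
            if (w.start, w.end) in by_window
        ]
        if not ratios:
            logger.info("gene %s dropped: no surviving window estimate", gene_id)
            continue
        scores.append(GeneScore(gene_id=gene_id, dnds=sum(ratios) / len(ratios), n_windows=len(ratios)))
    return scores


def partition_quantiles(
    scores: Sequence[GeneScore], spec: PartitionSpec
) -> dict[str, set[str]]:
    """Split genes into top/bottom quantile sets by dN/dS.

    Genes are sorted by dN/dS descending (ties broken by gene id ascending);
    a top (bottom) set of fraction F holds the first (last) ceil(F*n) genes.
    """
    if len(scores) < 4:
        raise ValueError(f"need at least 4 gene scores to partition, got {len(scores)}")
    ordered = sorted(scores, key=lambda s: (-s.dnds, s.gene_id))
    n = len(ordered)
    out: dict[str, set[str]] = {}
    for name, frac in spec.fractions.items():
        k = math.ceil(frac * n)
        if name.startswith("top"):
            out[name] = {s.gene_id for s in ordered[:k]}
        elif name.startswith("bottom"):
            out[name] = {s.gene_id for s in ordered[n - k :]}
        else:
            raise ValueError(f"partition name {name!r} must start with 'top' or 'bottom'")
    return out


def calibrate_divergence_time(
    percent_divergence: float, my_per_unit: float = 216.0, pct_per_unit: float = 2.8
) -> float:
    """Linear molecular-clock calibration: million years for a given percent
    16S rRNA divergence (default 216 My per 2.8%)."""
    if percent_divergence < 0:
        raise ValueError("percent divergence must be nonnegative")
    return percent_divergence * my_per_unit / pct_per_unit
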