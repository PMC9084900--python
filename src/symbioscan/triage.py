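"""Symbiont contig triage from community assemblies.

Filters a contig population down to likely endosymbiont contigs using three
rules in a fixed order: best-hit taxonomic classification over precomputed
hit tables, a GC band applied to contigs above a length gate, and a relative
coverage ceiling applied to long contigs. Also provides the stopping rule
for iterative read-enrichment assembly cycles.

All thresholds are strict, so boundary values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .errors import DegenerateInputError

VALID_BASES = set("ACGTN")


@dataclass
class ContigRecord:
    contig_id: str
    length: int
    gc: float
    mean_coverage: float
    sequence: Optional[str] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.contig_id}: length must be >= 1")
        if not (0 <= self.gc <= 1):
            raise ValueError(f"{self.contig_id}: gc {self.gc} outside [0,1]")
        if self.mean_coverage < 0:
            raise ValueError(f"{self.contig_id}: negative coverage")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(f"{self.contig_id}: sequence length != length field")


@dataclass(frozen=True)
class HitRecord:
    query_id: str
    subject_id: str
    subject_label: str
    bitscore: float
    evalue: float

    def __post_init__(self):
        if self.bitscore < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative bitscore")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative evalue")


@dataclass
class TriageReport:
    kept: list[str]
    removed: dict[str, str]
    reference_coverage: float


def compute_gc(sequence: str) -> float:
    """GC fraction of a nucleotide sequence; N bases excluded from the
    denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise DegenerateInputError("sequence contains only N bases; GC undefined")
    return (seq.count("G") + seq.count("C")) / denom


def filter_by_gc(
    contigs: Iterable[ContigRecord],
    min_gc: float = 0.24,
    max_gc: float = 0.42,
    min_len: int = 1000,
) -> dict[str, str]:
    """Removal reasons for contigs longer than the gate whose GC falls
    strictly outside [min_gc, max_gc]."""
    if not (0 <= min_gc <= max_gc <= 1):
        raise ValueError("require 0 <= min_gc <= max_gc <= 1")
    removed: dict[str, str] = {}
    for c in contigs:
        if c.length <= min_len:
            continue
        if c.gc < min_gc:
            removed[c.contig_id] = "gc_low"
        elif c.gc > max_gc:
            removed[c.contig_id] = "gc_high"
    return removed


def reference_coverage(contigs: Sequence[ContigRecord], n_longest: int = 10) -> float:
    """Mean coverage over the n longest contigs (ties broken by id ascending)."""
    if not contigs:
        raise ValueError("no contigs")
    ranked = sorted(contigs, key=lambda c: (-c.length, c.contig_id))[:n_longest]
    return sum(c.mean_coverage for c in ranked) / len(ranked)


def filter_by_coverage(
    contigs: Iterable[ContigRecord],
    reference: float,
    factor: float = 2.0,
    min_len: int = 5000,
) -> dict[str, str]:
    """Removal reasons for long contigs with coverage strictly above
    factor * reference (a screen for short horizontally transferred
    look-alike regions riding on host contigs)."""
    if reference <= 0:
        raise ValueError("reference coverage must be positive")
    removed: dict[str, str] = {}
    for c in contigs:
        if c.length > min_len and c.mean_coverage > factor * reference:
            removed[c.contig_id] = "coverage_high"
    return removed


def classify_best_hit(
    hits_step1: Iterable[HitRecord],
    hits_step2: Iterable[HitRecord],
    target_labels: set[str],
) -> dict[str, tuple[Optional[str], str]]:
    """Two-step best-hit classification.

    A query is a candidate iff it has at least one step-1 (custom database)
    hit. A candidate's final label is the label of its best step-2 (broad
    database) hit — max bitscore, ties by min evalue then subject id — and
    its status is "target" iff that label is in ``target_labels``.
    Candidates with no step-2 hit keep their step-1 label and count as
    targets (the custom-database evidence stands). Queries with no step-1
    hit are "unclassified".
    """
    hits_step1 = list(hits_step1)
    hits_step2 = list(hits_step2)

    def best(hits: list[HitRecord]) -> dict[str, HitRecord]:
        by_query: dict[str, HitRecord] = {}
        for h in sorted(hits, key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id)):
            by_query.setdefault(h.query_id, h)
        return by_query

    best1 = best(hits_step1)
    best2 = best(hits_step2)
    result: dict[str, tuple[Optional[str], str]] = {}
    all_queries = {h.query_id for h in hits_step1} | {h.query_id for h in hits_step2}
    for q in sorted(all_queries):
        if q not in best1:
            result[q] = (None, "unclassified")
        elif q in best2:
            label = best2[q].subject_label
            result[q] = (label, "target" if label in target_labels else "nontarget")
        else:
            result[q] = (best1[q].subject_label, "target")
    return result


def should_continue_enrichment(
    retained_lengths: Sequence[int], max_iterations: int = 10
) -> bool:
    """Continue iterative enrichment iff the retained length still grew in
    the last cycle and the iteration cap is not yet reached."""
    if not retained_lengths:
        raise ValueError("need at least one cycle's retained length")
    if any(x < 0 for x in retained_lengths):
        raise ValueError("retained lengths must be nonnegative")
    if len(retained_lengths) >= max_iterations:
        return False
    if len(retained_lengths) == 1:
        return True
    return retained_lengths[-1] > retained_lengths[-2]


def triage_contigs(
    contigs: Sequence[ContigRecord],
    classification: Optional[Mapping[str, tuple[Optional[str], str]]] = None,
    min_gc: float = 0.24,
    max_gc: float = 0.42,
    gc_min_len: int = 1000,
    coverage_factor: float = 2.0,
    coverage_min_len: int = 5000,
    n_longest: int = 10,
) -> TriageReport:
    """Full triage: classification, GC band, then relative coverage.

    The removal reason recorded for a contig is the first failing rule in
    that fixed order; the kept set itself is order-independent because each
    rule's condition does not depend on the other rules' outcomes (the
    coverage reference is computed on the full input population).
    """
    ref = reference_coverage(contigs, n_longest=n_longest)
    gc_removed = filter_by_gc(contigs, min_gc=min_gc, max_gc=max_gc, min_len=gc_min_len)
    cov_removed = filter_by_coverage(
        contigs, ref, factor=coverage_factor, min_len=coverage_min_len
    )
    removed: dict[str, str] = {}
    kept: list[str] = []
    for c in contigs:
        status = classification.get(c.contig_id) if classification else None
        if status is not None and status[1] == "nontarget":
            removed[c.contig_id] = "classified_nontarget"
        elif c.contig_id in gc_removed:
            removed[c.contig_id] = gc_removed[c.contig_id]
        elif c.contig_id in cov_removed:
            removed[c.contig_id] = cov_removed[c.contig_id]
        else:
            kept.append(c.contig_id)
    return TriageReport(kept=kept, removed=removed, reference_coverage=ref)
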