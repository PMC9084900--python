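"""Readers and writers for the plain-text formats the pipeline exchanges.

Pairwise alignments travel as AXT blocks or paired FASTA; gene intervals as
BED; abundance matrices as TSV with ``#read_total`` comment lines; GO
annotations as two-column TSV; simulated ontologies as OBO 1.2; BLAST hits
as 12-column tabular TSV with a subject->label sidecar.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import AbundanceMatrix
from .dnds import GeneInterval, PairAlignment
from .enrichment import GoDag
from .triage import HitRecord


# -- pairwise alignments -----------------------------------------------------

def read_paired_fasta(path) -> PairAlignment:
    """A two-record FASTA holding one pairwise alignment."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly 2 records, found {len(records)}")
    return PairAlignment.from_aligned(
        id=Path(str(path)).stem, seq_a=str(records[0].seq), seq_b=str(records[1].seq)
    )


def write_paired_fasta(alignment: PairAlignment, path, names=("seq_a", "seq_b")) -> None:
    records = [
        SeqRecord(Seq(alignment.seq_a), id=names[0], description=""),
        SeqRecord(Seq(alignment.seq_b), id=names[1], description=""),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_axt(path) -> list[PairAlignment]:
    """AXT pairwise blocks: a header line, two sequence lines, blank line."""
    alignments: list[PairAlignment] = []
    with open(path) as fh:
        block: list[str] = []
        for raw in fh:
            line = raw.strip()
            if line.startswith("#"):
                continue
            if not line:
                if block:
                    alignments.append(_axt_block(block, path))
                    block = []
                continue
            block.append(line)
        if block:
            alignments.append(_axt_block(block, path))
    return alignments


def _axt_block(block: list[str], path) -> PairAlignment:
    if len(block) != 3:
        raise ValueError(f"{path}: malformed AXT block {block[:1]}")
    header = block[0].split()
    name = header[0] if header else "axt"
    return PairAlignment.from_aligned(id=name, seq_a=block[1], seq_b=block[2])


def write_axt(alignments: Iterable[PairAlignment], path) -> None:
    with open(path, "w") as fh:
        for aln in alignments:
            fh.write(f"{aln.id}\n{aln.seq_a}\n{aln.seq_b}\n\n")


# -- gene intervals ----------------------------------------------------------

def read_bed(path, annotations: Optional[Mapping[str, Iterable[str]]] = None
             ) -> dict[str, list[GeneInterval]]:
    """BED (chrom, start, end, name) -> intervals grouped by chrom.

    chrom is the alignment id; optional ``annotations`` attaches GO terms
    by gene name.
    """
    by_chrom: dict[str, list[GeneInterval]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{i}: BED row needs 4 columns")
            chrom, start, end, name = fields[:4]
            go = frozenset(annotations.get(name, ())) if annotations else frozenset()
            by_chrom.setdefault(chrom, []).append(
                GeneInterval(gene_id=name, start=int(start), end=int(end), go_terms=go)
            )
    return by_chrom


def write_bed(intervals: Mapping[str, Iterable[GeneInterval]], path) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for g in intervals[chrom]:
                fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")


# -- abundance matrices ------------------------------------------------------

def read_abundance_tsv(path) -> AbundanceMatrix:
    """TSV with samples as rows; optional leading ``#read_total`` lines."""
    read_totals: dict[str, float] = {}
    rows: list[str] = []
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("#read_total"):
                _, sample, value = raw.rstrip("\n").split("\t")
                read_totals[sample] = float(value)
            elif raw.strip():
                rows.append(raw)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t", index_col=0)
    totals = pd.Series(read_totals) if read_totals else None
    return AbundanceMatrix(values=df, read_totals=totals)


def write_abundance_tsv(matrix: AbundanceMatrix, path) -> None:
    with open(path, "w") as fh:
        if matrix.read_totals is not None:
            for sample, total in matrix.read_totals.items():
                fh.write(f"#read_total\t{sample}\t{total:g}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="sample")


# -- GO annotations and ontologies -------------------------------------------

def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column (gene_id, term_id) TSV, one pair per line."""
    direct: dict[str, set[str]] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{i}: expected 2 columns, got {len(fields)}")
            direct.setdefault(fields[0], set()).add(fields[1])
    return direct


def write_annotation_tsv(direct: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(direct):
            for term in sorted(direct[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_obo(dag: GoDag, path) -> None:
    """Minimal OBO 1.2 writer (id, name, namespace, is_a), round-trippable
    through load_obo."""
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\nontology: simulated-go\n")
        for term in sorted(dag.terms):
            name, namespace = dag.terms[term]
            fh.write(f"\n[Term]\nid: {term}\nname: {name}\nnamespace: {namespace}\n")
            for parent in sorted(dag.parents.get(term, ())):
                pname = dag.terms[parent][0]
                fh.write(f"is_a: {parent} ! {pname}\n")


# -- BLAST tabular hits ------------------------------------------------------

BLAST_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tab(path, labels: Mapping[str, str]) -> list[HitRecord]:
    """12-column BLAST tabular hits with subject labels from a sidecar map.

    Subjects missing from ``labels`` get the label "unknown".
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(BLAST_COLUMNS):
                raise ValueError(
                    f"{path}:{i}: expected {len(BLAST_COLUMNS)} columns, got {len(fields)}"
                )
            try:
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"{path}:{i}: malformed numeric field: {exc}") from exc
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    subject_label=labels.get(fields[1], "unknown"),
                    bitscore=bitscore,
                    evalue=evalue,
                )
            )
    return hits


def read_label_tsv(path) -> dict[str, str]:
    """Two-column (subject_id, label) sidecar."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}:{i}: expected 2 columns")
            labels[fields[0]] = fields[1]
    return labels
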