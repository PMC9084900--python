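"""Gene repertoire algebra over presence/absence matrices.

Consumes Roary-style gene_presence_absence.csv tables and computes core
sets, pangenomes, Venn region counts, and shared-fraction statistics for
labeled strain groups. Presence is boolean: a nonempty cell means the gene
cluster has at least one member in that strain; paralog multiplicity is
ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

#: The standard Roary metadata columns preceding the per-strain columns.
ROARY_METADATA_COLUMNS = 14


@dataclass
class PresenceAbsenceMatrix:
    """Boolean gene-cluster x strain table (index: genes, columns: strains)."""

    present: pd.DataFrame

    def __post_init__(self):
        if self.present.shape[1] < 1:
            raise ValueError("need at least one strain column")
        if self.present.index.duplicated().any():
            dupes = sorted(set(self.present.index[self.present.index.duplicated()]))
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.present.columns.duplicated().any():
            raise ValueError("duplicate strain ids")
        self.present = self.present.astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.present.index)

    @property
    def strains(self) -> list[str]:
        return list(self.present.columns)

    def genes_of(self, strain: str) -> set[str]:
        col = self.present[strain]
        return set(col.index[col])


@dataclass(frozen=True)
class StrainGroup:
    label: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"group {self.label}: empty member set")


def read_presence_absence(
    path, strain_columns: Optional[Sequence[str]] = None
) -> PresenceAbsenceMatrix:
    """Load a Roary-style gene_presence_absence.csv.

    Strain columns are taken from ``strain_columns`` if given, otherwise
    auto-detected as every column after the fixed Roary metadata preamble.
    A cell is a presence iff it is nonempty.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.columns[0] != "Gene":
        raise ValueError(f"first column must be 'Gene', got {df.columns[0]!r}")
    if strain_columns is None:
        strain_columns = list(df.columns[ROARY_METADATA_COLUMNS:])
    else:
        missing = [c for c in strain_columns if c not in df.columns]
        if missing:
            raise ValueError(f"strain columns not in file: {missing}")
        strain_columns = list(strain_columns)
    if not strain_columns:
        raise ValueError("no strain columns found")
    present = df.set_index("Gene")[strain_columns].apply(lambda col: col.str.strip() != "")
    return PresenceAbsenceMatrix(present=present)


def write_presence_absence(matrix: PresenceAbsenceMatrix, path) -> None:
    """Write in the Roary CSV dialect (blank metadata, locus tags as cells)."""
    meta_names = [
        "Gene", "Non-unique Gene name", "Annotation", "No. isolates", "No. sequences",
        "Avg sequences per isolate", "Genome Fragment", "Order within Fragment",
        "Accessory Fragment", "Accessory Order with Fragment", "QC",
        "Min group size nuc", "Max group size nuc", "Avg group size nuc",
    ]
    out = pd.DataFrame(index=matrix.present.index)
    out["Gene"] = out.index
    out["No. isolates"] = matrix.present.sum(axis=1).astype(str)
    for name in meta_names:
        if name not in out.columns:
            out[name] = ""
    out = out[meta_names]
    for strain in matrix.strains:
        out[strain] = [
            f"{gene}_{strain}" if present else ""
            for gene, present in matrix.present[strain].items()
        ]
    out.to_csv(path, index=False)


def _check_group(matrix: PresenceAbsenceMatrix, group: StrainGroup) -> None:
    missing = group.members - set(matrix.strains)
    if missing:
        raise ValueError(f"group {group.label}: unknown strains {sorted(missing)}")


def core_set(matrix: PresenceAbsenceMatrix, group: StrainGroup) -> set[str]:
    """Gene clusters present in every member of the group."""
    _check_group(matrix, group)
    sub = matrix.present[list(group.members)]
    return set(sub.index[sub.all(axis=1)])


def pangenome_set(matrix: PresenceAbsenceMatrix, group: StrainGroup) -> set[str]:
    """Gene clusters present in at least one member of the group."""
    _check_group(matrix, group)
    sub = matrix.present[list(group.members)]
    return set(sub.index[sub.any(axis=1)])


def venn_regions(
    sets: Mapping[str, set[str]], max_sets: int = 6
) -> dict[str, int]:
    """Counts of exclusive Venn regions for 2 or more labeled gene sets.

    Region signatures are membership bit-strings in the order of the input
    labels ('110' = in the first two sets only). Empty regions are omitted;
    counts sum to the size of the union.
    """
    labels = list(sets)
    if len(labels) < 2:
        raise ValueError("need at least 2 sets")
    if len(labels) > max_sets:
        raise ValueError(f"more than {max_sets} sets; raise max_sets to override")
    regions: dict[str, int] = {}
    universe = set().union(*sets.values())
    for gene in universe:
        signature = "".join("1" if gene in sets[lab] else "0" for lab in labels)
        regions[signature] = regions.get(signature, 0) + 1
    return regions


def shared_fraction(set_a: set[str], reference: set[str]) -> float:
    """|set_a ∩ reference| / |reference|."""
    if not reference:
        raise ValueError("empty reference set")
    return len(set_a & reference) / len(reference)
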