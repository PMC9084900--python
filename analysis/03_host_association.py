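#!/usr/bin/env python
"""Nominate the symbiont's host from community co-occurrence.

Reads the simulated community matrix (run 01_simulate_inputs.py first),
converts a worked kmer-coverage example, normalizes to per-million reads,
and screens every column pair with Spearman midrank correlation + BH
correction. The planted host (taxon_005) should top the ranking.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from symbioscan import io as sio
from symbioscan.association import (
    association_screen,
    kmer_to_total_coverage,
    normalize_matrix,
)

SIMDATA = Path(__file__).resolve().parents[1] / "scratch" / "simdata"
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    c = kmer_to_total_coverage(10.0, 25, 150)
    print(f"kmer coverage 10 at k=25, r=150 -> total coverage {c:.4f}")

    matrix = sio.read_abundance_tsv(SIMDATA / "community_matrix.tsv")
    normalized = normalize_matrix(matrix)
    results = association_screen(normalized, "symbiont_16S")

    out = RESULTS / "03_association.tsv"
    with open(out, "w") as fh:
        fh.write("column_i\tcolumn_j\trho\tp_raw\tp_adj\tn_used\n")
        for r in results:
            fh.write(
                f"{r.pair[0]}\t{r.pair[1]}\t{r.rho:.6f}\t{r.p_raw:.3e}"
                f"\t{r.p_adj:.3e}\t{r.n_used}\n"
            )

    symbiont_pairs = [r for r in results if "symbiont_16S" in r.pair]
    top = symbiont_pairs[0]
    partner = top.pair[0] if top.pair[1] == "symbiont_16S" else top.pair[1]
    print(
        f"top symbiont partner: {partner} "
        f"(rho {top.rho:.3f}, BH-adjusted p {top.p_adj:.2e})"
    )
    n_sig = sum(r.p_adj < 0.05 for r in symbiont_pairs)
    print(f"{n_sig} symbiont pair(s) significant after BH at 0.05")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
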