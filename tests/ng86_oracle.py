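"""Brute-force Nei-Gojobori oracle, independent of the library implementation.

Site fractions are counted by direct single-base mutation of codon strings
(translation via Bio.Seq); difference counts enumerate every minimal
substitution pathway recursively, excluding pathways through stop codons.
Used only as a test reference.
"""

import math

from Bio.Seq import Seq

STOPS_11 = {"TAA", "TAG", "TGA"}


def aa(codon: str) -> str:
    if codon in STOPS_11:
        return "*"
    return str(Seq(codon).translate(table=11))


def oracle_syn_sites(codon: str) -> float:
    ref = aa(codon)
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOPS_11 and aa(mutant) == ref:
                syn += 1
    return syn / 3.0


def oracle_pathways(codon_a: str, codon_b: str):
    """All minimal pathways as (syn_steps, nonsyn_steps), stop-free only."""
    results = []

    def step(current: str, sd: int, nd: int):
        if current == codon_b:
            results.append((sd, nd))
            return
        for pos in range(3):
            if current[pos] != codon_b[pos]:
                nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
                if nxt in STOPS_11 and nxt != codon_b:
                    continue
                if aa(current) == aa(nxt):
                    step(nxt, sd + 1, nd)
                else:
                    step(nxt, sd, nd + 1)

    step(codon_a, 0, 0)
    return results


def oracle_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    paths = oracle_pathways(codon_a, codon_b)
    if not paths:
        # all minimal pathways blocked by stops: average over all orderings,
        # counting stop-crossing steps as nonsynonymous
        import itertools

        diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
        paths = []
        for order in itertools.permutations(diff):
            cur, sd, nd = codon_a, 0, 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
                if aa(cur) == aa(nxt) and nxt not in STOPS_11:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def oracle_estimate(seq_a: str, seq_b: str):
    """(ka, ks, s_sites, n_sites, sd, nd); None marks an undefined distance."""
    n_codons = len(seq_a) // 3
    s1 = sum(oracle_syn_sites(seq_a[3 * i : 3 * i + 3]) for i in range(n_codons))
    s2 = sum(oracle_syn_sites(seq_b[3 * i : 3 * i + 3]) for i in range(n_codons))
    s_sites = (s1 + s2) / 2
    n_sites = 3 * n_codons - s_sites
    sd = nd = 0.0
    for i in range(n_codons):
        d_s, d_n = oracle_differences(seq_a[3 * i : 3 * i + 3], seq_b[3 * i : 3 * i + 3])
        sd += d_s
        nd += d_n

    def jc(p):
        if p == 0:
            return 0.0
        if 4 * p / 3 >= 1:
            return None
        return -0.75 * math.log(1 - 4 * p / 3)

    ks = jc(sd / s_sites) if s_sites > 0 else None
    ka = jc(nd / n_sites) if n_sites > 0 else None
    return ka, ks, s_sites, n_sites, sd, nd
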