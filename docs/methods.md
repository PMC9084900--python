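# Methods

This package implements the analytical core of an endosymbiont discovery
study: extracting a low-GC intracellular symbiont (a *Wolbachia*-like
bacterium) from rhizosphere nematode community metagenome assemblies,
nominating its host by co-occurrence, and characterizing its functional
evolution through sliding-window dN/dS, GO enrichment, gene-repertoire set
algebra, and branch-transition comparisons. Because the raw sequencing data
and the heavyweight upstream toolchain (assembler, gene caller, ortholog
clusterer) sit outside the package's scope, every stage is exercised
against synthetic data whose generators plant known truth; the tests and
the acceptance script measure how well each stage recovers it.

## Contig triage (`triage`)

A community assembly mixes symbiont contigs with host and environmental
DNA. Triage applies three independent rules:

1. **Best-hit classification.** A contig with at least one hit to a custom
   marker database (step 1) is a candidate; its final label is the label of
   its best broad-database hit (step 2; max bitscore, ties by min e-value
   then subject id). Candidates whose best label is not a target label are
   removed. Candidates with step-1 evidence but no step-2 hit count as
   targets — the custom-database evidence stands. Contigs with no step-1
   hit are left unclassified and face only the remaining rules.
2. **GC band.** Contigs longer than 1,000 bp are removed if GC is strictly
   below 0.24 or strictly above 0.42. All thresholds in this module are
   strict, so boundary values are retained.
3. **Relative coverage.** Contigs longer than 5,000 bp are removed if mean
   coverage strictly exceeds 2x a reference coverage. "Average coverage of
   the longest contigs" is made concrete as the mean over the 10 longest
   (ties by id; `n_longest` configurable) — a deterministic, robust choice.
   The reference is computed on the full input population, which makes the
   kept set independent of rule order.

The removal reason recorded is the first failing rule in the fixed order
classification -> GC -> coverage. Iterative read-enrichment assembly stops
when the summed length of retained contigs fails to grow between cycles, or
at a safety cap of 10 iterations (the procedure typically converges in ~3).

*Synthetic fixture.* `simulate_contig_set` draws two contig classes with
normal GC (clipped to [0,1]) and normal coverage (floored above 0), lengths
log-uniform on [500, 60000] bp. Because ~14% of contigs fall under the
1,000 bp GC gate, GC+coverage alone cannot exceed ~0.87–0.89 precision on a
balanced mixture; the accuracy experiment therefore emulates the hit tables
too (80% of contigs carry two-step evidence, 2% of labels are wrong), which
is what the full procedure has available. Defaults: target GC 0.33 ± 0.02
vs background 0.55 ± 0.03; target coverage 16 ± 3 vs background 60 ± 15.

## Host association (`association`)

Marker abundance per sample is derived from assembler kmer coverage,
`C = C_K * R / (R − K + 1)` (read length R, kmer length K), and normalized
to coverage per million sequenced reads. The per-million scale is cosmetic
for what follows: Spearman correlation is rank-invariant. Association is
Spearman's rho with midranks for ties over pairwise-complete observations,
two-sided p from the t approximation on n−2 degrees of freedom (|rho| = 1
maps to p = 0), and Benjamini–Hochberg correction applied across **all**
column pairs — matching the all-pairs behaviour of the correlation-matrix
routines the procedure mirrors, not just the symbiont's pairs. Columns that
are constant after ranking are excluded with a logged reason rather than
failing the screen.

*Synthetic fixture.* The community generator draws independent lognormal
taxon columns and appends a symbiont column built as
`corr_strength * z(host) + (1 − corr_strength) * noise_sd * e`, shifted and
floored at zero — a monotone transform plus noise, which is all a rank
correlation needs. `corr_strength` is a mixing weight, not the resulting
rho: at 1 with zero noise the association is exactly monotone; at 0 the
column is independent of everything.

## Sliding-window dN/dS (`dnds`)

Pairwise codon alignments (gap codon columns removed; no internal stops
under translation table 11) are cut into 1,200 bp windows stepping 600 bp,
codon-aligned. The final window ends at the alignment end; a trailing
window shorter than 1,200 bp is kept only if it spans ≥ 300 bp, mirroring
the gene-assignment threshold.

Per window, Ka and Ks are estimated by Nei–Gojobori (1986) counting:

- Each codon position contributes the fraction of its three possible
  changes that are synonymous; changes creating a stop codon stay in the
  denominator but never count as synonymous. Site totals are averaged over
  the two sequences; S + N equals the window length.
- Observed differences average over all minimal substitution pathways with
  equal weights; pathways through stop codons are excluded (with a guarded
  fallback to all pathways if every one is blocked — not observed for
  sense-codon pairs under table 11).
- Proportions are corrected for multiple hits with Jukes–Cantor,
  d = −(3/4) ln(1 − 4p/3), undefined (NA) at p ≥ 3/4. The ratio is NA when
  Ks is 0 or either distance is undefined; NA ratios cannot be ranked and
  are excluded from partitioning while remaining in the raw report.

Windows with Ks above a saturation cutoff (2.0 by default; 2.5 for very
close strain pairs) are discarded. Genes are assigned to every window they
overlap by ≥ 300 bp and scored as the unweighted mean of their surviving
windows' ratios (the choice of mean over median is a design decision; with
2–5 windows per gene the two rarely differ in rank). Genes are partitioned
by sorting on the score descending, ties by gene id, into top/bottom 10%
and 25% sets of ceil(F·n) genes.

The NG86 counting estimator replaces the model-averaged maximum-likelihood
estimator sometimes used for this task: it is fully specified, exactly
checkable against a brute-force pathway-enumeration oracle, and the
downstream quantile partitioning depends only on ranks, which are robust to
the estimator choice.

A linear molecular-clock calibration converts percent 16S rRNA divergence
to time at 216 My per 2.8% divergence (so 3.934% ≈ 303 My, 4.211% ≈ 325
My).

*Synthetic fixture.* `simulate_codon_pair` draws a random sense-codon
ancestor and plants differences per NG86 site class: the number of
synonymous (nonsynonymous) single-nucleotide differences is Poisson with
mean `p_JC(target) * sites`, where `p_JC` inverts the Jukes–Cantor
correction, each placed at a not-yet-mutated position (stops resampled).
Planting *differences* rather than running a multiple-hit event process
makes recovery well-posed under the estimator's own site definitions — the
estimator's JC inversion then recovers the target in expectation instead of
inheriting the JC/2-fold-degeneracy mismatch of a literal event process.
Residual interactions (two planted changes in one codon re-enter pathway
averaging) keep recovery approximate: across targets 0.02–0.5 and Ks
0.1–1.0 at 2,000 codons, the mean estimate sits within ±0.03 of the target.

## GO enrichment (`enrichment`)

The ontology is an is_a DAG (OBO 1.2 via obonet; obsolete terms dropped,
alt_ids resolved, other relation types ignored). Annotations propagate to
all ancestors (true-path rule). Genes with no propagated annotation are
removed from both study and universe totals, keeping the 2×2 tables
well-defined. Per term, the classic p-value is the hypergeometric upper
tail P(X ≥ study_count). The elim variant processes terms children-first
(decreasing longest-path depth); when a term's current p falls below
elim_alpha = 0.01, its study genes are removed from all ancestors' gene
sets before those are tested, decorrelating the hierarchy. Enriched-term
reporting thresholds the chosen p-value strictly at alpha (default 0.05)
with no further multiple-testing correction, mirroring the upstream
toolchain's reporting convention. The weight01 hybrid statistic of that
toolchain is deliberately not reproduced; elim is precisely published and
oracle-testable, and acceptance is via planted-term recovery, not p-value
equality.

## Repertoire sets (`repertoire`)

Gene presence/absence comes from a Roary-style CSV: presence is a nonempty
cell in a strain column; paralog multiplicity is ignored since all derived
quantities are set counts. Strain columns are auto-detected after the fixed
14-column metadata preamble, overridable by an explicit list. Core = genes
in every group member; pangenome = genes in at least one; Venn regions are
exclusive membership signatures whose counts sum to the union; the shared
fraction of a set with a reference is |A ∩ R| / |R|.

## Branch transitions (`transitions`)

For an ordered chain of strains, each adjacent pair's alignment bundle runs
the scan -> assignment -> gene-score -> quantile pipeline, then each
quantile set is tested (elim, alpha 0.05) against all scored genes of that
pair — the universe is the scored-and-annotated gene set, the natural frame
given that only scored genes could have entered any quantile. Enriched
terms are classified by their presence pattern across pairs: universal
(every pair), unique:<pair> (exactly one), or shared:<pairs>. The per-pair
Ks cutoff is 2.5 for the closest (within-clade) pair and 2.0 otherwise.

## Study designs used by the recovery experiments (`experiments`)

- **dN/dS recovery**: targets in {0.02, 0.1, 0.2, 0.5} at Ks 0.4, 2,000
  codons, 50 seeds; scored by mean absolute error and bias, both ≤ 0.05.
- **Quantile/enrichment recovery**: 100 genes of 1,000 codons split 20/60/20
  into low (0.02) / background (0.1) / high (0.5) categories. The flanks
  must each fit inside a 25% quantile set, otherwise full sensitivity is
  arithmetically impossible; 20% flanks leave headroom for estimation
  noise. Gene order is shuffled before concatenation because adjacent genes
  share overlap windows, which would otherwise correlate the scores of
  same-category neighbours. A decoy term annotated to a random 20-gene
  subset measures the false-positive side.
- **Triage accuracy**: 200 target + 200 background contigs with the default
  separation and the emulated hit tables described above.
- **FDR control**: 200 null communities (12 samples, 10 taxa, independent
  symbiont column); the mean fraction of BH-significant symbiont pairs must
  stay at or below 0.05.

Problem sizes were chosen so each experiment completes in seconds while
leaving the Monte-Carlo error well inside the asserted margins.

## What the synthetic data does not emulate

No indels, no codon-usage bias, no rate variation within a gene, no
read-level noise (coverage is drawn, not computed from reads), no
phylogenetic structure beyond pairwise comparisons, and GO DAGs far smaller
than the real ontology. Passing tests therefore demonstrate that the
implementations compute their definitions correctly and recover planted
structure under the stated assumptions — not that the procedures are robust
to real-data artifacts such as misassembly, annotation error, or alignment
uncertainty.

## Known limitations

- NG86 with JC correction underestimates divergence under strong
  transition/transversion bias; ranks, which drive the partitioning, are
  less affected.
- The elim implementation removes study genes of significant children from
  ancestor tests (both counts); it is not a reimplementation of topGO's
  weight01 and will not reproduce its p-values.
- The per-gene score is an unweighted window mean; genes spanning window
  boundaries borrow signal from neighbours within 600 bp.
- With small study sets the hypergeometric tail is discrete; the effective
  size of an alpha = 0.05 test can be far below 0.05.
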