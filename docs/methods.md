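# Methods

This note documents the models and procedures implemented in `intronhet`,
the defaults they use, and what the synthetic-data generators do and do
not emulate.

## Methylcytosine calling

Input is a per-cytosine report of methylated (#C) and unmethylated (#T)
read counts with CG/CHG/CHH context.  The pipeline:

1. **Conversion rate.** Bisulfite converts unmethylated cytosines to
   uracil (read as T); incomplete conversion inflates apparent
   methylation.  The rate is estimated as ΣT / Σ(C+T) over a
   known-unmethylated control (in plants, the chloroplast genome; in the
   simulator, a contig named `control_chloroplast`).
2. **Coverage filter.** Sites covered by fewer than 3 reads are too noisy
   to test; sites covered by more than 100 reads are overwhelmingly
   collapsed repeats or mapping artifacts.  Both bounds are inclusive
   (3 ≤ c ≤ 100) and exposed as parameters; the upper bound in real data
   corresponds to a quantile of the coverage distribution, so it should
   be adjusted to the library at hand.
3. **Binomial test.** At each site, p is the upper-tail binomial
   probability of ≥ #C methylated reads among the covered reads under the
   error rate (1 − conversion rate).  The named procedure is only "a
   binomial test", so the multiple-testing scheme is our choice: q-values
   are Benjamini–Hochberg *within each context* (contexts have very
   different true-positive fractions), and a site is a methylcytosine iff
   q ≤ 0.05.  Methylation *level* is always #C/(#C+#T), independent of
   the call.

Region summaries (e.g. per-TE methylation) average site levels over all
coverage-passing sites inside the region, both strands pooled, and report
a context only when ≥ 5 informative sites support it.

## Heterochromatic domains and introns

A **heterochromatic domain** is a maximal run of ≥ 5 consecutive called
CHG methylcytosines whose unweighted mean level is ≥ 0.5.  Design choices
where the rule under-specifies:

- "Consecutive" is evaluated over CHG sites in genomic order with both
  strands pooled.  A covered CHG site that *failed* the call breaks a
  run; intervening CG/CHH cytosines are invisible.  We require the
  binomial call, not merely level data (the stricter reading; the
  alternative is one flag away in `call_methylcytosines`).
- A maximal run whose mean falls below 0.5 yields no domain; no sub-run
  search is attempted, because the rule describes a classification, not
  an optimization.
- The domain interval spans the first through last member site
  (half-open); it is not extended toward neighboring unmethylated sites.

An intron is **heterochromatic** iff at least one domain is *fully
contained* in it (an any-overlap mode exists behind `mode="overlap"`);
a gene is heterochromatic iff any intron of any of its transcripts is.
Introns are derived per transcript, not collapsed per gene, so a splice
variant shared by two transcripts counts twice — this matches how
positional distributions are usually reported for variant-level
annotations.  Intron ordinals count from the transcript 5′ end.

## Enrichment and expression statistics

- **Positional permutation test.** The statistic is the mean ordinal of
  the heterochromatic introns; the null resamples size-matched subsets
  of all intron ordinals without replacement.  The tail is lower
  (promoter-proximal bias) by default, with the add-one correction
  p = (1 + hits)/(N + 1), so p ≥ 1/(N+1).
- **Fisher enrichment** uses the exact two-sided hypergeometric
  definition (sum of tables with probability ≤ the observed table's);
  the sample odds ratio ad/bc is reported alongside.
- **Tissue-specificity entropy** follows the ROKU recipe: a one-step
  Tukey biweight (c = 5, ε = 1e-4, the reference defaults) is the robust
  "typical" expression w; deviations |xᵢ − w| are normalized to a
  probability vector whose Shannon entropy (log2, bits) is H′.
  H′ ≈ 0 means one condition dominates; a constant vector maps to the
  maximum log2 n.  Whether the original used log2 or ln is not
  documented; we use log2 and note that the choice only rescales H′.
  The ε constant breaks exact scale invariance at the ~1e-6 level.
- **Effect size** r = |Z|/√N from the tie-corrected normal approximation
  of the rank-sum statistic.
- **TPM** is the usual length-normalized rate scaled to 10⁶.

## Premature-termination (pre/post-intron) test

For each intron, reads mapping upstream (pre) and downstream (post) are
modeled as a binomial proportion post/(pre+post) with genotype as the
sole predictor and a likelihood-ratio test for the genotype term.
Because a single binary factor saturates the two group proportions, the
LRT reduces exactly to a G-test on the aggregated 2×2 table; replicates
enter through their summed counts, which is identical to modeling them
as separate binomial observations.  Choices:

- Introns with total (pre+post) < 10 in either genotype are skipped
  (degenerate fits); there is no documented filter, so this is ours.
- A zero aggregate cell (complete separation) gets +0.5 on all four
  cells and is flagged `separation_adjusted`.
- q-values are BH across tested introns; q ≤ 0.01 is "significantly
  changed downstream transcription", with direction from the sign of the
  log-odds difference.
- The single-replicate design uses an exact two-sided binomial test of
  the treatment proportion against the control's observed proportion.
- Gene-level DEG calls use the any-significant-intron rule; DEG sets
  from independent comparisons are intersected, and heterochromatic-gene
  enrichment among the intersection is a Fisher test against the full
  gene universe.

The binomial model assumes the pre/post split within a sample is
multinomial thinning of one transcript pool.  Replicate-level expression
noise that hits pre and post *independently* would overdisperse the
proportion and inflate the test; with shared expression noise (the
realistic case, and what the generator produces) the test is calibrated.
A quasi-binomial option is the natural extension if real libraries show
proportion-level overdispersion.

## Inter-species divergence

K_A and K_S follow Nei–Gojobori (unweighted pathway counting):

- Site counts: each codon position contributes one site split by the
  fraction of single-nucleotide changes (excluding changes to stops)
  that are synonymous; counts are averaged between the two sequences.
- Differences: averaged with equal weight over all minimal substitution
  pathways between the two codons; pathways through stop codons are
  excluded and the weights renormalized (if all are excluded, all are
  used).  Codon columns with a gap or ambiguity in either row are
  skipped whole.
- Proportions are Jukes–Cantor corrected, d = −(3/4)ln(1 − 4p/3);
  p ≥ 3/4 raises a saturation error.

Ortholog screening keeps queries with exactly one candidate and with
≥ 80% of aligned columns in matching exon/intron annotation state.
Genes with K_S > 0.1 are discarded (K_S = 0.1 retained) so that only
well-behaved, recently diverged pairs enter group comparisons.

Intron divergence K_I is a raw p-distance over columns that are ungapped
in both species and not repeat-masked; no multiple-hit correction is
applied at these depths.  Only gap and masked columns are excluded —
gap-adjacent columns are kept.

The **group aggregate** K_A/K_S is (mean K_A)/(mean K_S).  With K_S
capped at 0.1, per-gene ratios are unstable as K_S → 0; the ratio of
means is robust and matches reporting a single value per group.  The
per-gene-mean alternative is available via `mode="mean_of_ratios"`.
Group differences are assessed by label permutation with a tail fixed
a priori (`alternative="greater"` when the first group is hypothesized
larger); fixing the tail keeps null p-values uniform.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of (parameters, seed) and write
formats that round-trip through `core_io`.

- **Annotation**: genes with 1–8 introns (exons 100–300 bp, introns
  150–400 bp); a configurable fraction (default 0.3) of multi-intron
  genes hosts a TE (250–400 bp) inside one intron (600–1000 bp, TE ≥ 100
  bp from each boundary), with the host ordinal drawn from a truncated
  geometric (p = 0.45) to emulate promoter-proximal TE accumulation.
  Simple repeats and intergenic TEs are sprinkled for the overlap
  taxonomy.
- **Methylome**: cytosines of each context at uniform 10–60 bp spacing;
  per-site latent levels are Beta with concentration 20 around
  context means — heterochromatic CG/CHG/CHH 0.9/0.6/0.1, euchromatic
  0.05/0.02/0.01; depth is Poisson (mean 20); non-conversion adds
  methylated reads at rate 1 − 0.995.  Heterochromatin is anchored on
  the intronic TE ± 40 bp of spreading, clipped to the intron — TE-
  nucleated heterochromatin with limited spreading, not wall-to-wall
  intron methylation.  Not emulated: mapping bias, strand-specific
  coverage, M-bias, CHH asymmetry, or heterochromatin outside introns
  (intergenic TEs are left euchromatic, which real genomes are not).
- **Counts**: gamma-Poisson with the expression factor shared between
  pre and post within a sample (shape 10, lognormal per-intron
  expression σ = 0.5); termination effects divide the mutant post-intron
  mean by the stated fold (default 10).
- **Expression atlas**: "specific" genes express in exactly one
  condition; "broad" genes are near-uniform with lognormal noise
  (σ = 0.25).
- **Ortholog pairs**: each codon position mutates synonymously with
  probability p_S·f and nonsynonymously with p_N·(1−f), where f is the
  position's synonymous-change fraction and p_S, p_N invert the JC
  correction of the target K_S and K_A = dN/dS × K_S; stops are never
  created.  Introns diverge per-column at the target rate; a contiguous
  masked block (20%) mutates 5× faster and must be excluded by the
  estimator.  Within-codon multiple hits are slightly mis-calibrated
  (classification shifts after the first hit), a < 2% effect at
  K_S ≤ 0.1.

Consequently, passing recovery tests demonstrate that the analysis chain
is correct and calibrated *under these generative assumptions*; they do
not certify performance on real libraries with mapping artifacts,
unmodeled covariates, or partial heterochromatin.

## Problem sizes and numerical conventions

The packaged end-to-end run simulates 200 genes (~2,000 sites per
context per chromosome), two count comparisons, and 60 ortholog pairs
per group at 100 codons — sizes chosen so a full run takes seconds while
every stage still exercises its statistics.  Recovery studies use 100
methylome seeds (40 genes each), 10 count seeds (1,000 introns each),
and 500 ortholog genes per group at 200 codons.  All coordinates are
0-based half-open internally (GFF3 converts at I/O); permutation
p-values carry the add-one correction; BH is the standard step-up;
floating-point output is written at 10 significant digits to keep reruns
byte-identical across platforms.

## Known limitations

- The domain rule's containment reading means a domain spilling a few bp
  over an exon boundary un-flags the intron; real boundary behavior is
  not documented and the overlap mode is provided for sensitivity
  analysis.
- The high-coverage cutoff (100) is a fixed default, not data-derived.
- The location taxonomy ranks `exon-intron` above `exon/intron` when a
  TE qualifies as both across variants; the opposite priority is
  defensible.
- `group_rate_summary` reports NaN for a group whose mean K_S is 0.
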