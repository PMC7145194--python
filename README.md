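# intronhet

Analysis toolkit for **intronic heterochromatin** in plant genomes:
from per-cytosine bisulfite counts to heterochromatic-domain calls,
intron/TE overlap classification, premature-termination tests, and
inter-species substitution-rate comparisons — with a ground-truthed
synthetic-data generator so every stage is testable without sequencing
data.

## The problem

In large plant genomes (rice being the canonical case), transposable
elements inside introns can nucleate *heterochromatin* — detected as
dense CHG-context DNA methylation — while the host gene stays
transcriptionally active.  Characterizing these heterochromatic introns
requires a chain of analyses:

1. **Methylcytosine calling.**  Per site, methylation level is
   #C/(#C+#T); a cytosine is methylated if the upper-tail binomial
   probability of its methylated reads under the bisulfite
   non-conversion rate (estimated from the unmethylated chloroplast)
   survives Benjamini–Hochberg at q ≤ 0.05, within its context, after a
   3–100× coverage filter.
2. **Domain calling.**  A heterochromatic domain is a run of ≥ 5
   consecutive called CHG methylcytosines with mean level ≥ 0.5; an
   intron containing such a domain is heterochromatic.
3. **Positional and overlap statistics.**  Heterochromatic introns are
   tested for 5′ (promoter-proximal) bias with a subset-resampling
   permutation test on intron ordinals; TEs are classified as
   intergenic / intron / exon / exon-intron / exon/intron / other, and
   gene-set enrichments use exact Fisher tests.
4. **Premature termination.**  In mutants of the transcription factor
   that licenses transcription through intronic heterochromatin
   (IBM2-type), reads downstream of a heterochromatic intron drop.  Per
   intron, the post/(pre+post) read proportion is compared between
   genotypes with a binomial logistic model and a likelihood-ratio
   test; q ≤ 0.01 flags changed downstream transcription.
5. **Molecular evolution.**  Per ortholog pair, K_A and K_S by the
   Nei–Gojobori method (pathway-averaged differences, Jukes–Cantor
   correction), K_S > 0.1 discarded, intron divergence K_I as p-distance
   over unmasked ungapped columns, and group contrasts (heterochromatic
   vs normal genes) by label permutation on the (mean K_A)/(mean K_S)
   aggregate.

`docs/methods.md` documents every model, default and design decision.

## Worked example

Run the packaged 200-gene simulation end to end (simulate → call
methylation → call domains → classify → test):

```
intronhet run-all --out runs/demo --seed 7
```

or equivalently from Python:

```python
from intronhet.pipeline import PipelineConfig, run_end_to_end
manifest = run_end_to_end(PipelineConfig(seed=7), "runs/demo")
```

`runs/demo/enrichment.json` then contains (numbers printed by the run
above):

```json
{
 "conversion_rate": 0.9952372375978067,
 "mean_ordinal_all": 3.374307862679956,
 "mean_ordinal_het": 2.0588235294117645,
 "n_domains": 51,
 "n_heterochromatic_introns": 51,
 "position_permutation_p": 9.999000099990002e-05
}
```

Reading: the bisulfite conversion rate recovered from the control contig
is 99.5% (truth: 99.5%); 51 CHG domains were called and all 51 fell
inside introns; heterochromatic introns sit at mean ordinal 2.06 versus
3.37 for all introns, and the permutation test rejects a random
positional assignment at the smallest p reachable with 10⁴ permutations
(p = 1/(10⁴+1)) — the simulated 5′ bias is detected.  The divergence
stage of the same run reports group aggregates K_A/K_S = 0.505 (het)
vs 0.366 (normal) and mean K_I = 0.0328 vs 0.0243
(`runs/demo/divergence_groups.tsv`), recovering the simulated relaxation
of constraint in heterochromatic genes, with permutation p = 0.0087 at
this 57-genes-per-group scale.

Rerunning the same command reproduces every artifact byte-for-byte; the
`manifest.json` checksums make this auditable.

## Layout

- `src/intronhet/core_io.py` — gene models, intron derivation with
  5′-based ordinals, binning, GFF3/BED/cytosine-report I/O
- `src/intronhet/methylation.py` — conversion rate, coverage filter,
  binomial methylcytosine calls, region summaries
- `src/intronhet/domains.py` — CHG domain caller, intron/gene
  classification, positional distributions
- `src/intronhet/te_overlap.py` — repeat/MITE hit filters, TE location
  taxonomy, orientation test, methylation classes, overlap Venn
- `src/intronhet/stats.py` — permutation/Fisher tests, ROKU-style
  entropy, rank-sum effect size, TPM
- `src/intronhet/ratio_test.py` — pre/post-intron logistic and binomial
  tests, DEG intersection
- `src/intronhet/evolution.py` — Nei–Gojobori K_A/K_S, intron
  p-distance, ortholog screening, group permutation tests
- `src/intronhet/synthetic_data.py` — ground-truthed generators for all
  of the above
- `src/intronhet/pipeline.py`, `cli.py` — end-to-end orchestration and
  the `intronhet` command
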