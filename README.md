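# mndkit

Mitonuclear discordance (MND) analysis for admixed cohorts: from
per-haplotype local-ancestry calls and mtDNA haplogroup assignments to
gene-wise and gene-set-averaged discordance statistics, intergenerational
change (delta-MND) in mother-offspring pairs, and cohort-comparison
statistics — plus a synthetic-cohort simulator with known ground truth for
end-to-end testing.

MND is the fraction of a sample's nuclear local-ancestry calls (within
nuclear-encoded mitochondrial genes) that do not match the continental
ancestry of its mtDNA haplogroup. The per-sample statistic averages
gene-wise MND, unweighted, over a gene set (all mitonuclear / OXPHOS /
high-mt / low-mt); delta-MND is
`(MND_offspring - MND_mother) / MND_mother`.

## Layout

| module | role |
|---|---|
| `mndkit.ancestry_io` | read/write local-ancestry VCF (FORMAT `AN1`/`AN2`), gene BED4, gene-set TSV, haplogroup TSV, pair TSV; in-memory data model |
| `mndkit.haplogroups` | haplogroup → macrohaplogroup collapse (longest-prefix rules), macro → continental ancestry mapping |
| `mndkit.mnd_core` | gene-wise MND, per-sample gene-set means, global ancestry from local-ancestry averages, global MND, delta-MND |
| `mndkit.cohort_stats` | group summaries, ANOVA / Kruskal-Wallis omnibus, Bonferroni-corrected pairwise t / Mann-Whitney tests, Cohen's d (RMS or pooled sd), F / Levene variance tests, Spearman correlation |
| `mndkit.simulate` | Dirichlet ancestry proportions, Poisson admixture-tract haplotypes, maternal mtDNA draw, meiosis-based mother-offspring pairs |
| `mndkit.cli` | `mndkit simulate | compute | delta | compare` |
| `mndkit.plots` | simple reproducible boxplots |

## CLI quick start

```sh
# 1. synthetic cohort (ground truth in truth.tsv)
mndkit simulate --seed 7 --n-individuals 50 --n-pairs 10 --out-dir sim/

# 2. per-sample MND tables, one per gene set
mndkit compute --vcf sim/ancestry.vcf --bed sim/genes.bed \
    --sets sim/gene_sets.tsv --haplogroups sim/haplogroups.tsv \
    --out-dir mnd/

# optionally restrict to the A-D macrohaplogroups:
#   --restrict-macros A,B,C,D

# 3. intergenerational delta-MND
mndkit delta --mnd-table mnd/mnd_all_sets.tsv --pairs sim/pairs.tsv \
    --gene-set all_mitonuclear --out-dir delta/

# 4. cohort comparison (needs a TSV with sample_id and group columns)
mndkit compare --mnd-table mnd/mnd_all_sets.tsv --groups groups.tsv \
    --gene-set all_mitonuclear --out-dir report/
```

Every subcommand writes a `run_manifest.json` and an exclusion log next to
its outputs; exit codes are 0 (ok), 1 (validation error), 2 (runtime
error). Runs are deterministic given `--seed` and a fixed config.

## Input formats

- **local-ancestry VCF** — VCFv4.2 with integer FORMAT fields `AN1`/`AN2`
  (per-haplotype ancestry codes) and the panel declared in a header line
  `##ANCESTRY=<NAT=0,EUR=1,AFR=2>` (the code-first dialect
  `##ANCESTRY=<0=NAT,...>` is also accepted, as is `--panel NAT,EUR,AFR`
  when the header line is absent). Missing calls (`.`) are excluded from
  numerators and denominators.
- **genes** — BED4 (`chrom start end gene_id`, 0-based half-open). A site
  at 1-based position `p` belongs to a gene iff `start <= p-1 < end`.
- **gene sets** — TSV with `gene_id in_all in_oxphos in_high_mt in_low_mt`
  0/1 flags; OXPHOS / high-mt / low-mt must be subsets of all-mitonuclear,
  high-mt and low-mt disjoint.
- **haplogroups** — TSV with `SampleID` and `Haplogroup` columns
  (Haplogrep-style; extra columns ignored).
- **pairs** — TSV with `mother_id`, `offspring_id`, optional `cohort`.

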