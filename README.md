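# ribovar

Variant analysis for the multi-copy human ribosomal DNA (rDNA) locus:
within-individual variant-frequency calling from short reads, per-region
rare-variant burden, twin-based heritability, and covariate-adjusted
trait association — plus a fully seeded synthetic-cohort simulator so the
whole stack can be exercised and validated without biobank access.

## The problem

The 45S rDNA unit (18S, 5.8S and 28S rRNA genes) is present in hundreds
of near-identical tandem copies on the five human acrocentric
chromosomes. Standard diploid variant callers do not apply: a short read
cannot be placed on a chromosome, and a "genotype" is really a
*frequency* — the fraction of an individual's rDNA copies carrying a
variant. Sequence variation concentrates in hyper-variable expansion
segments (ESs) of the rRNA; abundant variants (ribosome subtypes) are
largely germline and heritable, while low-abundance variants are largely
somatic.

`ribovar` works against an **atlas**: each 18S/28S subunit is tiled into
ES / non-ES regions, each region carries a set of observed alleles
(variant combinations spanning the region), and each allele sequence is
extended with up to 150 bp of non-variant reference flank so that 150-bp
reads can align. A per-region **lookup table** maps each allele to the
single-nucleotide variants it carries (keys like `4913:C:T` or the
left-anchored indel `2177:G:GTG`, 1-based on the subunit).

## The method

**Frequency calling.** Reads are mapped by exact substring search
against the extended allele sequences (only perfect, gapless alignments
are ever counted, so an internal perfect-match index replaces an
external aligner; SAM from `bwa mem -a` can be ingested and re-verified
instead). Per-allele read counts are converted through the lookup table:

    freq(v) = sum of counts of alleles carrying v / total reads mapped to the region

A `quality_masked` mode treats read positions with base quality <= 20 as
wildcards (no gaps, all high-quality bases must agree).

**Rare-variant burden.** Per region and participant, with u_a the
unique-mapper count of allele a:

1. keep alleles with at least 2 unique mappers cohort-wide (A-bar);
   collapse the indistinguishable rest onto the most atlas-abundant
   excluded allele, recount unique mappers as u+;
2. exclude regions whose cohort-median read depth is below 30;
3. pi_a = u+_a / sum(u+); allele copy number c_a = pi_a x c45S, where
   c45S is the individual's rDNA copy number proxied by its rDNA read
   fraction; entries with c_a < 1 copy are zeroed as somatic noise, and
   the rest renormalized to pi*;
4. MAF = max_a pi*_a (the region's most common resolved allele) and
   burden = 1 − MAF.

**Heritability.** Monozygotic twins are pairs with kinship > 0.4
(parent-offspring: kinship in [0.17, 0.35] and birth years > 18 years
apart; trios are assembled from these). Heritability of a variant is the
Spearman correlation of its frequency across twin pairs; variants with
R > 0.8 are classified heritable. Diagnostics: the correlation between
twin-correlation and read depth (GC-coverage confound), pairwise linkage
of heritable variants, and per-variant correlation with rDNA copy
number.

**Association.** OLS for quantitative traits, maximum-likelihood
logistic regression for disease indicators (statsmodels), controlling
for age, sex, age x sex, age², rDNA copy number, 20 genetic PCs and
one-hot sequencing batches; the logistic path z-scores the predictor and
continuous covariates. Diseases with fewer than 30,000 cases (6%
prevalence at biobank scale) are skipped; significance is Bonferroni at
alpha / (variants x independent traits); QQ data and the
genomic-control lambda summarize calibration. Non-converged fits are
excluded, never zeroed.

## Worked example

Everything below is synthetic and driven by one seed:

```bash
ribovar simulate --seed 11 --out sim --participants 8 --twin-pairs 3 \
    --regions 3 --depth 1200
# simulated 8 participants (3 twin pairs), 3 regions
ribovar freq --atlas sim/atlas --reads-dir sim/reads --out freq
# 8 participants x 19 variants; 19 low-depth variants
ribovar twins --freq freq/variant_frequencies.tsv --kinship sim/kinship.tsv \
    --depth freq/variant_depth_stats.tsv --out twins
# 3 twin pairs; 15 heritable variants (Spearman R > 0.8)
ribovar burden --atlas sim/atlas --reads-dir sim/reads \
    --copy-number sim/copy_number.tsv --out burden
# 24 (participant, region) burden rows
```

`freq/variant_frequencies.tsv` holds participants x variant keys (a cell
is the fraction of that participant's rDNA copies carrying the variant;
NA means the region was unobserved). All 19 variants are flagged
low-depth here because the demo cohort is sequenced far below the 5,000
reads-per-variant threshold meaningful at biobank scale.
`twins/heritability.tsv` gives per-variant twin Spearman correlations —
with only 3 demo pairs germline variants sit at R = 1:

```
variant  twin_spearman  n_pairs  mean_depth  heritable
109:C:T  1.0            3        121.6       True
```

`burden/region_burden.tsv` gives per (participant, region) MAF and
burden, e.g. `P0001 r01 ES maf=0.4375 burden=0.5625` — r01 is a
hyper-variable region where the most common resolved allele covers only
44% of this participant's copies.

The library surface mirrors the CLI (`ribovar.atlas`, `.mapper`,
`.frequency`, `.burden`, `.twins`, `.association`, `.simulate`,
`.io`); see docstrings and `docs/methods.md`.

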