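# Methods

This note documents the models, conventions, numerical choices and known
limitations of `ribovar`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinate and variant conventions

Subunit coordinates are 1-based inclusive everywhere in memory and in
TSV output; BED files on disk are 0-based half-open and converted on
read. Variants are VCF-style: SNVs as `position:ref:alt`, indels
left-anchored with one shared reference base (`2177:G:GTG` inserts TG
after the G at 2177). Variant sets derived from allele sequences use
Needleman–Wunsch global alignment (Biopython `PairwiseAligner`, match 2,
mismatch −3, gap open −5, extend −1) followed by standard left-shift
normalization against the subunit sequence, so a given allele always
yields one canonical variant list. Substitution runs are split into
individual SNVs; each gap run becomes a single anchored indel.

## Perfect-match mapping

Because only alignments with no mismatches (at high-quality positions)
and no gaps are ever counted, read mapping is exact substring search,
implemented as a k-mer seed (k = 31, configurable) plus verification on
both strands. Results are therefore exactly equal to a brute-force
sliding-window scan, which the tests assert on random instances; the
scan implementation is kept in the package as the permanent oracle
(`mapper.brute_force_map`). In `quality_masked` mode, positions with
base quality <= 20 are wildcards; the seed is taken from a clean
high-quality k-mer when one exists, otherwise the scan falls back to a
regex sweep. Soft-clipped or gapped SAM records are rejected on ingest,
and every ingested alignment is re-verified against the allele sequence
(trust-but-verify), so SAM input and the internal mapper agree by
construction.

A read is a *unique mapper* when its hits touch exactly one allele
across **all** regions; hitting one allele at several offsets counts
once; hits in two regions make it a multi-mapper.

## Region geometry and an intrinsic ambiguity

Regions tile each subunit, and every allele is extended with up to
150 bp of non-variant reference flank (truncated at subunit ends, and
identical across the alleles of a region). A consequence worth stating
plainly: a region's flank overlaps its neighbours' extents, so a 150-mer
of pure reference sequence lying near a region boundary matches the
reference context of more than one atlas entry and is *inherently* a
multi-mapper. Only windows that either cover a variant position or lie
more than a read length away from any other entry's extent can be
unique. This is a property of the atlas design, not of the mapper; the
validation experiments therefore place diagnostic variant sites more
than 150 bp inside region cores (frequency recovery) or draw reads from
variant-carrying alleles (lookup-conversion exactness), and real
analyses should expect reference-allele support to be carried
disproportionately by interior windows.

## Counting policies and their biases

Three multi-mapper policies are provided. `fractional` (default) splits
a read with k tied alleles 1/k each, conserving read counts and matching
a denominator of "all reads mapped to the region"; but uninformative
reads (flank or shared-sequence windows) then pull every allele toward
the uniform 1/k, so rare-allele frequencies are biased upward when many
reads are uninformative. `unique_only` drops all multi-mappers and is
unbiased whenever alleles are equally distinguishable (it is also the
convention of the burden algorithm). `all_hits` credits every hit in
full (an all-alignments aligner tally; not count-conserving). The policy
is a logged switch; recovery experiments use `unique_only`.

## Burden algorithm

Per region: cohort support filter A-bar = {a : sum_p u_ap >= 2}
("at least 2 unique mappers across the entire cohort"; the >= semantics
follow the stated rule, a strict > variant is available via
`min_support`). Excluded alleles are collapsed onto the single most
atlas-abundant one (ties by allele id); reads all of whose hits fall
outside A-bar within one region become unique mappers credited to that
representative; reads mixing supported and excluded alleles remain
multi-mappers (conservative). Collapsing can only add unique mappers —
a property the tests check — and with `min_support = 0` the pipeline
reduces exactly to plain unique-mapper counting.

Segment depth defaults to per-base coverage,
d = sum(u+) x read_length / L_s, with the literal reads-over-length
ratio available as `count_per_base`; the per-base form is the default
because a "read depth" threshold of 30 is a coverage-scale quantity for
150-bp reads over few-hundred-base segments. Regions with cohort-median
depth < 30 are masked to NA (flagged, not dropped silently).

Copy-number-scaled zeroing: c_a = pi_a x c45S; entries below 1 copy
(configurable `zero_threshold`) are set to zero — an allele estimated at
less than one copy per genome is read noise or a low-frequency somatic
clone — and the remainder renormalizes to pi*. All-zero regions are
flagged `unresolved`. MAF = max pi*; burden = 1 − MAF. The `c45S` input
is the read-fraction proxy times a calibration constant supplied by the
caller; the package does not estimate the constant.

## Twins and heritability

MZ pairs: kinship > 0.4 (strict), deduplicated greedily by descending
kinship so a participant appears in at most one pair. Parent-offspring:
kinship in [0.17, 0.35] inclusive and birth-year gap > 18 years; trios
are children with two distinct parents that are not parent-offspring
with each other. Heritability is reported directly as the per-variant
Spearman correlation across twin pairs (no Falconer-style transform);
pair orientation is randomized once under a logged seed, which cannot
change the value (Spearman is exchange-symmetric) but guards against
accidental ordering conventions downstream. Variants with fewer than 3
informative pairs get a missing value. The depth-confound diagnostic
reports the Pearson correlation between twin-correlation and mean
variant depth before and after dropping variants below 5,000 mean reads.

## Association models

Design matrix: intercept, predictor, age, sex, age x sex, age², rDNA
copy number, PCs (as many `pc1..pc20` columns as supplied), and one-hot
batches with the lexicographically first level as reference. The
logistic path z-scores the predictor and continuous covariates; the
linear path fits on the raw scale. Complete-case analysis per
(predictor, trait) pair; no imputation. Rank deficiency is logged;
singular or non-converged fits (including complete separation) are
returned with `converged=False` and excluded from significance
tabulation, keeping attempted = reported + non-converged.

Bonferroni uses alpha / (n_variants x n_independent_traits). The
default independent-trait count is the raw column count (maximally
conservative); an eigenvalue-based effective number (Li–Ji style,
sum of I(lambda >= 1) + frac(lambda) over trait-correlation
eigenvalues, with near-integer eigenvalues snapped to avoid floor()
round-off) is available but never silently used. The disease filter
keeps codes with >= 30,000 cases, or >= 6% prevalence when the cohort
size is given — the same rule at smaller scale. QQ output uses expected
quantiles −log10((i − 0.5)/m) and lambda_GC as the median implied
chi-square(1) over its null median; zero p-values are clamped to the
smallest positive float with a warning.

## Synthetic cohorts

The simulator emulates the structure the analyses assume: a subunit
tiled by alternating ES / non-ES regions of 220–320 bp; per region one
reference allele, germline alleles with Dirichlet atlas abundances, and
somatic-only alleles (abundance 0) reachable only by injection; per
participant ~Normal(400, 40) copies of the unit (hundreds of tandem
copies, floored at 50); germline copy compositions drawn
Dirichlet-multinomial around atlas abundances (concentration 8, enough
inter-individual variation for twin correlations to be informative);
monozygotic twins share the germline composition and copy number
exactly and differ only by somatic injection and read sampling; somatic
conversion is per-copy Bernoulli (default rate 0.004), optionally
coupled to copy-number deviation for the copy-number-correlation
diagnostic. Truth tables (copy compositions, variant frequencies,
burden, covariates) are always produced, so every downstream test is a
recovery test.

Reads are 150 bp, sampled from allele copies proportionally to copies x
usable start positions, uniform starts, random strand. Base qualities
are two-state (Q37 / Q10, low-quality fraction 0.02) with state-specific
error rates (default 5e-4 high-quality, 0.1 low-quality) — enough to
exercise quality masking without modelling full Phred profiles. GC bias
applies logistic rejection with acceptance sigmoid(−g (GC − 0.5)); at
g = 0 acceptance is uniform. Kinship tables place twins at
Normal(0.5, 0.02) and unrelated pairs below 0.08. Phenotypes are linear
in true variant frequencies (traits, Gaussian noise) or logistic in
true region burden (diseases, intercept solved for a target
prevalence). Everything derives from one integer seed, and outputs are
byte-identical across runs.

For cohort-scale statistical experiments a count-level sampler
(`sample_observed_frequencies`, `simulate_twin_frequency_study`)
applies Binomial(depth) sampling noise directly to true frequencies —
the distribution the read pipeline converges to with error-free
full-span reads — so twin studies with hundreds of pairs and thousands
of variants run in seconds. The read-level pipeline is validated at
smaller sizes: the mapper oracle on 1,000 reads x 50 alleles, frequency
recovery on 5 regions x 32,000 reads, the burden path on 8 participants
x 3 regions x 2,400 reads.

What the simulator does **not** model: realistic Illumina error
profiles, chromosome-of-origin and tandem-array structure,
Robertsonian translocations, PCR duplicates, and atlas curation errors.
Passing tests therefore demonstrate correctness of the algorithms under
the stated sampling models, not robustness to every artefact of real
sequencing data.

## Known limitations

- Novel variants absent from the atlas are never called; reads carrying
  them simply fail to map (by design).
- The fractional policy's uninformative-read dilution (above) means its
  output should not be read as an unbiased copy fraction when a region
  has few distinguishing positions.
- Heritability from twin correlation conflates measurement noise with
  somatic variation; the depth-confound diagnostic quantifies but does
  not remove the noise component.
- GC bias is diagnosed (via depth statistics) but not corrected.
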