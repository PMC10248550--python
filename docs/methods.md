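# Methods

## Problem setting

A quad-family design contrasts de novo single-nucleotide variants (dnSNVs)
in affected probands against unaffected siblings drawn from the same
families. Because both cohorts share the germline mutation machinery, the
sibling set is a matched control: any annotation category genuinely linked
to the phenotype should capture a larger *fraction* of proband dnSNVs than
sibling dnSNVs. The package implements the full chain from variant-level
quality control to the statistical post-mortem of a null result.

The reference cohort geometry used throughout defaults to 1,917 quad
families contributing 134,969 proband and 131,896 sibling autosomal
dnSNVs (medians of 70 and 68 per child).

## De novo identification and filtering

A site is a candidate de novo in a child iff the child carries ≥ 1 alt
allele and the mother, father, and other child carry none. The rule is
applied literally, so an allele shared by both children tags neither — at
the population mutation rate a genuine shared de novo is vanishingly rare
relative to a genotyping artifact, and dropping both is the conservative
choice. Sites with any missing member genotype are ineligible and counted.

Candidates then pass, in fixed order:

| Rule | Default | Meaning |
| --- | --- | --- |
| GQ | min member GQ ≥ 20 | genotype quality of all four members |
| DP | min member DP ≥ 10 | read depth of all four members |
| AC/AF | AC < 4 **and** AF < 0.001 | cohort allele count/frequency; requiring both implements "the more stringent of" the two at any cohort size |
| MAF | reference-panel MAF < 0.001, missing retained | population frequency; absence of a panel record is evidence of rarity, not of commonness |
| exclusion | drop overlaps | low-complexity / indel-proximal BED regions |
| recurrence | drop all carriers | a variant key seen in more than one child is treated as a shared artifact |

Every removal is attributed to exactly one rule in a `FilterReport` whose
arithmetic identity (input − removals = retained) is asserted at run time.
A homozygous-alt child at an otherwise de novo-patterned site is retained
(it satisfies the rule) but flagged as an implausible de novo in the
report. Upstream genotype refinement and recalibration are consumed, not
performed; a pass-through hook marks where they would sit. Family-level
exclusions are supplied as a blocklist file.

## Burden tests

For a category *C*, the 2×2 table counts proband/sibling dnSNVs inside and
outside *C* with cohort totals as fixed margins. The one-sided
(proband-excess) Fisher exact p-value is the hypergeometric upper tail
P(X ≥ k_p); the screen also reports the sample odds ratio and the relative
risk (k_p/N_p)/(k_s/N_s). For continuous scores the table is built from
membership in the top 5% of the **pooled** two-cohort score distribution
(the published procedure does not state the reference set; pooling keeps
the margins interpretable, and a per-cohort alternative would change the
margins themselves). The empirical quantile uses the "higher"
interpolation rule so the threshold is an observed score, and ties at the
threshold are all included — with pathological constant scores every
variant is a member, which is documented and tested rather than special-
cased. A one-sided Wilcoxon rank-sum test (tie-corrected, exact for small
untied samples) compares unthresholded score rankings.

Benjamini–Hochberg FDR adjustment is applied across the FET family of a
screen only; rank-sum p-values are reported raw alongside, matching how
score-rank comparisons are conventionally presented as a secondary,
separately-interpreted test.

## Power analysis

The modeled test is the arcsine two-proportion z-test, the estimand of
classical pwr-style power calculations:

    h = 2·arcsin(√p1) − 2·arcsin(√p2)
    power(n) = Φ( h·√(n/2) − z_{1−α} ),   α = 0.05, one-sided "greater".

Choices and conventions:

- **Per-group n** is the mean of the two cohort dnSNV totals at the given
  family count (133,432.5 at the reference size). The totals differ by
  ~2%, and using the proband total instead moves every reported quantity
  by well under its printed precision.
- **Family ↔ n mapping** is linear at the observed per-family rates
  (70.41 / 68.80 dnSNVs per proband/sibling child), configurable via
  `FamilyRateMap`.
- **Inversion**: published summaries print a category's starting power but
  not its sibling overlap count. `invert_power_for_p2` recovers the
  implied p₂ by Brent root-finding on the (strictly monotone) power
  function to |Δ| < 1e−12; all solvers are exact inverses of
  `power_two_prop` to that tolerance.
- **Forward**: n₈₀ = 2·((z₁₋α + z₀.₈)/h)²; family counts are rounded up.
- **Reverse**: holding n fixed, the smallest g ≥ 0 with
  power(p₁(1+g), p₂, n) = 0.80, again by Brent root-finding; the
  additional-variant count is p₁·g·N_p. A category already at or above
  target returns g = 0; a target unreachable before p₁(1+g) = 1 raises.

No exact (conditional or unconditional) Fisher power is computed: the
normal-approximation estimand is the modeled quantity, and the Monte-Carlo
suite verifies that simulated rejection rates of the arcsine test match it
within sampling error at n from 10³ to 10⁵.

## Permutation null

Proband/sibling labels are shuffled across all dnSNVs with fixed margins
(exactly N_p proband labels in every permutation, the literal label
shuffle; an independent-Bernoulli variant is deliberately not offered).
Each permutation conserves the total in-category count K, so the null
proband count is hypergeometric with mean K·N_p/N and variance
K·(N_p/N)·(N_s/N)·(N−K)/(N−1) — exposed as `hypergeom_moments` and used as
the analytic cross-check of the empirical null. The observed count is
scored as Z = (observed − null mean)/null SD with significance at Z ≥ 2;
a degenerate null (SD = 0, e.g. an empty category) yields a flagged NaN
rather than a value. Defaults: 10,000 permutations, mandatory recorded
seed.

## Call-set comparison

`CallSet` identity defaults to (chrom, pos, ref, alt) because published
cross-study variant lists lack child identifiers; (variant, child)
matching is available where both sets carry them. Mixing identity modes is
an error. `upset_counts` assigns every variant in the union to exactly one
exclusive membership pattern, so per-study totals are recoverable by
summing patterns — the partition identity is property-tested on random
sets.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical* structure the analyses consume:

- **Counts**: per-child dnSNV counts are Poisson at the observed
  per-family rates. Only medians are published; Poisson is the standard
  model for germline mutation counts, and the Poisson medians (70/68 at
  rates 70.41/68.80) match the printed medians. Overdispersion can be
  introduced by varying rates per family if needed.
- **Genome**: 22 synthetic autosomes of 10 Mb with unique uniform variant
  positions. Coordinates are arbitrary; no sequence context, trinucleotide
  spectrum, mutation-rate heterogeneity, or real-genome clustering is
  modeled.
- **Compartments**: multinomial with ~98.8% mass on intronic/intergenic
  (0.55/0.43), mirroring the reported ~98% noncoding fraction; coding
  0.012, 3′/5′ UTR 0.005/0.003.
- **Categories**: membership is Bernoulli per variant — p₂ for siblings,
  p₂(1+g) for probands — emitted as 1-bp intervals so interval overlap
  reproduces the planted truth exactly. Real annotations are spatially
  clustered; the Bernoulli model is exactly the sampling model of the
  power analysis, which is the point: passing calibration shows the
  statistics are correct under their own assumptions, not that real
  annotations behave this way.
- **Scores**: Uniform(0,1) under the null — rank-based tests are
  distribution-free, so the null shape is immaterial — with a location
  shift (default 0.01, the scale of reported disease-impact-score effects)
  applied to a configurable fraction of probands, clipped to [0,1].
- **Quad VCF fixtures**: planted site classes (true de novo, inherited,
  low-GQ, low-DP, high-AF, high-MAF, excluded-region, recurrent,
  missing-genotype) with clean GQ 60 / DP 30 elsewhere, each violating
  exactly one rule, so filter sensitivity/specificity and report
  attribution can be asserted exactly. INFO AC/AF emulate values computed
  on a much larger cohort, so a de novo singleton carries a realistically
  tiny AF regardless of fixture size.
- **Multi-study call sets**: each study drops true variants independently
  at a false-negative rate and adds never-shared spurious variants at a
  false-positive rate. FP independence is an explicit modeling assumption
  (it encodes the idea that study-unique calls are error-enriched), not a
  claim about real pipelines, whose errors correlate through shared
  sequencing data.

All generators are pure functions of (config, seed).

## Numerical choices and degenerate inputs

- Coordinates: variant positions 1-based, intervals 0-based half-open;
  a position p overlaps (start, end) iff start < p ≤ end, converted in a
  single code path. Intervals are merged per chromosome, so overlap
  queries are order-independent binary searches.
- FET on an empty category (no in-category variants at all) returns p = 1
  by convention and logs; relative risk with a zero sibling count is NaN.
- Rank-sum on two identical constant samples returns 0.5 (no directional
  evidence) instead of a tie-corrected division by zero.
- BH adjustment preserves input order and is capped at 1.
- Root-finding brackets are [0, p₁] for inversion and [0, 1/p₁ − 1] for
  the reverse solve; both functions are strictly monotone on the bracket.

## Problem sizes used by the test suite

The suite runs everything at desk scale by choice of cohort size rather
than by weakening assertions: unit and property tests use 20–150-family
cohorts (~3k–21k variants); one session-scoped cohort at the full
reference size (1,917 families, ~267k variants) backs the
structure-matching tests; calibration suites use 1,000 replicates
(binomial 95% CI ±1.35 percentage points around α = 0.05); the FET oracle
sweep enumerates all ~320k 2×2 tables with N_p + N_s ≤ 60.

## Known limitations

- Power is computed for the normal-approximation two-proportion test, not
  for Fisher's exact test; at cohort-scale counts the difference is
  negligible, at very small counts FET is conservative relative to it.
- The filter consumes refined genotypes; no genotype-likelihood modeling,
  phasing, or mosaicism handling.
- No genome-build liftover, FASTA access, or tabix indexing; inputs are
  desk-scale text files.
- The synthetic generator does not emulate sequence-context mutation
  models or spatially structured annotations (see above), so calibration
  results certify the statistics, not the biology of real annotations.
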