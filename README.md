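# dnvscreen

Burden testing and power analysis for **de novo single-nucleotide variants
(dnSNVs)** in quad families (two parents, one affected proband, one
unaffected sibling).

Studies of complex neurodevelopmental disorders such as autism spectrum
disorder ask whether probands carry an excess of de novo mutations inside
particular genomic annotation categories — enhancers, promoters, coding
consequence classes, or the top tail of machine-learned variant
prioritization scores. Most such screens come up empty, and `dnvscreen`
packages the toolkit needed to understand why: it quantifies how much of
the failure is sample size, how much is annotation quality (effect size),
and how much is the reliability of the dnSNV call set itself.

The package is aimed at statistical geneticists designing or auditing
de novo burden studies. It provides:

- **De novo filtering** — candidate tagging from a quad VCF (child carries
  the allele, no other family member does) with GQ/DP/allele-count/
  allele-frequency/MAF thresholds, exclusion-region filtering, and
  cross-individual recurrence removal, with a full per-rule audit report.
- **Burden testing** — one-sided Fisher's exact tests on 2×2 tables of
  cohort × in/out-of-category counts, relative risk, top-5% score
  thresholding, Wilcoxon rank-sum tests on unthresholded scores, and
  Benjamini–Hochberg FDR control across the screen.
- **Power analysis** — forward and reverse power on the arcsine
  two-proportion test. With Cohen's effect size
  *h* = 2 arcsin √p₁ − 2 arcsin √p₂, one-sided power at per-group size *n* is
  Φ(*h*·√(n/2) − z₁₋α). The *reverse* analysis holds *n* fixed and solves for
  the relative inflation *g* of the proband proportion (p₁ → p₁(1+g))
  required to reach 80% power — an "annotation quality" metric.
- **Permutation testing** — a label-shuffling null (proband/sibling labels
  permuted across all dnSNVs, margins fixed) with Z-scores against the
  empirical null, plus the closed-form hypergeometric moments as an
  analytic cross-check.
- **Call-set comparison** — intersection/union/disjoint algebra and
  exclusive membership-pattern (UpSet) counts across studies' variant sets.
- **Synthetic data** — quad-family cohorts, planted annotation categories
  with known effect sizes, synthetic score columns, quad VCF fixtures with
  per-site planted truth, and multi-study call sets with independent
  false positives, so the whole pipeline runs without restricted data.

## Worked example

How much more informative would the best-performing noncoding annotation
(brain-specific TURF scores, 6,828 proband dnSNVs observed in the top 5%,
starting power 0.32 at 1,917 quad families) need to be to reach 80% power
without adding families?

```python
from dnvscreen.power import reverse_power_from_observed, families_from_observed
from dnvscreen.reference import REFERENCE_RATES

res = reverse_power_from_observed(6_828, starting_power=0.32, rates=REFERENCE_RATES)
print(f"increase {res.increase_pct:.2f}%  extra {res.extra_variants:.0f}  p2={res.p2:.4f}")
# increase 2.21%  extra 151  p2=0.0496

print(families_from_observed(1_806, 0.14, REFERENCE_RATES))
# 37189
```

The first call inverts the printed starting power to recover the implied
sibling in-category proportion (p₂ ≈ 0.0496), then root-finds on the power
function: the proband overlap proportion would need to rise by ~2.2%
(about 151 additional in-category proband variants) for the one-sided
two-proportion test to reach 80% power at the present cohort size. The
second call answers the forward question for the fetal-brain-promoter
category: ~37,000 quad families would be needed at its observed effect
size — the "just add samples" strategy is far more expensive than a
modestly better annotation.

The same analyses are available from the shell:

```bash
dnv power reverse --observed 6828 --start-power 0.32
dnv pipeline --families 200 --excess 0.5 --seed 1 --out run/
dnv reproduce
```

`dnv pipeline` chains the synthetic stages end to end (quad VCF → filter →
cohort → enrichment screen → permutation null); `dnv reproduce` recomputes
every published power-analysis number from printed constants and exits
non-zero if any misses its documented tolerance.

## Layout

| Module | Contents |
| --- | --- |
| `dnvscreen.variants` | `VariantKey`, `VariantRecord`, `VariantTable` (TSV round-trip) |
| `dnvscreen.intervals` | `IntervalSet`, BED parsing, point-overlap queries, promoter windows |
| `dnvscreen.callsets` | `CallSet` algebra, UpSet membership-pattern counts |
| `dnvscreen.vcfio` | quad VCF + PLINK PED ingestion |
| `dnvscreen.filtering` | de novo tagging, quality filters, exclusion, recurrence dedup |
| `dnvscreen.simulate` | synthetic cohorts, categories, scores, quad VCFs, call sets |
| `dnvscreen.enrichment` | FET, relative risk, top-5% thresholding, rank-sum, BH-FDR |
| `dnvscreen.power` | Cohen's h, power, inversion, sample-size and reverse-power solvers |
| `dnvscreen.permutation` | label-shuffle null, Z-scores, hypergeometric moments |
| `dnvscreen.cli` | the `dnv` command-line interface |

See `docs/methods.md` for the statistical model, assumptions, and design
choices.
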