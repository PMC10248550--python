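"""Published summary constants of the 1,917-quad-family SSC dnSNV screen.

These are the printed cohort-level numbers the power analyses are anchored
to: cohort dnSNV totals, and per-category observed proband overlap counts
with their reported starting powers and the reported reverse-power /
sample-size solutions. They are inputs (and, for the ``reproduce`` driver,
comparison values) — never substitutes for computation.
"""

from __future__ import annotations

from dataclasses import dataclass

from dnvscreen.power import FamilyRateMap

#: Cohort geometry: 1,917 quad families, 134,969 proband and 131,896
#: sibling autosomal dnSNVs.
REFERENCE_RATES = FamilyRateMap(families_ref=1_917, n_p_ref=134_969, n_s_ref=131_896)

MEDIAN_DNSNV_PROBAND = 70
MEDIAN_DNSNV_SIBLING = 68


@dataclass(frozen=True)
class CategoryBenchmark:
    """One annotation category's printed power-analysis summary."""

    name: str
    observed_proband: int  # proband dnSNVs in category (top 5% for scores)
    starting_power: float  # reported power at the reference cohort size
    reported_increase_pct: float | None = None  # reverse power: % increase for 80%
    reported_extra_variants: int | None = None  # reverse power: additional variants
    reported_families: int | None = None  # forward: families for 80% power
    families_is_lower_bound: bool = False


BRAIN_TURF = CategoryBenchmark(
    name="TURF brain-specific (top 5%)",
    observed_proband=6_828,
    starting_power=0.32,
    reported_increase_pct=2.2,
    reported_extra_variants=150,
)

GENERIC_TURF = CategoryBenchmark(
    name="TURF generic (top 5%)",
    observed_proband=7_370,
    starting_power=0.12,
    reported_increase_pct=3.2,
    reported_extra_variants=240,
    reported_families=50_000,
    families_is_lower_bound=True,
)

FETAL_BRAIN_PROMOTER = CategoryBenchmark(
    name="Fetal brain promoters",
    observed_proband=1_806,
    starting_power=0.14,
    reported_increase_pct=6.5,
    reported_extra_variants=117,
    reported_families=37_000,
)

REVERSE_POWER_BENCHMARKS = (BRAIN_TURF, GENERIC_TURF, FETAL_BRAIN_PROMOTER)

#: Coding burden counts: predicted loss-of-function coding mutations and
#: the stop-gain subset (proband vs sibling).
LOFCM_COUNTS = (604, 467)
STOPGAIN_COUNTS = (120, 62)

#: Comparison tolerances used by the ``reproduce`` driver: the printed
#: values carry ~ two significant figures, so recomputed increases must
#: match within 0.15 percentage points, extra-variant counts within 5,
#: and family counts within 10% (lower bounds checked as bounds).
TOL_INCREASE_PCT = 0.15
TOL_EXTRA_VARIANTS = 5
TOL_FAMILIES_REL = 0.10
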