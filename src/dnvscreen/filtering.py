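"""Candidate de novo SNV tagging and quality filtering.

A variant is tagged as a candidate de novo in a child when that child
carries at least one alt allele while the mother, the father, AND the other
child carry none — "present in a child and not any of the other family
members". The quoted rule is applied literally, so a variant shared by both
children of a quad is tagged in neither.

Candidates then pass, in fixed order, the site-quality filters (minimum
member GQ and DP, cohort allele count/frequency caps applied jointly as
the more stringent reading, and a population-MAF cap with missing MAF
retained), region exclusion against low-complexity/indel-proximal BED
files, and removal of recurrent variants seen in more than one child.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dnvscreen.intervals import IntervalSet
from dnvscreen.variants import CORE_COLUMNS, VariantTable
from dnvscreen.vcfio import ROLES, SiteGenotypes

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for dnSNV quality filtering.

    ``ac_max`` is exclusive (retain AC < ac_max) and ``af_max``/``maf_max``
    are exclusive caps; requiring AC and AF jointly implements "the more
    stringent of" the two at any cohort size. ``keep_missing_maf`` retains
    variants with no reference-panel frequency.
    """

    gq_min: int = 20
    dp_min: int = 10
    ac_max: int = 4
    af_max: float = 0.001
    maf_max: float = 0.001
    keep_missing_maf: bool = True
    drop_recurrent: bool = True

    def __post_init__(self) -> None:
        if self.gq_min < 0 or self.dp_min < 0 or self.ac_max < 0:
            raise ValueError("thresholds must be non-negative")
        for name in ("af_max", "maf_max"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class FilterReport:
    """Audit trail: candidates removed per rule, in application order."""

    n_input_sites: int = 0
    n_ineligible_missing_gt: int = 0
    n_non_biallelic_snv: int = 0
    n_candidates: int = 0
    removed: dict[str, int] = field(default_factory=dict)
    n_implausible_homalt: int = 0
    retained_proband: int = 0
    retained_sibling: int = 0

    @property
    def retained(self) -> int:
        return self.retained_proband + self.retained_sibling

    def check_arithmetic(self) -> bool:
        return self.n_candidates - sum(self.removed.values()) == self.retained

    def to_frame(self) -> pd.DataFrame:
        rows = [("candidates", self.n_candidates)]
        rows += [(f"removed_{rule}", n) for rule, n in self.removed.items()]
        rows += [
            ("retained_proband", self.retained_proband),
            ("retained_sibling", self.retained_sibling),
            ("ineligible_missing_gt", self.n_ineligible_missing_gt),
            ("non_biallelic_snv", self.n_non_biallelic_snv),
            ("implausible_homalt_flagged", self.n_implausible_homalt),
        ]
        return pd.DataFrame(rows, columns=["step", "count"])


def genotype_refinement_hook(sites: list[SiteGenotypes]) -> list[SiteGenotypes]:
    """Placeholder for upstream genotype refinement / recalibration.

    The pipeline consumes VCFs that have already been refined and
    recalibrated; this pass-through marks where such a step would sit if a
    raw call set were supplied.
    """
    return sites


def tag_candidate_denovo(site: SiteGenotypes) -> list[str]:
    """Return the cohort roles ('proband'/'sibling') tagged de novo at a site.

    A child is tagged iff it carries >=1 alt allele and the three other
    family members carry 0. Any missing member genotype makes the site
    ineligible (empty list; counted separately by the caller).
    """
    if not site.complete:
        return []
    counts = {r: site.members[r].alt_count for r in ROLES}
    tagged = []
    for child, other in (("proband", "sibling"), ("sibling", "proband")):
        if (
            counts[child] >= 1
            and counts["mother"] == 0
            and counts["father"] == 0
            and counts[other] == 0
        ):
            tagged.append(child)
    return tagged


def _site_filter_failures(site: SiteGenotypes, cfg: FilterConfig, maf: float | None) -> str | None:
    """First violated rule name in fixed order (GQ, DP, AC/AF, MAF), else None."""
    gq = site.min_gq()
    if gq is None or gq < cfg.gq_min:
        return "gq"
    dp = site.min_dp()
    if dp is None or dp < cfg.dp_min:
        return "dp"
    if not (site.ac < cfg.ac_max and site.af < cfg.af_max):
        return "ac_af"
    if maf is None or (isinstance(maf, float) and math.isnan(maf)):
        if not cfg.keep_missing_maf:
            return "maf"
    elif maf >= cfg.maf_max:
        return "maf"
    return None


@dataclass
class _Candidate:
    site: SiteGenotypes
    cohort: str
    maf: float | None = None

    @property
    def child_sample(self) -> str:
        return f"{self.site.family_id}.{self.cohort}"


def apply_site_filters(
    candidates: list[_Candidate], cfg: FilterConfig, report: FilterReport
) -> list[_Candidate]:
    """Drop candidates violating GQ/DP/AC-AF/MAF rules; itemize removals."""
    for rule in ("gq", "dp", "ac_af", "maf"):
        report.removed.setdefault(rule, 0)
    kept = []
    for cand in candidates:
        rule = _site_filter_failures(cand.site, cfg, cand.maf)
        if rule is None:
            kept.append(cand)
        else:
            report.removed[rule] += 1
    return kept


def exclude_regions(
    candidates: list[_Candidate], exclusions: list[IntervalSet], report: FilterReport
) -> list[_Candidate]:
    """Drop candidates overlapping any exclusion interval set."""
    kept = candidates
    for excl in exclusions:
        key = f"excluded_{excl.name}"
        report.removed.setdefault(key, 0)
        if not kept:
            continue
        hits = excl.contains([c.site.chrom for c in kept], [c.site.pos for c in kept])
        report.removed[key] += int(hits.sum())
        kept = [c for c, h in zip(kept, hits) if not h]
    return kept


def dedup_recurrent(candidates: list[_Candidate], report: FilterReport) -> list[_Candidate]:
    """Remove every carrier of a variant observed in more than one child."""
    report.removed.setdefault("recurrent", 0)
    seen: dict[tuple, int] = {}
    for c in candidates:
        k = (c.site.chrom, c.site.pos, c.site.ref, c.site.alt)
        seen[k] = seen.get(k, 0) + 1
    kept = []
    for c in candidates:
        if seen[(c.site.chrom, c.site.pos, c.site.ref, c.site.alt)] > 1:
            report.removed["recurrent"] += 1
        else:
            kept.append(c)
    return kept


def filter_denovo(
    sites: list[SiteGenotypes],
    cfg: FilterConfig | None = None,
    exclusions: list[IntervalSet] | None = None,
    family_blocklist: set[str] | None = None,
    maf_lookup: dict[tuple, float] | None = None,
) -> tuple[VariantTable, FilterReport]:
    """Full candidate-dnSNV pipeline: tag, quality-filter, exclude, dedup.

    ``maf_lookup`` maps (chrom, pos, ref, alt) to a population MAF; keys
    absent from the mapping are treated as "MAF unavailable".
    """
    cfg = cfg or FilterConfig()
    exclusions = exclusions or []
    family_blocklist = family_blocklist or set()
    report = FilterReport(n_input_sites=len(sites))

    sites = genotype_refinement_hook(sites)
    candidates: list[_Candidate] = []
    for site in sites:
        if site.family_id in family_blocklist:
            continue
        if not site.biallelic_snv:
            report.n_non_biallelic_snv += 1
            continue
        if not site.complete:
            report.n_ineligible_missing_gt += 1
            continue
        for cohort in tag_candidate_denovo(site):
            maf = None
            if maf_lookup is not None:
                maf = maf_lookup.get((site.chrom, site.pos, site.ref, site.alt))
            cand = _Candidate(site, cohort, maf)
            if site.members[cohort].alt_count == 2:
                report.n_implausible_homalt += 1
            candidates.append(cand)
    report.n_candidates = len(candidates)

    kept = apply_site_filters(candidates, cfg, report)
    kept = exclude_regions(kept, exclusions, report)
    if cfg.drop_recurrent:
        kept = dedup_recurrent(kept, report)
    else:
        report.removed.setdefault("recurrent", 0)

    rows = []
    for c in kept:
        rows.append(
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "ref": c.site.ref,
                "alt": c.site.alt,
                "child_id": c.child_sample,
                "family_id": c.site.family_id,
                "cohort": c.cohort,
                "compartment": None,
                "maf": np.nan if c.maf is None else c.maf,
            }
        )
    df = pd.DataFrame(rows, columns=CORE_COLUMNS)
    table = VariantTable(df)
    report.retained_proband = table.n_proband
    report.retained_sibling = table.n_sibling
    assert report.check_arithmetic(), "filter report arithmetic identity violated"
    return table, report
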