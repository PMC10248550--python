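"""Burden tests: one-sided Fisher tests on category overlap and rank-sum
tests on continuous prioritization scores, with BH-FDR control.

The contingency table for a category counts proband and sibling dnSNVs
inside vs outside the category, with cohort totals as fixed margins; the
one-sided alternative is proband excess ("greater"). For continuous scores
the same table is built from membership in the top 5% of the pooled score
distribution, and a one-sided Wilcoxon rank-sum test compares the
unthresholded score rankings.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from dnvscreen.intervals import IntervalSet, overlap_membership
from dnvscreen.variants import VariantTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: cohort x in/out of category, cohort totals fixed."""

    k_p: int
    k_s: int
    n_p: int
    n_s: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_p <= self.n_p):
            raise ValueError(f"need 0 <= k_p <= N_p, got {self.k_p}, {self.n_p}")
        if not (0 <= self.k_s <= self.n_s):
            raise ValueError(f"need 0 <= k_s <= N_s, got {self.k_s}, {self.n_s}")

    @property
    def as_2x2(self) -> list[list[int]]:
        return [[self.k_p, self.n_p - self.k_p], [self.k_s, self.n_s - self.k_s]]


@dataclass
class EnrichmentResult:
    category: str
    test: str  # "fet" | "fet_top5" | "ranksum"
    table: ContingencyTable | None
    relative_risk: float
    odds_ratio: float
    p_raw: float
    p_adjusted: float


def fet_one_sided(t: ContingencyTable) -> tuple[float, float]:
    """One-sided ("greater") Fisher exact p and sample odds ratio.

    p is the fixed-margin hypergeometric upper tail P(X >= k_p). A table
    with no in-category variants at all gives p = 1 by convention.
    """
    K = t.k_p + t.k_s
    n = t.n_p + t.n_s
    if K == 0 or t.k_p == 0:
        p = 1.0
        if K == 0:
            logger.info("empty category: FET p set to 1")
    else:
        p = float(stats.hypergeom.sf(t.k_p - 1, n, K, t.n_p))
    num = t.k_p * (t.n_s - t.k_s)
    den = (t.n_p - t.k_p) * t.k_s
    odds = math.inf if den == 0 and num > 0 else (num / den if den else math.nan)
    return p, odds


def relative_risk(t: ContingencyTable) -> float:
    """RR = (k_p/N_p) / (k_s/N_s); NaN when the sibling count is zero."""
    if t.k_s == 0:
        return math.nan
    return (t.k_p / t.n_p) / (t.k_s / t.n_s)


def score_threshold_membership(
    scores_p: np.ndarray, scores_s: np.ndarray, fraction: float = 0.05
) -> tuple[ContingencyTable, float]:
    """Top-``fraction`` membership table from the pooled score distribution.

    The threshold is the empirical (1 - fraction) quantile of the pooled
    two-cohort scores; membership is inclusive (score >= threshold), so
    ties at the threshold are all members. Returns (table, threshold).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    scores_p = np.asarray(scores_p, dtype=float)
    scores_s = np.asarray(scores_s, dtype=float)
    scores_p = scores_p[~np.isnan(scores_p)]
    scores_s = scores_s[~np.isnan(scores_s)]
    if len(scores_p) == 0 or len(scores_s) == 0:
        raise ValueError("need scores in both cohorts")
    pooled = np.concatenate([scores_p, scores_s])
    thr = float(np.quantile(pooled, 1.0 - fraction, method="higher"))
    t = ContingencyTable(
        k_p=int((scores_p >= thr).sum()),
        k_s=int((scores_s >= thr).sum()),
        n_p=len(scores_p),
        n_s=len(scores_s),
    )
    return t, thr


def wilcoxon_greater(scores_p: np.ndarray, scores_s: np.ndarray) -> float:
    """One-sided (proband > sibling) rank-sum p with tie correction.

    Exact for small untied samples, normal approximation otherwise. Two
    identical constant samples carry no directional evidence: p = 0.5.
    """
    scores_p = np.asarray(scores_p, dtype=float)
    scores_s = np.asarray(scores_s, dtype=float)
    if len(scores_p) == 0 or len(scores_s) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([scores_p, scores_s])
    if np.all(pooled == pooled[0]):
        return 0.5
    return float(stats.mannwhitneyu(scores_p, scores_s, alternative="greater").pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrichment_screen(
    table: VariantTable,
    categories: list[IntervalSet] | None = None,
    score_columns: list[str] | None = None,
    alpha: float = 0.05,
    top_fraction: float = 0.05,
) -> pd.DataFrame:
    """Screen categories and score columns for proband excess.

    One FET per interval category; per score column, one FET on top-5%
    membership plus one unadjusted rank-sum test. BH-FDR is applied across
    the FET family only (rank-sum p values are reported raw, as is
    conventional for the secondary score comparison). Rows are sorted by
    adjusted p within test family.
    """
    categories = categories or []
    score_columns = score_columns or []
    if not categories and not score_columns:
        return pd.DataFrame(
            columns=["category", "test", "k_p", "k_s", "n_p", "n_s",
                     "relative_risk", "odds_ratio", "p_raw", "p_adjusted", "significant"]
        )
    rows = []
    fet_ps = []
    for cat in categories:
        _, k_p, k_s = overlap_membership(table, cat)
        t = ContingencyTable(k_p, k_s, table.n_proband, table.n_sibling)
        p, orat = fet_one_sided(t)
        rows.append((cat.name, "fet", t, relative_risk(t), orat, p))
        fet_ps.append(p)
    for col in score_columns:
        sp, ss = table.cohort_scores(col)
        t, _thr = score_threshold_membership(sp, ss, top_fraction)
        p, orat = fet_one_sided(t)
        rows.append((col, "fet_top5", t, relative_risk(t), orat, p))
        fet_ps.append(p)
        rows.append((col, "ranksum", None, math.nan, math.nan, wilcoxon_greater(sp, ss)))

    adj = iter(bh_adjust(fet_ps))
    out = []
    for name, test, t, rr, orat, p in rows:
        p_adj = float(next(adj)) if test.startswith("fet") else p
        out.append(
            {
                "category": name,
                "test": test,
                "k_p": t.k_p if t else pd.NA,
                "k_s": t.k_s if t else pd.NA,
                "n_p": t.n_p if t else pd.NA,
                "n_s": t.n_s if t else pd.NA,
                "relative_risk": rr,
                "odds_ratio": orat,
                "p_raw": p,
                "p_adjusted": p_adj,
                "significant": p_adj <= alpha,
            }
        )
    df = pd.DataFrame(out)
    return df.sort_values(["test", "p_adjusted", "category"], kind="stable").reset_index(drop=True)
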