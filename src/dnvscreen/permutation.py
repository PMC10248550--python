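"""Label-shuffling permutation null for category overlap counts.

The null model for "does this category's proband overlap count deviate
from chance" shuffles the proband/sibling labels across all dnSNVs,
keeping the label margins fixed (exactly N_p variants labelled proband in
every permutation). Shuffling conserves the total in-category count, so
the per-permutation proband count follows a hypergeometric distribution —
whose closed-form moments serve as an analytic cross-check. The observed
count is scored as Z = (observed - null mean) / null SD, with Z >= 2
flagged as a significant departure from random expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from dnvscreen.variants import VariantTable

DEFAULT_N_PERM = 10_000
Z_THRESHOLD = 2.0


@dataclass
class PermutationNull:
    """Empirical shuffle null for one category."""

    n_perm: int
    null_p: np.ndarray  # per-permutation proband in-category counts
    observed_p: int
    observed_s: int
    total_in_category: int
    n_p: int
    n_s: int
    seed: int

    @property
    def null_s(self) -> np.ndarray:
        return self.total_in_category - self.null_p

    @property
    def mean(self) -> float:
        return float(self.null_p.mean())

    @property
    def sd(self) -> float:
        return float(self.null_p.std(ddof=0))

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    @property
    def z_p(self) -> float:
        return z_score(self.observed_p, self)

    @property
    def z_s(self) -> float:
        if self.degenerate:
            return math.nan
        mean_s = self.total_in_category - self.mean
        return (self.observed_s - mean_s) / self.sd

    @property
    def significant(self) -> bool:
        z = self.z_p
        return (not math.isnan(z)) and z >= Z_THRESHOLD


def permute_null(
    table: VariantTable,
    membership: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
) -> PermutationNull:
    """Shuffle cohort labels across all dnSNVs ``n_perm`` times.

    ``membership`` is the per-record in-category boolean aligned to the
    table. Every permutation reassigns exactly N_p proband labels uniformly
    at random without replacement and records the in-category count per
    cohort. Deterministic under ``seed``.
    """
    membership = np.asarray(membership, dtype=bool)
    if len(membership) != len(table):
        raise ValueError("membership must align with the variant table")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n_p, n_s = table.n_proband, table.n_sibling
    if n_p + n_s != len(table):
        raise ValueError("cohort totals do not partition the table")
    is_p = table.is_proband
    observed_p = int(membership[is_p].sum())
    observed_s = int(membership[~is_p].sum())
    rng = np.random.default_rng(seed)
    member = membership.copy()
    null_p = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        rng.shuffle(member)
        null_p[i] = member[:n_p].sum()  # first N_p shuffled slots = "proband"
    return PermutationNull(
        n_perm=n_perm,
        null_p=null_p,
        observed_p=observed_p,
        observed_s=observed_s,
        total_in_category=observed_p + observed_s,
        n_p=n_p,
        n_s=n_s,
        seed=seed,
    )


def z_score(observed: float, null: PermutationNull) -> float:
    """Z = (observed - null mean) / null SD; NaN when the null is degenerate."""
    if null.degenerate:
        return math.nan
    return (observed - null.mean) / null.sd


def hypergeom_moments(K: int, n_p: int, n_s: int) -> tuple[float, float]:
    """Closed-form mean and SD of the shuffle null's proband count.

    Drawing which K in-category variants land among the N_p proband slots
    is sampling without replacement: mean = K*N_p/N and
    sd = sqrt(K * (N_p/N) * (N_s/N) * (N-K)/(N-1)), N = N_p + N_s.
    """
    n = n_p + n_s
    if n <= 1:
        raise ValueError("need N_p + N_s > 1")
    if not (0 <= K <= n):
        raise ValueError("need 0 <= K <= N_p + N_s")
    mean = K * n_p / n
    var = K * (n_p / n) * (n_s / n) * (n - K) / (n - 1)
    return mean, math.sqrt(var)
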