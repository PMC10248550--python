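"""Two-proportion power analysis on Cohen's h, forward and reverse.

The modeled test is the arcsine-transformed two-proportion z-test with a
one-sided "greater" alternative, the estimand of the classical pwr-style
power calculation:

    h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p2))
    power = Phi( h * sqrt(n/2) - z_{1-alpha} )

with equal per-group sample size n. Here p1 and p2 are the proband and
sibling in-category dnSNV proportions, and n per group is the mean of the
two cohort dnSNV totals at a given family count (the cohort totals differ
by ~2%, and either choice moves results by well under printed precision).

Forward analysis solves for the per-group n (and hence family count, via
linear scaling of the per-family mutation rates) that reaches a target
power. Reverse analysis holds n fixed and solves for the relative increase
g in the proband proportion — p1 -> p1*(1+g) — needed to reach the target,
i.e. how much more informative an annotation category would have to be at
the present cohort size. Published summaries print the starting power but
not the sibling overlap count, so :func:`invert_power_for_p2` recovers the
implied p2 from (p1, starting power, n) by monotone root-finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

DEFAULT_ALPHA = 0.05
_ROOT_TOL = 1e-12


@dataclass(frozen=True)
class FamilyRateMap:
    """Linear mapping between quad-family counts and cohort dnSNV totals."""

    families_ref: int = 1_917
    n_p_ref: int = 134_969
    n_s_ref: int = 131_896

    @property
    def n_per_group_ref(self) -> float:
        return 0.5 * (self.n_p_ref + self.n_s_ref)

    def n_per_group(self, families: float) -> float:
        return families / self.families_ref * self.n_per_group_ref

    def families_for_n(self, n_per_group: float) -> float:
        return n_per_group / self.n_per_group_ref * self.families_ref


@dataclass(frozen=True)
class PowerSpec:
    """Inputs of one power evaluation."""

    p1: float
    p2: float
    n_per_group: float
    alpha: float = DEFAULT_ALPHA

    @property
    def h(self) -> float:
        return cohens_h(self.p1, self.p2)

    @property
    def power(self) -> float:
        return power_two_prop(self.p1, self.p2, self.n_per_group, self.alpha)


@dataclass(frozen=True)
class ReversePowerResult:
    """Solution of the effect-size inflation ("reverse power") problem."""

    g_star: float  # smallest relative increase in p1 reaching target power
    extra_variants: float  # (p1*(1+g) - p1) * N_p
    p1: float
    p2: float
    n_per_group: float
    starting_power: float
    target_power: float

    @property
    def increase_pct(self) -> float:
        return 100.0 * self.g_star


def _check_prop(p: float, name: str) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p}")


def cohens_h(p1: float, p2: float) -> float:
    """Effect size h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p2)); antisymmetric."""
    _check_prop(p1, "p1")
    _check_prop(p2, "p2")
    return 2.0 * math.asin(math.sqrt(p1)) - 2.0 * math.asin(math.sqrt(p2))


def power_two_prop(
    p1: float, p2: float, n_per_group: float, alpha: float = DEFAULT_ALPHA
) -> float:
    """Power of the one-sided (p1 > p2) two-proportion test at equal n."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    h = cohens_h(p1, p2)
    return float(norm.cdf(h * math.sqrt(n_per_group / 2.0) - norm.ppf(1.0 - alpha)))


def invert_power_for_p2(
    p1: float, observed_power: float, n_per_group: float, alpha: float = DEFAULT_ALPHA
) -> float:
    """Sibling proportion p2 <= p1 implied by a printed starting power.

    Solves power(p1, p2, n) = observed_power for p2 on [0, p1] by monotone
    root-finding (power decreases in p2).
    """
    if not (alpha < observed_power < 1.0):
        raise ValueError("observed_power must lie in (alpha, 1)")
    if not (0.0 < p1 < 1.0):
        raise ValueError("p1 must lie in (0, 1)")

    def f(p2: float) -> float:
        return power_two_prop(p1, p2, n_per_group, alpha) - observed_power

    if f(0.0) < 0:
        raise ValueError("no p2 in [0, p1] attains the observed power")
    return float(brentq(f, 0.0, p1, xtol=_ROOT_TOL))


def solve_n_for_power(
    p1: float,
    p2: float,
    target_power: float = 0.80,
    alpha: float = DEFAULT_ALPHA,
    rates: FamilyRateMap | None = None,
) -> tuple[float, int]:
    """Per-group n (closed form) and quad-family count reaching target power.

    n = 2 * ((z_{1-alpha} + z_{target}) / h)^2; the family count is scaled
    linearly through ``rates`` and rounded up.
    """
    if p1 <= p2:
        raise ValueError("one-sided power cannot reach target unless p1 > p2")
    if not (alpha < target_power < 1.0):
        raise ValueError("target_power must lie in (alpha, 1)")
    rates = rates or FamilyRateMap()
    h = cohens_h(p1, p2)
    n = 2.0 * ((norm.ppf(1.0 - alpha) + norm.ppf(target_power)) / h) ** 2
    families = math.ceil(rates.families_for_n(n))
    return float(n), int(families)


def solve_increase_for_power(
    p1: float,
    p2: float,
    n_per_group: float,
    target_power: float = 0.80,
    alpha: float = DEFAULT_ALPHA,
    n_p_total: float | None = None,
) -> ReversePowerResult:
    """Smallest relative increase g with power(p1*(1+g), p2, n) = target.

    ``n_p_total`` is the proband cohort dnSNV total used to express the
    increase as an absolute number of additional in-category variants
    (defaults to the reference cohort total).
    """
    start = power_two_prop(p1, p2, n_per_group, alpha)
    n_p_total = FamilyRateMap().n_p_ref if n_p_total is None else n_p_total
    if start >= target_power:
        return ReversePowerResult(0.0, 0.0, p1, p2, n_per_group, start, target_power)
    g_max = 1.0 / p1 - 1.0

    def f(g: float) -> float:
        return power_two_prop(p1 * (1.0 + g), p2, n_per_group, alpha) - target_power

    if f(g_max) < 0:
        raise ValueError("target power unreachable: p1*(1+g) hits 1 first")
    g_star = float(brentq(f, 0.0, g_max, xtol=_ROOT_TOL))
    extra = p1 * g_star * n_p_total
    return ReversePowerResult(g_star, extra, p1, p2, n_per_group, start, target_power)


def power_curve_families(
    p1: float,
    p2: float,
    family_grid,
    alpha: float = DEFAULT_ALPHA,
    rates: FamilyRateMap | None = None,
) -> pd.DataFrame:
    """Forward power curve over quad-family counts."""
    rates = rates or FamilyRateMap()
    fams = np.asarray(family_grid, dtype=float)
    if len(fams) == 0 or np.any(np.diff(fams) <= 0):
        raise ValueError("family grid must be non-empty and increasing")
    powers = [power_two_prop(p1, p2, rates.n_per_group(f), alpha) for f in fams]
    return pd.DataFrame({"families": fams, "power": powers})


def power_curve_increase(
    p1: float, p2: float, n_per_group: float, g_grid, alpha: float = DEFAULT_ALPHA
) -> pd.DataFrame:
    """Reverse power curve over relative increases g at fixed sample size."""
    gs = np.asarray(g_grid, dtype=float)
    if len(gs) == 0 or np.any(np.diff(gs) <= 0):
        raise ValueError("g grid must be non-empty and increasing")
    powers = [power_two_prop(p1 * (1.0 + g), p2, n_per_group, alpha) for g in gs]
    return pd.DataFrame({"relative_increase": gs, "power": powers})


def reverse_power_from_observed(
    observed_count: int,
    starting_power: float,
    rates: FamilyRateMap | None = None,
    target_power: float = 0.80,
    alpha: float = DEFAULT_ALPHA,
) -> ReversePowerResult:
    """Reverse-power solution from the printed summary of one category.

    Takes the observed proband in-category count and the printed starting
    power, derives p1 = count / N_p and the implied sibling proportion,
    then solves for the required relative increase at the reference cohort
    size.
    """
    rates = rates or FamilyRateMap()
    p1 = observed_count / rates.n_p_ref
    n = rates.n_per_group_ref
    p2 = invert_power_for_p2(p1, starting_power, n, alpha)
    return solve_increase_for_power(p1, p2, n, target_power, alpha, rates.n_p_ref)


def families_from_observed(
    observed_count: int,
    starting_power: float,
    rates: FamilyRateMap | None = None,
    target_power: float = 0.80,
    alpha: float = DEFAULT_ALPHA,
) -> int:
    """Quad families needed for target power, from a printed starting power."""
    rates = rates or FamilyRateMap()
    p1 = observed_count / rates.n_p_ref
    p2 = invert_power_for_p2(p1, starting_power, rates.n_per_group_ref, alpha)
    _, families = solve_n_for_power(p1, p2, target_power, alpha, rates)
    return families
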