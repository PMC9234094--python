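"""Independent re-computation routes for double-programming checks.

Every headline quantity has a second implementation that shares no code
with the primary path: exact binomial bounds by root-finding on binomial
tail sums (instead of beta quantiles), and minimum detectable effects by
exhaustive grid search (instead of bisection).  The pipeline can run
these after the primary computation and assert agreement.
"""

from __future__ import annotations

import math

from scipy import optimize, stats

from .detectable_risk import (
    DesignAssumptions,
    grid_search_min_ratio,
    odds_ratio_to_case_prevalence,
    power_two_proportions,
)


def clopper_pearson_tail_inversion(
    x: int, n: int, conf_level: float = 0.95, xtol: float = 1e-12
) -> tuple[float, float]:
    """Exact binomial bounds by inverting the binomial tail sums.

    The lower bound is the p solving ``P(X >= x | n, p) = alpha/2`` (0
    when x = 0); the upper bound solves ``P(X <= x | n, p) = alpha/2``
    (1 when x = n).
    """
    if not 0 <= x <= n or n < 1:
        raise ValueError("need 0 <= x <= n, n >= 1")
    alpha = 1.0 - conf_level
    if x == 0:
        low = 0.0
    else:
        low = optimize.brentq(
            lambda p: stats.binom.sf(x - 1, n, p) - alpha / 2.0, 0.0, 1.0, xtol=xtol
        )
    if x == n:
        high = 1.0
    else:
        high = optimize.brentq(
            lambda p: stats.binom.cdf(x, n, p) - alpha / 2.0, 0.0, 1.0, xtol=xtol
        )
    return float(low), float(high)


def grid_search_mdrr(
    x: int,
    n: int,
    annual_denominator: float,
    design: DesignAssumptions | None = None,
    step: float = 0.001,
) -> float:
    """Grid-search oracle for the cohort minimum detectable relative risk."""
    design = design or DesignAssumptions()
    p0 = x / n
    k = design.cohort_exposed_ratio
    total = annual_denominator * design.duration_years
    n1, n0 = total / (1.0 + k), k * total / (1.0 + k)
    cap = min(100.0, (1.0 - 1e-12) / p0)
    return grid_search_min_ratio(
        lambda rr: power_two_proportions(rr * p0, n1, p0, n0, design.alpha),
        design.target_power,
        step=step,
        cap=cap,
    )


def grid_search_mdor(
    x: int,
    n: int,
    annual_denominator: float,
    design: DesignAssumptions | None = None,
    step: float = 0.001,
) -> float:
    """Grid-search oracle for the case-control minimum detectable odds ratio."""
    design = design or DesignAssumptions()
    q0 = design.exposure_prevalence_controls
    cases = (x / n) * annual_denominator * design.duration_years
    if cases < 1.0:
        return math.inf
    return grid_search_min_ratio(
        lambda orr: power_two_proportions(
            odds_ratio_to_case_prevalence(orr, q0),
            cases,
            q0,
            design.cc_control_ratio * cases,
            design.alpha,
        ),
        design.target_power,
        step=step,
    )
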