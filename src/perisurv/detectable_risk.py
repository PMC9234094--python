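"""Minimum detectable relative risk and odds ratio for safety designs.

Given a site's observed event count x out of n births over a 12-month
surveillance period, these calculators invert a two-proportion power
function to find the smallest effect a future study at that site could
detect with the target power at a two-sided significance level.

Power uses the classical normal approximation for two independent
proportions: with pooled null standard error
``s0 = sqrt(pbar (1-pbar) (1/n1 + 1/n0))`` and unpooled alternative
standard error ``s1 = sqrt(p1(1-p1)/n1 + p0(1-p0)/n0)``,

    power = Phi((|p1 - p0| - z_{1-alpha/2} * s0) / s1)

with no continuity correction.  Group sizes may be fractional — this is
a planning approximation, not an enrolment plan.

*Cohort design*: the total cohort over the study duration is split by
the exposed:unexposed ratio 1:k; the minimum detectable relative risk is
the smallest RR > 1 with power(RR·p0 vs p0) at least the target.

*Case-control design*: the expected number of cases accrues at the
observed rate over the study duration, with m controls per case and a
given exposure prevalence q0 among controls; a candidate odds ratio maps
to the case exposure prevalence ``q1 = OR·q0 / (1 + q0(OR − 1))``.

Confidence bounds on the minimum detectable effect propagate the exact
Clopper–Pearson interval of x/n through the same inversion: the upper
rate bound (more events, more information) yields the lower bound on the
detectable effect, and vice versa.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Search cap: effects above this ratio are reported as not reached.
SEARCH_CAP = 100.0
BISECTION_TOL = 1e-6


class DegenerateProportionError(ValueError):
    """A proportion at 0 or 1 makes the normal-approximation power undefined."""


class NoFiniteDetectableRiskError(ValueError):
    """Zero observed events: no finite minimum detectable effect exists."""


@dataclass(frozen=True)
class DesignAssumptions:
    """Design parameters for future safety studies.

    Defaults: two-sided alpha 5%, 80% power, two-year duration, 1:3
    exposed:unexposed cohort, 1:1 case-control with 25% exposure
    prevalence (e.g. vaccination coverage) among controls.
    """

    alpha: float = 0.05
    target_power: float = 0.80
    duration_years: float = 2.0
    cohort_exposed_ratio: float = 3.0  # unexposed per exposed (1:k)
    cc_control_ratio: float = 1.0  # controls per case (1:m)
    exposure_prevalence_controls: float = 0.25

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if not 0.0 < self.target_power < 1.0:
            raise ValueError("target_power must be in (0, 1)")
        if self.cohort_exposed_ratio < 1 or self.cc_control_ratio < 1:
            raise ValueError("allocation ratios must be >= 1")
        if not 0.0 < self.exposure_prevalence_controls < 1.0:
            raise ValueError("exposure_prevalence_controls must be in (0, 1)")
        if self.duration_years <= 0:
            raise ValueError("duration_years must be positive")


@dataclass(frozen=True)
class DetectableRisk:
    """A minimum detectable RR or OR with its propagated interval.

    ``point`` is infinite when the target power is not reached anywhere
    below the search cap (``reached`` is then False).
    """

    measure: str  # "relative_risk" | "odds_ratio"
    point: float
    ci_low: float
    ci_high: float
    inputs: dict = field(default_factory=dict)

    @property
    def reached(self) -> bool:
        return math.isfinite(self.point)

    def rounded(self, decimals: int = 2) -> tuple[float, float, float]:
        r = lambda v: round(v, decimals) if math.isfinite(v) else v
        return r(self.point), r(self.ci_low), r(self.ci_high)


def power_two_proportions(
    p1: float, n1: float, p0: float, n0: float, alpha: float = 0.05
) -> float:
    """Two-sided two-proportion z-test power, normal approximation."""
    for p in (p0, p1):
        if not 0.0 < p < 1.0:
            raise DegenerateProportionError(f"proportion {p} not strictly inside (0, 1)")
    if n1 < 1 or n0 < 1:
        raise ValueError("group sizes must be >= 1")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
    s0 = math.sqrt(pbar * (1.0 - pbar) * (1.0 / n1 + 1.0 / n0))
    s1 = math.sqrt(p1 * (1.0 - p1) / n1 + p0 * (1.0 - p0) / n0)
    return float(stats.norm.cdf((abs(p1 - p0) - z * s0) / s1))


def odds_ratio_to_case_prevalence(odds_ratio: float, q0: float) -> float:
    """Exposure prevalence among cases implied by an odds ratio.

    OR = 1 maps to q0; OR → ∞ maps to 1.
    """
    return odds_ratio * q0 / (1.0 + q0 * (odds_ratio - 1.0))


def _invert_power(power_at, target_power: float, hi_cap: float) -> float:
    """Smallest ratio > 1 whose power reaches the target, by bisection.

    Returns ``inf`` when even the cap does not reach the target power.
    """
    lo = 1.0 + 1e-9
    if power_at(hi_cap) < target_power:
        return math.inf
    return float(
        optimize.brentq(
            lambda r: power_at(r) - target_power, lo, hi_cap, xtol=BISECTION_TOL
        )
    )


def min_detectable_rr_cohort(
    x: int,
    n: int,
    annual_denominator: float,
    design: DesignAssumptions | None = None,
) -> DetectableRisk:
    """Minimum detectable relative risk for a cohort design at one site.

    ``x``/``n`` is the observed 12-month count and denominator;
    ``annual_denominator`` is the site's annual accrual of the relevant
    denominator (livebirths, or total births for stillbirth).
    """
    design = design or DesignAssumptions()
    if x == 0:
        raise NoFiniteDetectableRiskError("x=0: no finite minimum detectable RR")
    if not 0 < x <= n:
        raise ValueError("need 0 < x <= n")
    from .rate_estimation import clopper_pearson  # local import avoids cycle

    k = design.cohort_exposed_ratio
    total = annual_denominator * design.duration_years
    n_exposed = total / (1.0 + k)
    n_unexposed = k * total / (1.0 + k)

    def solve(p0: float) -> float:
        if p0 <= 0.0:
            return math.inf
        hi = min(SEARCH_CAP, (1.0 - 1e-12) / p0)
        return _invert_power(
            lambda rr: power_two_proportions(
                rr * p0, n_exposed, p0, n_unexposed, design.alpha
            ),
            design.target_power,
            hi,
        )

    est = clopper_pearson(x, n)
    point = solve(x / n)
    return DetectableRisk(
        measure="relative_risk",
        point=point,
        ci_low=solve(est.ci_high),  # more events -> smaller detectable effect
        ci_high=solve(est.ci_low),
        inputs={
            "x": x,
            "n": n,
            "annual_denominator": annual_denominator,
            "design": design,
        },
    )


def min_detectable_or_case_control(
    x: int,
    n: int,
    annual_denominator: float,
    design: DesignAssumptions | None = None,
) -> DetectableRisk:
    """Minimum detectable odds ratio for a case-control design at one site."""
    design = design or DesignAssumptions()
    if x == 0:
        raise NoFiniteDetectableRiskError("x=0: no finite minimum detectable OR")
    if not 0 < x <= n:
        raise ValueError("need 0 < x <= n")
    from .rate_estimation import clopper_pearson

    q0 = design.exposure_prevalence_controls
    m = design.cc_control_ratio

    def solve(p0: float) -> float:
        cases = p0 * annual_denominator * design.duration_years
        if cases < 1.0:
            return math.inf
        return _invert_power(
            lambda orr: power_two_proportions(
                odds_ratio_to_case_prevalence(orr, q0), cases, q0, m * cases, design.alpha
            ),
            design.target_power,
            SEARCH_CAP,
        )

    est = clopper_pearson(x, n)
    point = solve(x / n)
    return DetectableRisk(
        measure="odds_ratio",
        point=point,
        ci_low=solve(est.ci_high),
        ci_high=solve(est.ci_low),
        inputs={
            "x": x,
            "n": n,
            "annual_denominator": annual_denominator,
            "design": design,
        },
    )


def scenario_grid(
    x: int,
    n: int,
    annual_denominator: float,
    durations_years=(2.0,),
    cohort_exposed_ratios=(3.0,),
    cc_control_ratios=(1.0,),
    exposure_prevalences=(0.25,),
    base_design: DesignAssumptions | None = None,
) -> pd.DataFrame:
    """Minimum detectable effects over a Cartesian grid of design scenarios.

    Cohort rows vary (duration, exposed ratio); case-control rows vary
    (duration, control ratio, exposure prevalence).  Rows are sorted by
    (measure, duration, ratio, prevalence) and the evaluation is fully
    deterministic.
    """
    base = base_design or DesignAssumptions()
    for name, grid in (
        ("durations_years", durations_years),
        ("cohort_exposed_ratios", cohort_exposed_ratios),
        ("cc_control_ratios", cc_control_ratios),
        ("exposure_prevalences", exposure_prevalences),
    ):
        if len(tuple(grid)) == 0:
            raise ValueError(f"empty grid: {name}")
    rows = []
    for dur, ratio in itertools.product(sorted(durations_years), sorted(cohort_exposed_ratios)):
        design = DesignAssumptions(
            alpha=base.alpha,
            target_power=base.target_power,
            duration_years=dur,
            cohort_exposed_ratio=ratio,
            cc_control_ratio=base.cc_control_ratio,
            exposure_prevalence_controls=base.exposure_prevalence_controls,
        )
        res = min_detectable_rr_cohort(x, n, annual_denominator, design)
        rows.append(
            {
                "measure": "relative_risk",
                "duration_years": dur,
                "ratio": ratio,
                "exposure_prevalence": math.nan,
                "point": res.point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    for dur, ratio, prev in itertools.product(
        sorted(durations_years), sorted(cc_control_ratios), sorted(exposure_prevalences)
    ):
        design = DesignAssumptions(
            alpha=base.alpha,
            target_power=base.target_power,
            duration_years=dur,
            cohort_exposed_ratio=base.cohort_exposed_ratio,
            cc_control_ratio=ratio,
            exposure_prevalence_controls=prev,
        )
        res = min_detectable_or_case_control(x, n, annual_denominator, design)
        rows.append(
            {
                "measure": "odds_ratio",
                "duration_years": dur,
                "ratio": ratio,
                "exposure_prevalence": prev,
                "point": res.point,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["measure", "duration_years", "ratio", "exposure_prevalence"],
        na_position="first",
    ).reset_index(drop=True)


def grid_search_min_ratio(
    power_at, target_power: float, step: float = 0.001, cap: float = SEARCH_CAP
) -> float:
    """Exhaustive-search oracle: first grid point at/above the target power.

    Independent of the bisection path; used for double-programming
    verification.
    """
    ratios = np.arange(1.0 + step, cap + step, step)
    for r in ratios:
        if power_at(float(r)) >= target_power:
            return float(r)
    return math.inf
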