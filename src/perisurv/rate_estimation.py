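"""Exact binomial estimation of outcome rates per 1,000.

Rates are reported per 1,000 livebirths (per 1,000 total births for
stillbirth) with 95% confidence intervals from the exact Clopper–Pearson
method: the lower bound is the Beta(x, n−x+1) quantile at (1−conf)/2
(zero when x = 0) and the upper bound the Beta(x+1, n−x) quantile at
1−(1−conf)/2 (one when x = n).  All arithmetic is done on unrounded
proportions; the per-1,000 scaling is applied last and display rounding
(one decimal, half away from zero) only at the very end.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .outcome_rules import ALL_OUTCOMES, Outcome

SUBTYPES = ("invasive_bloodstream", "meningitis", "respiratory")


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (2.45 -> 2.5 at one decimal)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


@dataclass(frozen=True)
class BinomialEstimate:
    """x successes out of n trials with exact confidence bounds."""

    x: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95


@dataclass(frozen=True)
class RateEstimate:
    """A per-1,000 outcome rate with its exact interval.

    ``rate_per_1000`` and the bounds are unrounded; use :meth:`display`
    for the conventional one-decimal presentation.
    """

    outcome: str
    site_id: str
    numerator: int
    denominator: int
    denominator_kind: str
    rate_per_1000: float
    ci_low_per_1000: float
    ci_high_per_1000: float
    conf_level: float = 0.95

    def rounded(self, decimals: int = 1) -> tuple[float, float, float]:
        return (
            round_half_away(self.rate_per_1000, decimals),
            round_half_away(self.ci_low_per_1000, decimals),
            round_half_away(self.ci_high_per_1000, decimals),
        )

    def display(self) -> str:
        rate, low, high = self.rounded()
        fmt = lambda v: f"{v:g}"
        return f"{fmt(rate)} ({fmt(low)}-{fmt(high)})"


def clopper_pearson(x: int, n: int, conf_level: float = 0.95) -> BinomialEstimate:
    """Exact (Clopper–Pearson) binomial point estimate and interval."""
    if n < 1:
        raise ZeroDivisionError("n must be >= 1 for a binomial estimate")
    if not 0 <= x <= n:
        raise ValueError(f"x={x} outside [0, {n}]")
    if not 0.0 < conf_level < 1.0:
        raise ValueError("conf_level must be in (0, 1)")
    alpha = 1.0 - conf_level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
    return BinomialEstimate(
        x=int(x), n=int(n), proportion=x / n, ci_low=low, ci_high=high, conf_level=conf_level
    )


def outcome_rate(
    numerator: int,
    denominator: int,
    denominator_kind: str = "livebirths",
    conf_level: float = 0.95,
    outcome: str | Outcome = "",
    site_id: str = "",
) -> RateEstimate:
    """Per-1,000 rate with exact interval for one site and outcome."""
    if denominator_kind not in ("livebirths", "total_births"):
        raise ValueError(f"unknown denominator_kind {denominator_kind!r}")
    est = clopper_pearson(numerator, denominator, conf_level)
    return RateEstimate(
        outcome=str(outcome),
        site_id=site_id,
        numerator=est.x,
        denominator=est.n,
        denominator_kind=denominator_kind,
        rate_per_1000=1000.0 * est.proportion,
        ci_low_per_1000=1000.0 * est.ci_low,
        ci_high_per_1000=1000.0 * est.ci_high,
        conf_level=conf_level,
    )


def subtype_share(
    subtype_counts,
    total_infections: int,
    livebirths: int,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Share of each infection subtype among all neonatal infections.

    ``subtype_counts`` is a mapping or 3-sequence over (invasive
    bloodstream, meningitis, respiratory).  Each subtype gets its
    percentage among all infections (missing when there are none) and
    its own per-1,000-livebirths rate with exact interval.
    """
    if isinstance(subtype_counts, dict):
        counts = [int(subtype_counts.get(s, 0)) for s in SUBTYPES]
    else:
        counts = [int(c) for c in subtype_counts]
        if len(counts) != 3:
            raise ValueError("expected 3 subtype counts")
    if sum(counts) > total_infections:
        raise ValueError("subtype counts exceed total infections")
    rows = []
    for name, count in zip(SUBTYPES, counts):
        share = (
            math.nan
            if total_infections == 0
            else round_half_away(100.0 * count / total_infections, 1)
        )
        rate = outcome_rate(count, livebirths, "livebirths", conf_level, outcome=name)
        rows.append(
            {
                "subtype": name,
                "count": count,
                "share_pct": share,
                "rate_per_1000": rate.rate_per_1000,
                "ci_low_per_1000": rate.ci_low_per_1000,
                "ci_high_per_1000": rate.ci_high_per_1000,
            }
        )
    return pd.DataFrame(rows)


def site_summary(counts: pd.DataFrame, conf_level: float = 0.95) -> pd.DataFrame:
    """Site-by-outcome rate table from a long counts table.

    Input columns: ``site_id``, ``outcome``, ``numerator``,
    ``denominator`` (and optionally ``denominator_kind``; stillbirth
    defaults to total births, everything else to livebirths).  Output has
    one row per site (sorted by site id), per-outcome numerator / rate /
    CI columns, and a ``TOTAL`` row whose count columns are the column
    sums.  A zero denominator yields missing rates and a warning.
    """
    required = {"site_id", "outcome", "numerator", "denominator"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    counts = counts.copy()
    if "denominator_kind" not in counts.columns:
        counts["denominator_kind"] = np.where(
            counts["outcome"] == Outcome.STILLBIRTH.value, "total_births", "livebirths"
        )
    outcomes = [o.value for o in ALL_OUTCOMES if o.value in set(counts["outcome"])]
    rows = {}
    for rec in counts.itertuples(index=False):
        row = rows.setdefault(rec.site_id, {"site_id": rec.site_id})
        if pd.isna(rec.numerator):
            continue
        x, n = int(rec.numerator), int(rec.denominator)
        row[f"{rec.outcome}_n"] = x
        if n == 0:
            warnings.warn(
                f"site {rec.site_id}: zero denominator for {rec.outcome}", stacklevel=2
            )
            continue
        est = outcome_rate(x, n, rec.denominator_kind, conf_level, rec.outcome, rec.site_id)
        row[f"{rec.outcome}_rate"] = est.rate_per_1000
        row[f"{rec.outcome}_ci_low"] = est.ci_low_per_1000
        row[f"{rec.outcome}_ci_high"] = est.ci_high_per_1000
    table = pd.DataFrame(sorted(rows.values(), key=lambda r: r["site_id"]))
    total = {"site_id": "TOTAL"}
    for outcome in outcomes:
        col = f"{outcome}_n"
        if col in table.columns:
            total[col] = table[col].sum()
    table = pd.concat([table, pd.DataFrame([total])], ignore_index=True)
    ordered = ["site_id"]
    for outcome in outcomes:
        for suffix in ("_n", "_rate", "_ci_low", "_ci_high"):
            col = outcome + suffix
            if col in table.columns:
                ordered.append(col)
    return table[ordered]
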