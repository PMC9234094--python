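"""Ascertainment sensitivity analysis.

Routine facility surveillance misses cases.  After systematic
measurement collection, study statisticians can re-identify cases with
standardized rules; the sensitivity analysis estimates, per outcome and
site, the proportion of all identified cases (union of site-flagged and
rule-identified) that the site found on its own, with an exact binomial
interval.  By construction the site count never exceeds the total.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .outcome_rules import (
    ClassificationConfig,
    GrowthReference,
    Outcome,
    _classify_frame,
)
from .rate_estimation import clopper_pearson, round_half_away
from .records import BirthRecord, records_to_frame

#: The four outcomes covered by the post-amendment sensitivity analysis.
SENSITIVITY_OUTCOMES = (
    Outcome.LOW_BIRTHWEIGHT,
    Outcome.PRETERM,
    Outcome.SGA,
    Outcome.MICROCEPHALY,
)


@dataclass(frozen=True)
class AscertainmentResult:
    """Proportion of cases identified by the site, among all identified."""

    outcome: str
    site_id: str
    n_total: int
    n_site: int
    proportion_pct: float
    ci_low_pct: float
    ci_high_pct: float
    conf_level: float = 0.95

    def rounded(self, decimals: int = 1) -> tuple[float, float, float]:
        return (
            round_half_away(self.proportion_pct, decimals),
            round_half_away(self.ci_low_pct, decimals),
            round_half_away(self.ci_high_pct, decimals),
        )


def union_cases(
    records: list[BirthRecord],
    outcome: Outcome | str,
    config: ClassificationConfig | None = None,
    reference: GrowthReference | None = None,
    mode: str = "union",
) -> tuple[int, int]:
    """Count (n_total, n_site) for one outcome.

    ``n_total`` counts records identified by the site flag **or** the
    standardized rule (per-record union: a case found by both counts
    once); ``n_site`` counts site-flagged records.  A record the site
    flagged but the rule cannot confirm (missing measurements) is still
    included — it was identified by the site.  ``mode="sum"`` replaces
    the union with the raw sum of the two counts, for comparison only.
    """
    if mode not in ("union", "sum"):
        raise ValueError("mode must be 'union' or 'sum'")
    outcome = Outcome(outcome)
    if not records:
        return 0, 0
    config = config or ClassificationConfig()
    reference = reference or GrowthReference.packaged()
    labels = _classify_frame(records_to_frame(records), config, reference)
    rule = labels[f"label_{outcome.value}"].to_numpy()
    flagged = pd.Series([outcome.value in r.site_flags for r in records]).to_numpy()
    n_site = int(flagged.sum())
    n_total = int((rule | flagged).sum()) if mode == "union" else int(rule.sum()) + n_site
    return n_total, n_site


def ascertainment_proportion(
    n_site: int, n_total: int, conf_level: float = 0.95,
    outcome: str = "", site_id: str = "",
) -> AscertainmentResult:
    """Exact-interval estimate of the site-identified proportion, in percent."""
    if n_total < 1:
        raise ZeroDivisionError("n_total must be >= 1")
    if n_site > n_total:
        raise ValueError("n_site cannot exceed n_total")
    est = clopper_pearson(n_site, n_total, conf_level)
    return AscertainmentResult(
        outcome=str(outcome),
        site_id=site_id,
        n_total=est.n,
        n_site=est.x,
        proportion_pct=100.0 * est.proportion,
        ci_low_pct=100.0 * est.ci_low,
        ci_high_pct=100.0 * est.ci_high,
        conf_level=conf_level,
    )


def sensitivity_table(
    records: list[BirthRecord],
    config: ClassificationConfig | None = None,
    reference: GrowthReference | None = None,
    outcomes=SENSITIVITY_OUTCOMES,
    windows: dict[str, int] | None = None,
    conf_level: float = 0.95,
) -> pd.DataFrame:
    """Per-site ascertainment table over the post-amendment window.

    ``windows`` maps site ids to the number of trailing weeks of that
    site's line list that fall after its protocol amendment; records
    outside the window (or sites absent from ``windows`` when given) are
    excluded.  Each row carries, per outcome, the union total, the
    site-identified count, and the site-identified percentage with its
    exact interval; sites with no identified cases for an outcome get
    missing percentages.
    """
    df = records_to_frame(records)
    rows = []
    for site_id, idx in df.groupby("site_id", sort=True).groups.items():
        site_records = [records[i] for i in idx]
        weeks = None
        if windows is not None:
            if site_id not in windows:
                continue
            weeks = int(windows[site_id])
            last = max(r.birth_date for r in site_records)
            cutoff = last - pd.Timedelta(weeks=weeks).to_pytimedelta()
            site_records = [r for r in site_records if r.birth_date > cutoff]
        row: dict = {"site_id": site_id}
        if weeks is not None:
            row["weeks"] = weeks
        for outcome in outcomes:
            outcome = Outcome(outcome)
            n_total, n_site = union_cases(site_records, outcome, config, reference)
            row[f"{outcome.value}_n_total"] = n_total
            row[f"{outcome.value}_n_site"] = n_site
            if n_total > 0:
                res = ascertainment_proportion(
                    n_site, n_total, conf_level, outcome.value, site_id
                )
                row[f"{outcome.value}_pct"] = res.proportion_pct
                row[f"{outcome.value}_ci_low"] = res.ci_low_pct
                row[f"{outcome.value}_ci_high"] = res.ci_high_pct
        rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_table_from_counts(
    counts: pd.DataFrame, conf_level: float = 0.95
) -> pd.DataFrame:
    """Ascertainment table from a pre-aggregated long counts table.

    Input columns: ``site_id``, ``outcome``, ``n_total``, ``n_site`` and
    optionally ``weeks``.  Rows with ``n_total`` = 0 (outcome not
    assessed or no cases) get missing percentages.
    """
    rows = []
    for rec in counts.itertuples(index=False):
        row = {
            "site_id": rec.site_id,
            "outcome": rec.outcome,
            "n_total": int(rec.n_total),
            "n_site": int(rec.n_site),
        }
        if hasattr(rec, "weeks"):
            row["weeks"] = int(rec.weeks)
        if rec.n_total > 0:
            res = ascertainment_proportion(
                int(rec.n_site), int(rec.n_total), conf_level, rec.outcome, rec.site_id
            )
            row["pct"] = res.proportion_pct
            row["ci_low_pct"] = res.ci_low_pct
            row["ci_high_pct"] = res.ci_high_pct
        rows.append(row)
    return pd.DataFrame(rows)
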