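"""End-to-end surveillance analysis runs.

``run_pipeline`` ties the stages together — simulate (or load) a
multi-site line list, apply imperfect routine ascertainment, classify
with the standardized rules, estimate per-1,000 rates with exact
intervals, run the post-amendment ascertainment analysis, and compute
minimum detectable risks — and writes a report bundle of delimited
tables with a provenance header (package version, seed, config hash) in
every file.  A counts-only entry point accepts pre-aggregated per-site
counts so published summary tables can be analysed without any line
list, which is also how facilities that only submit monthly aggregates
enter the analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ascertainment import sensitivity_table
from .cohort_synth import (
    SiteProfile,
    aggregate_monthly,
    apply_site_ascertainment,
    simulate_site,
)
from .detectable_risk import (
    DesignAssumptions,
    NoFiniteDetectableRiskError,
    min_detectable_or_case_control,
    min_detectable_rr_cohort,
)
from .outcome_rules import (
    ALL_OUTCOMES,
    ClassificationConfig,
    GrowthReference,
    Outcome,
    classify_cohort,
)
from .rate_estimation import site_summary
from .records import (
    BirthRecord,
    GA_DAYS_MAX,
    GA_DAYS_MIN,
    LINELIST_COLUMNS,
    frame_to_records,
    records_to_frame,
)
from .verification import (
    clopper_pearson_tail_inversion,
    grid_search_mdor,
    grid_search_mdrr,
)

logger = logging.getLogger("perisurv")

#: Outcomes for which detectable-risk planning is run by default.
MDR_OUTCOMES = (Outcome.LOW_BIRTHWEIGHT, Outcome.PRETERM, Outcome.STILLBIRTH)


class SchemaError(ValueError):
    """Line-list header does not match the expected schema."""


def read_linelist(path) -> tuple[list[BirthRecord], pd.DataFrame]:
    """Read a delimited line list into typed records plus a rejects report.

    Malformed rows (impossible values, unknown categories) are collected
    into the rejects table with their 1-based data line number and the
    reason, never silently dropped.  Unknown columns raise
    :class:`SchemaError`; an empty file with a valid header yields an
    empty record list.
    """
    df = pd.read_csv(path, dtype={"site_flags": "string"})
    unknown = set(df.columns) - set(LINELIST_COLUMNS)
    if unknown:
        raise SchemaError(f"unknown columns: {sorted(unknown)}")
    missing = set(LINELIST_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    records: list[BirthRecord] = []
    rejects = []
    for pos in range(len(df)):
        row = df.iloc[[pos]]
        try:
            bw = row["birthweight_g"].iloc[0]
            if pd.notna(bw) and float(bw) <= 0:
                raise ValueError(f"birthweight_g={bw} not positive")
            ga = row["gestational_age_days"].iloc[0]
            if pd.notna(ga) and not (GA_DAYS_MIN <= float(ga) <= GA_DAYS_MAX):
                raise ValueError(f"gestational_age_days={ga} outside plausible range")
            records.extend(frame_to_records(row))
        except (ValueError, TypeError) as exc:
            rejects.append({"line": pos + 1, "reason": str(exc)})
    return records, pd.DataFrame(rejects, columns=["line", "reason"])


def counts_wide_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    """Melt a wide per-site counts table into the long analysis format.

    The wide table has one row per site with ``total_births``,
    ``livebirths`` and one column per outcome; missing outcome cells
    (outcome not assessed at that site) are skipped.
    """
    rows = []
    for rec in wide.itertuples(index=False):
        for outcome in ALL_OUTCOMES:
            value = getattr(rec, outcome.value, None)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                continue
            is_sb = outcome is Outcome.STILLBIRTH
            rows.append(
                {
                    "site_id": rec.site_id,
                    "outcome": outcome.value,
                    "numerator": int(value),
                    "denominator": int(rec.total_births if is_sb else rec.livebirths),
                    "denominator_kind": "total_births" if is_sb else "livebirths",
                }
            )
    return pd.DataFrame(rows)


def mdr_table(
    counts_long: pd.DataFrame,
    design: DesignAssumptions | None = None,
    outcomes=MDR_OUTCOMES,
    annual_scale: float = 1.0,
) -> pd.DataFrame:
    """Per-site minimum detectable RR and OR from a long counts table.

    ``annual_scale`` converts the observed denominator to an annual
    accrual (1.0 when the counts already cover 12 months).  Sites with
    zero events get missing entries and a warning in the log.
    """
    design = design or DesignAssumptions()
    wanted = {Outcome(o).value for o in outcomes}
    rows = []
    for rec in counts_long.itertuples(index=False):
        if rec.outcome not in wanted:
            continue
        x, n = int(rec.numerator), int(rec.denominator)
        row = {
            "site_id": rec.site_id,
            "outcome": rec.outcome,
            "events": x,
            "denominator": n,
        }
        if x == 0:
            logger.warning(
                "site %s, %s: zero events, no finite detectable risk", rec.site_id, rec.outcome
            )
            rows.append(row)
            continue
        annual = n * annual_scale
        rr = min_detectable_rr_cohort(x, n, annual, design)
        orr = min_detectable_or_case_control(x, n, annual, design)
        row.update(
            mdrr=rr.point, mdrr_ci_low=rr.ci_low, mdrr_ci_high=rr.ci_high,
            mdor=orr.point, mdor_ci_low=orr.ci_low, mdor_ci_high=orr.ci_high,
        )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """Everything one reproducible end-to-end run needs."""

    sites: list[SiteProfile]
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    design: DesignAssumptions = field(default_factory=DesignAssumptions)
    windows: dict[str, int] = field(default_factory=dict)
    seed: int = 0
    verify: bool = False

    def config_hash(self) -> str:
        payload = repr(
            (
                sorted(
                    (p.site_id, tuple(sorted(dataclasses.asdict(p).items(), key=str)))
                    for p in self.sites
                ),
                dataclasses.asdict(self.classification),
                dataclasses.asdict(self.design),
                sorted(self.windows.items()),
                self.seed,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            sites=[SiteProfile.from_dict(s) for s in doc["sites"]],
            classification=ClassificationConfig(**doc.get("classification", {})),
            design=DesignAssumptions(**doc.get("design", {})),
            windows={str(k): int(v) for k, v in doc.get("windows", {}).items()},
            seed=int(doc.get("seed", 0)),
            verify=bool(doc.get("verify", False)),
        )


@dataclass
class ReportBundle:
    """In-memory result of a pipeline run."""

    records: list[BirthRecord]
    counts: pd.DataFrame
    rates: pd.DataFrame
    ascertainment: pd.DataFrame
    detectable_risk: pd.DataFrame
    monthly: pd.DataFrame
    provenance: dict


def _site_seed(base_seed: int, index: int, stage: int) -> int:
    ss = np.random.SeedSequence([base_seed, index, stage])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _flag_counts(records: list[BirthRecord]) -> pd.DataFrame:
    """Long table of site-flagged counts per (site, outcome)."""
    df = records_to_frame(records)
    rows = []
    for site_id, idx in df.groupby("site_id", sort=True).groups.items():
        site_records = [records[i] for i in idx]
        n_total = len(site_records)
        n_live = sum(r.delivery_outcome == "livebirth" for r in site_records)
        for outcome in ALL_OUTCOMES:
            is_sb = outcome is Outcome.STILLBIRTH
            rows.append(
                {
                    "site_id": site_id,
                    "outcome": outcome.value,
                    "numerator": sum(outcome.value in r.site_flags for r in site_records),
                    "denominator": n_total if is_sb else n_live,
                    "denominator_kind": "total_births" if is_sb else "livebirths",
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, reference: GrowthReference | None = None) -> ReportBundle:
    """Simulate, flag, classify, estimate, and plan — deterministically.

    Rates are estimated from the *site-flagged* counts, mirroring routine
    surveillance; the ascertainment table contrasts those flags with the
    standardized rules over each site's post-amendment window; detectable
    risks use the flagged counts scaled to annual accrual.
    """
    reference = reference or GrowthReference.packaged()
    records: list[BirthRecord] = []
    for i, profile in enumerate(config.sites):
        simulated = simulate_site(profile, _site_seed(config.seed, i, 0), reference)
        flagged = apply_site_ascertainment(
            simulated, profile, _site_seed(config.seed, i, 1), config.classification, reference
        )
        logger.info("site %s: %d records simulated", profile.site_id, len(simulated))
        records.extend(flagged)

    classification = classify_cohort(records, config.classification, reference)
    flag_counts = _flag_counts(records)
    rates = site_summary(flag_counts)
    asc = sensitivity_table(
        records,
        config.classification,
        reference,
        windows=config.windows or None,
    )
    duration_weeks = {p.site_id: p.duration_weeks for p in config.sites}
    mdr_frames = []
    for site_id, grp in flag_counts.groupby("site_id"):
        scale = 52.0 / duration_weeks[site_id]
        mdr_frames.append(mdr_table(grp, config.design, annual_scale=scale))
    mdr = pd.concat(mdr_frames, ignore_index=True)

    if config.verify:
        verify_bundle(flag_counts, mdr, config.design, duration_weeks)

    provenance = {
        "package": "perisurv",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_records": len(records),
    }
    return ReportBundle(
        records=records,
        counts=classification.counts,
        rates=rates,
        ascertainment=asc,
        detectable_risk=mdr,
        monthly=aggregate_monthly(records),
        provenance=provenance,
    )


def verify_bundle(
    counts_long: pd.DataFrame,
    mdr: pd.DataFrame,
    design: DesignAssumptions,
    duration_weeks: dict[str, int],
    ci_tol: float = 1e-8,
    mdr_step: float = 0.001,
) -> None:
    """Double-programming pass: recompute every CI and detectable risk
    with the independent oracles and assert agreement.

    Raises ``AssertionError`` on any disagreement beyond tolerance.
    """
    from .rate_estimation import clopper_pearson

    for rec in counts_long.itertuples(index=False):
        x, n = int(rec.numerator), int(rec.denominator)
        if n == 0:
            continue
        primary = clopper_pearson(x, n)
        low, high = clopper_pearson_tail_inversion(x, n)
        assert abs(low - primary.ci_low) < ci_tol, (rec.site_id, rec.outcome, "ci_low")
        assert abs(high - primary.ci_high) < ci_tol, (rec.site_id, rec.outcome, "ci_high")
    for _, row in mdr.iterrows():
        if "mdrr" not in mdr.columns or pd.isna(row.get("mdrr")):
            continue
        x, n = int(row["events"]), int(row["denominator"])
        annual = n * 52.0 / duration_weeks.get(row["site_id"], 52)
        oracle_rr = grid_search_mdrr(x, n, annual, design, step=mdr_step)
        oracle_or = grid_search_mdor(x, n, annual, design, step=mdr_step)
        assert abs(oracle_rr - row["mdrr"]) <= mdr_step + 1e-9, (row["site_id"], "mdrr")
        assert abs(oracle_or - row["mdor"]) <= mdr_step + 1e-9, (row["site_id"], "mdor")


def write_bundle(bundle: ReportBundle, out_dir) -> None:
    """Write the report bundle as delimited tables plus a text summary.

    Every file starts with ``#``-prefixed provenance lines naming the
    package version, seed, and config hash; output is byte-identical for
    identical (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = bundle.provenance
    header = (
        f"# {prov['package']} {prov['version']}\n"
        f"# seed={prov['seed']} config_hash={prov['config_hash']}\n"
    )

    def write_csv(df: pd.DataFrame, name: str) -> None:
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        (out / name).write_text(header + buf.getvalue())

    write_csv(records_to_frame(bundle.records), "linelist.csv")
    write_csv(bundle.counts, "classified_counts.csv")
    write_csv(bundle.rates, "rates.csv")
    write_csv(bundle.ascertainment, "ascertainment.csv")
    write_csv(bundle.detectable_risk, "detectable_risk.csv")
    write_csv(bundle.monthly, "monthly_aggregates.csv")
    lines = [
        f"perisurv {prov['version']} run summary",
        f"seed: {prov['seed']}",
        f"config hash: {prov['config_hash']}",
        f"records: {prov['n_records']}",
        f"sites: {bundle.rates['site_id'].nunique() - 1}",
    ]
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
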