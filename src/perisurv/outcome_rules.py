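"""Standardized outcome definitions for perinatal surveillance.

Seven adverse outcomes are classified from measurements recorded at
birth and during the neonatal period:

* **low birthweight** — livebirth with birthweight strictly below a
  threshold (default 2,500 g);
* **preterm birth** — livebirth before 37 completed weeks of gestation
  (default threshold 259 days, strict);
* **small for gestational age (SGA)** — livebirth with birthweight
  strictly below the 10th percentile of a sex- and gestational-age
  specific reference;
* **congenital microcephaly** — livebirth with head circumference below
  a sex- and GA-specific cut-off (3rd percentile, or −2 SD / −3 SD from
  the reference mean, configurable);
* **stillbirth** — fetal death at or beyond a viability threshold
  (default 28 completed weeks = 196 days);
* **neonatal death** — in-hospital death on days 0–27 after a livebirth;
* **neonatal infection** — a recorded diagnosis of invasive bloodstream
  infection, meningitis, or respiratory infection.

All anthropometric thresholds are strict inequalities: a value exactly
at the cut-off is not a case.  Missing measurements leave the label
absent and the record is tallied as unassessable for that rule; such
records remain in denominators, which mirrors surveillance practice of
using all livebirths (or all births, for stillbirth) as the denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .records import BirthRecord, records_to_frame


class Outcome(str, enum.Enum):
    """Study outcome labels."""

    LOW_BIRTHWEIGHT = "low_birthweight"
    PRETERM = "preterm"
    SGA = "sga"
    MICROCEPHALY = "microcephaly"
    STILLBIRTH = "stillbirth"
    NEONATAL_DEATH = "neonatal_death"
    NEONATAL_INFECTION = "neonatal_infection"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Outcomes defined only for livebirths (denominator: 1,000 livebirths).
LIVEBIRTH_OUTCOMES = (
    Outcome.LOW_BIRTHWEIGHT,
    Outcome.PRETERM,
    Outcome.SGA,
    Outcome.MICROCEPHALY,
    Outcome.NEONATAL_DEATH,
    Outcome.NEONATAL_INFECTION,
)

ALL_OUTCOMES = LIVEBIRTH_OUTCOMES + (Outcome.STILLBIRTH,)

MICROCEPHALY_RULES = ("p3", "minus2sd", "minus3sd")

_REFERENCE_COLUMNS = [
    "sex",
    "ga_week",
    "weight_p10_g",
    "weight_median_g",
    "weight_sd_g",
    "hc_p3_cm",
    "hc_median_cm",
    "hc_sd_cm",
]


class ReferenceRangeError(ValueError):
    """Gestational age outside the reference span with clamping disabled."""


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds and conventions for outcome classification.

    Defaults follow the internationally standard definitions; every
    threshold is overridable because facilities in practice use diverse
    charts and cut-off values.
    """

    lbw_threshold_g: float = 2500.0
    preterm_threshold_days: int = 259
    sga_percentile: int = 10
    microcephaly_rule: str = "p3"
    stillbirth_min_ga_days: int = 196
    stillbirth_when_ga_missing: bool = True
    neonatal_period_days: int = 28
    clamp_ga_to_reference: bool = True

    def __post_init__(self) -> None:
        if self.lbw_threshold_g <= 0 or self.preterm_threshold_days <= 0:
            raise ValueError("thresholds must be positive")
        if self.stillbirth_min_ga_days <= 0:
            raise ValueError("stillbirth_min_ga_days must be positive")
        if self.microcephaly_rule not in MICROCEPHALY_RULES:
            raise ValueError(f"microcephaly_rule must be one of {MICROCEPHALY_RULES}")
        if self.neonatal_period_days != 28:
            raise ValueError("the neonatal period is fixed at 28 days")


class GrowthReference:
    """Sex- and gestational-age-specific anthropometric reference.

    Wraps a table keyed by (sex, completed gestational week 24–42) with
    birthweight 10th percentile / median / SD and head-circumference 3rd
    percentile / median / SD columns.  Lookups at non-integral weeks use
    linear interpolation between adjacent whole-week rows; gestational
    ages outside the span are clamped to the nearest endpoint when the
    classification config allows it.
    """

    MEASURES = ("weight_p10", "weight_median", "weight_sd", "hc_p3", "hc_median", "hc_sd")

    def __init__(self, table: pd.DataFrame):
        missing = set(_REFERENCE_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"reference table missing columns {sorted(missing)}")
        table = table[_REFERENCE_COLUMNS].sort_values(["sex", "ga_week"]).reset_index(drop=True)
        for sex, grp in table.groupby("sex"):
            if (grp["weight_p10_g"] >= grp["weight_median_g"]).any():
                raise ValueError(f"p10 >= median in reference rows for sex={sex}")
            if not grp["weight_median_g"].is_monotonic_increasing:
                raise ValueError(f"weight medians not increasing for sex={sex}")
            if not grp["hc_median_cm"].is_monotonic_increasing:
                raise ValueError(f"HC medians not increasing for sex={sex}")
        self.table = table
        self._grids = {}
        for sex, grp in table.groupby("sex"):
            self._grids[sex] = {
                "weeks": grp["ga_week"].to_numpy(float),
                "weight_p10": grp["weight_p10_g"].to_numpy(float),
                "weight_median": grp["weight_median_g"].to_numpy(float),
                "weight_sd": grp["weight_sd_g"].to_numpy(float),
                "hc_p3": grp["hc_p3_cm"].to_numpy(float),
                "hc_median": grp["hc_median_cm"].to_numpy(float),
                "hc_sd": grp["hc_sd_cm"].to_numpy(float),
            }

    @property
    def week_span(self) -> tuple[float, float]:
        weeks = next(iter(self._grids.values()))["weeks"]
        return float(weeks[0]), float(weeks[-1])

    @classmethod
    def from_csv(cls, path) -> "GrowthReference":
        return cls(pd.read_csv(path))

    @classmethod
    def packaged(cls) -> "GrowthReference":
        """The synthetic reference grid shipped with the package."""
        with resources.files("perisurv.data").joinpath(
            "growth_reference_synthetic.csv"
        ).open() as fh:
            return cls(pd.read_csv(fh))

    def interp(self, sex, ga_days, measure, clamp: bool = True) -> np.ndarray:
        """Vectorized interpolated lookup; ``sex`` and ``ga_days`` are arrays."""
        if measure not in self.MEASURES:
            raise ValueError(f"unknown measure {measure!r}")
        sex = np.asarray(sex, dtype=object)
        ga_days = np.asarray(ga_days, dtype=float)
        out = np.full(ga_days.shape, np.nan)
        for s, grid in self._grids.items():
            mask = sex == s
            if not mask.any():
                continue
            weeks = ga_days[mask] / 7.0
            lo, hi = grid["weeks"][0], grid["weeks"][-1]
            if clamp:
                weeks = np.clip(weeks, lo, hi)
            elif ((weeks < lo) | (weeks > hi)).any():
                raise ReferenceRangeError(
                    f"gestational age outside reference span [{lo*7:.0f}, {hi*7:.0f}] days"
                )
            out[mask] = np.interp(weeks, grid["weeks"], grid[measure])
        return out


def lookup_reference(
    reference: GrowthReference,
    sex: str,
    gestational_age_days: float,
    measure: str,
    clamp: bool = True,
):
    """Scalar reference lookup.

    ``measure`` is one of ``weight_p10`` (grams), ``hc_p3`` (cm), or
    ``hc_mean_sd`` (returns the (median, SD) pair in cm).
    """
    if sex is None:
        raise ValueError("sex is required for a reference lookup")
    if sex not in reference._grids:
        raise ValueError(f"sex {sex!r} not in reference")
    if measure == "hc_mean_sd":
        med = reference.interp([sex], [gestational_age_days], "hc_median", clamp=clamp)
        sd = reference.interp([sex], [gestational_age_days], "hc_sd", clamp=clamp)
        return float(med[0]), float(sd[0])
    if measure not in ("weight_p10", "hc_p3"):
        raise ValueError(f"unknown measure {measure!r}")
    return float(reference.interp([sex], [gestational_age_days], measure, clamp=clamp)[0])


def microcephaly_cutoff(
    reference: GrowthReference, sex, ga_days, rule: str, clamp: bool = True
) -> np.ndarray:
    """Head-circumference cut-off (cm) under the configured rule."""
    if rule == "p3":
        return reference.interp(sex, ga_days, "hc_p3", clamp=clamp)
    med = reference.interp(sex, ga_days, "hc_median", clamp=clamp)
    sd = reference.interp(sex, ga_days, "hc_sd", clamp=clamp)
    k = 2.0 if rule == "minus2sd" else 3.0
    return med - k * sd


def _classify_frame(
    df: pd.DataFrame, config: ClassificationConfig, reference: GrowthReference
) -> pd.DataFrame:
    """Boolean label matrix (one column per outcome) plus assessability.

    Returns a frame with a ``label_<outcome>`` and an ``assessable_<outcome>``
    column for every outcome; unassessable implies label False.
    """
    live = (df["delivery_outcome"] == "livebirth").to_numpy()
    ga = df["gestational_age_days"].to_numpy(dtype=float, na_value=np.nan)
    bw = df["birthweight_g"].to_numpy(dtype=float, na_value=np.nan)
    hc = df["head_circumference_cm"].to_numpy(dtype=float, na_value=np.nan)
    sex = df["sex"].to_numpy(dtype=object)
    death_day = df["neonatal_death_day"].to_numpy(dtype=float, na_value=np.nan)
    subtype = df["infection_subtype"].fillna("none").to_numpy(dtype=object)

    has_ga = ~np.isnan(ga)
    has_bw = ~np.isnan(bw)
    has_hc = ~np.isnan(hc)
    has_sex = pd.notna(df["sex"]).to_numpy()
    clamp = config.clamp_ga_to_reference

    out = pd.DataFrame(index=df.index)

    out["assessable_low_birthweight"] = live & has_bw
    out["label_low_birthweight"] = live & has_bw & (bw < config.lbw_threshold_g)

    out["assessable_preterm"] = live & has_ga
    out["label_preterm"] = live & has_ga & (ga < config.preterm_threshold_days)

    sga_ok = live & has_bw & has_ga & has_sex
    p10 = np.full(len(df), np.nan)
    if sga_ok.any():
        p10[sga_ok] = reference.interp(sex[sga_ok], ga[sga_ok], "weight_p10", clamp=clamp)
    out["assessable_sga"] = sga_ok
    out["label_sga"] = sga_ok & (bw < p10)

    mc_ok = live & has_hc & has_ga & has_sex
    cutoff = np.full(len(df), np.nan)
    if mc_ok.any():
        cutoff[mc_ok] = microcephaly_cutoff(
            reference, sex[mc_ok], ga[mc_ok], config.microcephaly_rule, clamp=clamp
        )
    out["assessable_microcephaly"] = mc_ok
    out["label_microcephaly"] = mc_ok & (hc < cutoff)

    sb = (df["delivery_outcome"] == "stillbirth").to_numpy()
    sb_ga_ok = has_ga & (ga >= config.stillbirth_min_ga_days)
    if config.stillbirth_when_ga_missing:
        sb_label = sb & (sb_ga_ok | ~has_ga)
        out["assessable_stillbirth"] = np.ones(len(df), bool)
    else:
        sb_label = sb & sb_ga_ok
        out["assessable_stillbirth"] = ~sb | has_ga
    out["label_stillbirth"] = sb_label

    out["assessable_neonatal_death"] = live
    out["label_neonatal_death"] = (
        live & ~np.isnan(death_day) & (death_day < config.neonatal_period_days)
    )

    out["assessable_neonatal_infection"] = live
    out["label_neonatal_infection"] = live & (subtype != "none")
    return out


def classify_birth(
    record: BirthRecord,
    config: ClassificationConfig | None = None,
    reference: GrowthReference | None = None,
) -> set[Outcome]:
    """Outcome label set for a single delivery."""
    config = config or ClassificationConfig()
    reference = reference or GrowthReference.packaged()
    labels = _classify_frame(records_to_frame([record]), config, reference)
    return {o for o in ALL_OUTCOMES if bool(labels.at[0, f"label_{o.value}"])}


@dataclass
class CohortClassification:
    """Per-record labels and per-outcome counts for a classified cohort."""

    labels: pd.DataFrame  # boolean label/assessable matrix, aligned to records
    counts: pd.DataFrame  # site_id, outcome, numerator, denominator, ...
    label_sets: list[set[Outcome]] = field(repr=False, default_factory=list)


def classify_cohort(
    records: list[BirthRecord],
    config: ClassificationConfig | None = None,
    reference: GrowthReference | None = None,
) -> CohortClassification:
    """Classify a cohort and tabulate per-site, per-outcome counts.

    Denominators are livebirths for livebirth outcomes and total births
    for stillbirth.  Records whose measurements are missing for a rule
    are counted in an ``unassessable`` column but stay in denominators.
    """
    config = config or ClassificationConfig()
    reference = reference or GrowthReference.packaged()
    df = records_to_frame(records)
    if df.empty:
        counts = pd.DataFrame(
            columns=[
                "site_id",
                "outcome",
                "numerator",
                "denominator",
                "denominator_kind",
                "unassessable",
            ]
        )
        return CohortClassification(labels=pd.DataFrame(), counts=counts, label_sets=[])
    labels = _classify_frame(df, config, reference)
    labels.insert(0, "site_id", df["site_id"])

    rows = []
    for site_id, grp in labels.groupby("site_id", sort=True):
        site_df = df.loc[grp.index]
        live_mask = (site_df["delivery_outcome"] == "livebirth").to_numpy()
        n_total = len(grp)
        n_live = int(live_mask.sum())
        for outcome in ALL_OUTCOMES:
            is_sb = outcome is Outcome.STILLBIRTH
            assessable = grp[f"assessable_{outcome.value}"].to_numpy()
            # unassessable is counted within the outcome's denominator population
            unassessable = (
                int((~assessable).sum()) if is_sb else int((live_mask & ~assessable).sum())
            )
            rows.append(
                {
                    "site_id": site_id,
                    "outcome": outcome.value,
                    "numerator": int(grp[f"label_{outcome.value}"].sum()),
                    "denominator": n_total if is_sb else n_live,
                    "denominator_kind": "total_births" if is_sb else "livebirths",
                    "unassessable": unassessable,
                }
            )
    counts = pd.DataFrame(rows)
    label_sets = [
        {o for o in ALL_OUTCOMES if labels.at[i, f"label_{o.value}"]} for i in labels.index
    ]
    return CohortClassification(labels=labels, counts=counts, label_sets=label_sets)
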