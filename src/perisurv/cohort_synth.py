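"""Multi-site synthetic facility birth line lists.

Emulates the statistical structure of a facility-based perinatal
surveillance network: each site has an annual obstetric load, per-birth
probabilities of stillbirth, preterm delivery, in-hospital neonatal
death and neonatal infection, reference-based anthropometry, per-measure
missingness, and imperfect routine ascertainment (a true case is flagged
by the site with a per-outcome sensitivity; a non-case may be falsely
flagged).

The generative model is deliberately simple.  Gestational age is a
two-component mixture: a term component (truncated normal, mean 276 d,
SD 8 d on [259, 294]) and a preterm component 259 − d with d drawn from
an exponential of mean 16 d truncated to keep gestational age above the
site's registration floor.  Birthweight and head circumference are drawn
normally around the packaged reference median at the child's sex and
gestational age, so that by construction about 10% of livebirths fall
below the weight 10th percentile (small for gestational age) and about
3% below the head-circumference 3rd percentile; a configurable excess
fraction of heads is redrawn from below the 1st percentile to emulate
pathological microcephaly.  Outcomes are drawn independently per birth.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .outcome_rules import (
    ALL_OUTCOMES,
    ClassificationConfig,
    GrowthReference,
    Outcome,
    _classify_frame,
)
from .records import BirthRecord, records_to_frame

MEASURES = ("gestational_age", "birthweight", "head_circumference")

TERM_GA_MEAN = 276.0
TERM_GA_SD = 8.0
TERM_GA_RANGE = (259.0, 294.0)
PRETERM_EXP_MEAN_DAYS = 16.0


class EmptyCohortError(ValueError):
    """Simulation requested for a zero-duration cohort."""


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name}={value} outside [0, 1]")


@dataclass(frozen=True)
class SiteProfile:
    """Simulation parameters for one facility.

    ``ascertainment_sensitivity`` and ``false_flag_prob`` map outcome
    labels to the probability that a true case is site-flagged and that
    a non-case is falsely flagged; unlisted outcomes default to perfect
    sensitivity and zero false flagging.
    """

    site_id: str
    annual_births: int
    facility_level: str = "tertiary"
    duration_weeks: int = 52
    sex_ratio_male: float = 0.515
    stillbirth_prob: float = 0.0
    preterm_prob: float = 0.0
    neonatal_death_prob: float = 0.0
    infection_prob: float = 0.0
    infection_subtype_mix: tuple[float, float, float] = (0.85, 0.05, 0.10)
    microcephaly_excess_prob: float = 0.0
    measurement_missingness: Mapping[str, float] = field(default_factory=dict)
    ascertainment_sensitivity: Mapping[str, float] = field(default_factory=dict)
    false_flag_prob: Mapping[str, float] = field(default_factory=dict)
    #: Minimum gestational age (days) for a birth to be registered at all.
    min_ga_days: int = 154
    #: Gestational-age floor for registered stillbirths (28 completed weeks).
    stillbirth_min_ga_days: int = 196

    def __post_init__(self) -> None:
        if self.annual_births < 1:
            raise ValueError("annual_births must be >= 1")
        if self.facility_level not in ("primary", "secondary", "tertiary"):
            raise ValueError(f"unknown facility_level {self.facility_level!r}")
        for name in (
            "sex_ratio_male",
            "stillbirth_prob",
            "preterm_prob",
            "neonatal_death_prob",
            "infection_prob",
            "microcephaly_excess_prob",
        ):
            _check_prob(name, getattr(self, name))
        mix = tuple(float(p) for p in self.infection_subtype_mix)
        if len(mix) != 3:
            raise ValueError("infection_subtype_mix must have 3 entries")
        for p in mix:
            _check_prob("infection_subtype_mix entry", p)
        if abs(sum(mix) - 1.0) > 1e-9:
            raise ValueError("infection_subtype_mix must sum to 1")
        object.__setattr__(self, "infection_subtype_mix", mix)
        for mapping, label in (
            (self.measurement_missingness, "measurement_missingness"),
            (self.ascertainment_sensitivity, "ascertainment_sensitivity"),
            (self.false_flag_prob, "false_flag_prob"),
        ):
            for key, value in mapping.items():
                _check_prob(f"{label}[{key}]", value)
        bad = set(self.measurement_missingness) - set(MEASURES)
        if bad:
            raise ValueError(f"unknown measures in measurement_missingness: {sorted(bad)}")

    def sensitivity(self, outcome: Outcome | str) -> float:
        return float(self.ascertainment_sensitivity.get(str(Outcome(outcome)), 1.0))

    def false_flag(self, outcome: Outcome | str) -> float:
        return float(self.false_flag_prob.get(str(Outcome(outcome)), 0.0))

    @classmethod
    def from_dict(cls, data: Mapping) -> "SiteProfile":
        data = dict(data)
        if "infection_subtype_mix" in data:
            data["infection_subtype_mix"] = tuple(data["infection_subtype_mix"])
        return cls(**data)


def load_site_profiles(path) -> list[SiteProfile]:
    """Read site profiles from a YAML config (a ``sites`` list of mappings)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [SiteProfile.from_dict(entry) for entry in doc["sites"]]


def packaged_site_profiles() -> list[SiteProfile]:
    """The 21-site fixture network shipped with the package.

    Loads and per-outcome rates are transcribed from a published
    multi-country facility surveillance network; routine ascertainment
    sensitivities reflect its post-amendment sensitivity analysis.
    """
    path = resources.files("perisurv.data").joinpath("site_profiles.yaml")
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    return [SiteProfile.from_dict(entry) for entry in doc["sites"]]


def packaged_site_counts() -> pd.DataFrame:
    """Per-site outcome counts fixture (whole study period)."""
    with resources.files("perisurv.data").joinpath("site_counts.csv").open() as fh:
        return pd.read_csv(fh)


def packaged_ascertainment_counts() -> pd.DataFrame:
    """Per-site post-amendment ascertainment counts fixture."""
    with resources.files("perisurv.data").joinpath("ascertainment_counts.csv").open() as fh:
        return pd.read_csv(fh)


def _draw_gestational_age(
    rng: np.random.Generator,
    n: int,
    preterm_prob: float,
    floor_days: int,
) -> np.ndarray:
    """Two-component term/preterm gestational-age mixture, integer days."""
    preterm = rng.random(n) < preterm_prob
    ga = np.empty(n)
    n_term = int((~preterm).sum())
    if n_term:
        a = (TERM_GA_RANGE[0] - TERM_GA_MEAN) / TERM_GA_SD
        b = (TERM_GA_RANGE[1] - TERM_GA_MEAN) / TERM_GA_SD
        ga[~preterm] = stats.truncnorm.rvs(
            a, b, loc=TERM_GA_MEAN, scale=TERM_GA_SD, size=n_term, random_state=rng
        )
    n_pre = int(preterm.sum())
    if n_pre:
        # deficit below 259 d from a truncated exponential; GA stays in
        # [floor_days, 258]
        d_lo, d_hi = 1.0, 259.0 - floor_days
        scale = PRETERM_EXP_MEAN_DAYS
        f_lo = 1.0 - np.exp(-d_lo / scale)
        f_hi = 1.0 - np.exp(-d_hi / scale)
        u = rng.random(n_pre)
        d = -scale * np.log(1.0 - (f_lo + u * (f_hi - f_lo)))
        ga[preterm] = 259.0 - d
    return np.clip(np.rint(ga), floor_days, TERM_GA_RANGE[1]).astype(int)


def simulate_site(
    profile: SiteProfile,
    seed: int,
    reference: GrowthReference | None = None,
    poisson_size: bool = False,
    start_date: _dt.date = _dt.date(2019, 5, 1),
) -> list[BirthRecord]:
    """Simulate one site's line list; deterministic given (profile, seed).

    ``poisson_size`` replaces the fixed cohort size
    ``round(annual_births * duration_weeks / 52)`` with a Poisson draw of
    the same mean.
    """
    if profile.duration_weeks == 0:
        raise EmptyCohortError(f"site {profile.site_id}: duration_weeks=0")
    reference = reference or GrowthReference.packaged()
    rng = np.random.default_rng(seed)

    expected = profile.annual_births * profile.duration_weeks / 52.0
    n = int(rng.poisson(expected)) if poisson_size else int(round(expected))

    day_offsets = rng.integers(0, profile.duration_weeks * 7, size=n)
    sex = np.where(rng.random(n) < profile.sex_ratio_male, "male", "female").astype(object)
    stillborn = rng.random(n) < profile.stillbirth_prob

    ga = _draw_gestational_age(rng, n, profile.preterm_prob, profile.min_ga_days)
    if stillborn.any():
        # registered stillbirths are at/above the stillbirth GA floor
        sb_floor = max(profile.min_ga_days, profile.stillbirth_min_ga_days)
        ga_sb = _draw_gestational_age(
            np.random.default_rng(rng.integers(2**31)),
            int(stillborn.sum()),
            profile.preterm_prob,
            sb_floor,
        )
        ga = ga.copy()
        ga[stillborn] = ga_sb

    wt_med = reference.interp(sex, ga, "weight_median")
    wt_sd = reference.interp(sex, ga, "weight_sd")
    birthweight = np.maximum(np.rint(rng.normal(wt_med, wt_sd)), 150.0)

    hc_med = reference.interp(sex, ga, "hc_median")
    hc_sd = reference.interp(sex, ga, "hc_sd")
    head_circ = rng.normal(hc_med, hc_sd)
    small_head = rng.random(n) < profile.microcephaly_excess_prob
    if small_head.any():
        # redraw from strictly below the 1st reference percentile
        u = rng.random(int(small_head.sum())) * 0.01
        head_circ[small_head] = hc_med[small_head] + hc_sd[small_head] * stats.norm.ppf(u)
    head_circ = np.round(head_circ, 1)

    live = ~stillborn
    dies = live & (rng.random(n) < profile.neonatal_death_prob)
    day_weights = 0.75 ** np.arange(28)
    death_day = rng.choice(28, size=n, p=day_weights / day_weights.sum())

    infected = live & (rng.random(n) < profile.infection_prob)
    subtype_idx = rng.choice(3, size=n, p=profile.infection_subtype_mix)
    subtype_names = np.array(
        ["invasive_bloodstream", "meningitis", "respiratory"], dtype=object
    )

    miss = {
        m: rng.random(n) < float(profile.measurement_missingness.get(m, 0.0))
        for m in MEASURES
    }

    records = []
    for i in range(n):
        records.append(
            BirthRecord(
                site_id=profile.site_id,
                birth_date=start_date + _dt.timedelta(days=int(day_offsets[i])),
                delivery_outcome="stillbirth" if stillborn[i] else "livebirth",
                sex=str(sex[i]),
                gestational_age_days=None if miss["gestational_age"][i] else int(ga[i]),
                birthweight_g=None if miss["birthweight"][i] else float(birthweight[i]),
                head_circumference_cm=(
                    None if miss["head_circumference"][i] else float(head_circ[i])
                ),
                neonatal_death_day=int(death_day[i]) if dies[i] else None,
                infection_subtype=str(subtype_names[subtype_idx[i]]) if infected[i] else "none",
            )
        )
    return records


def apply_site_ascertainment(
    records: list[BirthRecord],
    profile: SiteProfile,
    seed: int,
    config: ClassificationConfig | None = None,
    reference: GrowthReference | None = None,
) -> list[BirthRecord]:
    """Write imperfect routine site flags onto a line list.

    True labels are derived with the standardized classification rules;
    for each outcome, each true case is flagged with the profile's
    per-outcome ascertainment sensitivity and each non-case with its
    false-flag probability.  Measurements are unchanged.
    """
    if not records:
        return []
    config = config or ClassificationConfig()
    reference = reference or GrowthReference.packaged()
    labels = _classify_frame(records_to_frame(records), config, reference)
    rng = np.random.default_rng(seed)
    n = len(records)
    flag_matrix = {}
    for outcome in ALL_OUTCOMES:  # fixed order keeps draws reproducible
        truth = labels[f"label_{outcome.value}"].to_numpy()
        u = rng.random(n)
        sens = profile.sensitivity(outcome)
        ff = profile.false_flag(outcome)
        flag_matrix[outcome.value] = np.where(truth, u < sens, u < ff)
    out = []
    for i, record in enumerate(records):
        flags = frozenset(name for name, col in flag_matrix.items() if col[i])
        out.append(record.with_flags(flags))
    return out


def aggregate_monthly(records: list[BirthRecord]) -> pd.DataFrame:
    """Monthly site aggregates: births, livebirths, per-outcome flag counts.

    Summing any column over months reproduces the whole-period totals;
    an empty record list yields an empty table.
    """
    columns = ["site_id", "month", "births", "livebirths"] + [
        f"flagged_{o.value}" for o in ALL_OUTCOMES
    ]
    if not records:
        return pd.DataFrame(columns=columns)
    df = records_to_frame(records)
    df["month"] = pd.to_datetime(df["birth_date"]).dt.strftime("%Y-%m")
    df["births"] = 1
    df["livebirths"] = (df["delivery_outcome"] == "livebirth").astype(int)
    flags = [r.site_flags for r in records]
    for outcome in ALL_OUTCOMES:
        df[f"flagged_{outcome.value}"] = [int(outcome.value in f) for f in flags]
    agg = (
        df.groupby(["site_id", "month"], sort=True)[columns[2:]]
        .sum()
        .reset_index()
    )
    return agg[columns]


def write_linelist(records: list[BirthRecord], path) -> None:
    """Write a line list as delimited text (ISO dates, empty = missing)."""
    records_to_frame(records).to_csv(path, index=False)
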