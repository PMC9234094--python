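"""Per-birth line-list records and their tabular representation.

A line list holds one row per delivery recorded at a facility: the
delivery outcome (livebirth or stillbirth), the newborn's sex and
anthropometry, the day of any in-hospital neonatal death, any neonatal
infection diagnosis, and the set of study outcomes the site itself
flagged during routine surveillance.  Measurements may be missing; a
missing value means the facility did not record it, which is data, not
an error.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import pandas as pd

DELIVERY_OUTCOMES = ("livebirth", "stillbirth")
SEXES = ("male", "female")
INFECTION_SUBTYPES = ("none", "invasive_bloodstream", "meningitis", "respiratory")

#: Valid gestational-age span for a recorded delivery, in days
#: (20 completed weeks to 45 weeks).
GA_DAYS_MIN = 140
GA_DAYS_MAX = 315

#: Neonatal period: death on day 0 through day 27 after a livebirth.
NEONATAL_DAY_MAX = 27

LINELIST_COLUMNS = [
    "site_id",
    "birth_date",
    "delivery_outcome",
    "sex",
    "gestational_age_days",
    "birthweight_g",
    "head_circumference_cm",
    "neonatal_death_day",
    "infection_subtype",
    "site_flags",
]


@dataclass(frozen=True)
class BirthRecord:
    """One delivery at one facility.

    ``site_flags`` is the set of outcome labels the site reported for
    this birth through its routine surveillance; it is distinct from the
    labels a standardized classification rule would assign.
    """

    site_id: str
    birth_date: _dt.date
    delivery_outcome: str
    sex: str | None = None
    gestational_age_days: int | None = None
    birthweight_g: float | None = None
    head_circumference_cm: float | None = None
    neonatal_death_day: int | None = None
    infection_subtype: str = "none"
    site_flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.delivery_outcome not in DELIVERY_OUTCOMES:
            raise ValueError(f"unknown delivery_outcome {self.delivery_outcome!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.infection_subtype not in INFECTION_SUBTYPES:
            raise ValueError(f"unknown infection_subtype {self.infection_subtype!r}")
        if self.gestational_age_days is not None and not (
            GA_DAYS_MIN <= self.gestational_age_days <= GA_DAYS_MAX
        ):
            raise ValueError(
                f"gestational_age_days={self.gestational_age_days} outside "
                f"[{GA_DAYS_MIN}, {GA_DAYS_MAX}]"
            )
        if self.birthweight_g is not None and self.birthweight_g <= 0:
            raise ValueError("birthweight_g must be positive when present")
        if self.neonatal_death_day is not None and not (
            0 <= self.neonatal_death_day <= NEONATAL_DAY_MAX
        ):
            raise ValueError("neonatal_death_day outside [0, 27]")
        if self.delivery_outcome == "stillbirth":
            if self.neonatal_death_day is not None:
                raise ValueError("stillbirth cannot have a neonatal death day")
            if self.infection_subtype != "none":
                raise ValueError("stillbirth cannot carry a neonatal infection")
        if not isinstance(self.site_flags, frozenset):
            object.__setattr__(self, "site_flags", frozenset(self.site_flags))

    def with_flags(self, flags) -> "BirthRecord":
        return replace(self, site_flags=frozenset(flags))


def records_to_frame(records: list[BirthRecord]) -> pd.DataFrame:
    """Tabulate records into a DataFrame with one column per field.

    ``site_flags`` is serialized as a ``;``-joined sorted string (empty
    string for no flags) so the frame round-trips through delimited text.
    """
    rows = []
    for r in records:
        rows.append(
            (
                r.site_id,
                r.birth_date,
                r.delivery_outcome,
                r.sex,
                r.gestational_age_days,
                r.birthweight_g,
                r.head_circumference_cm,
                r.neonatal_death_day,
                r.infection_subtype,
                ";".join(sorted(r.site_flags)),
            )
        )
    df = pd.DataFrame(rows, columns=LINELIST_COLUMNS)
    for col in ("gestational_age_days", "neonatal_death_day"):
        df[col] = df[col].astype("Int64")
    for col in ("birthweight_g", "head_circumference_cm"):
        df[col] = df[col].astype("Float64")
    return df


def frame_to_records(df: pd.DataFrame) -> list[BirthRecord]:
    """Inverse of :func:`records_to_frame`; raises on invalid rows."""
    records = []
    for row in df.itertuples(index=False):
        birth_date = row.birth_date
        if isinstance(birth_date, str):
            birth_date = _dt.date.fromisoformat(birth_date)
        elif isinstance(birth_date, pd.Timestamp):
            birth_date = birth_date.date()
        flags = row.site_flags
        if pd.isna(flags):
            flags = ""
        records.append(
            BirthRecord(
                site_id=str(row.site_id),
                birth_date=birth_date,
                delivery_outcome=str(row.delivery_outcome),
                sex=None if pd.isna(row.sex) else str(row.sex),
                gestational_age_days=(
                    None
                    if pd.isna(row.gestational_age_days)
                    else int(row.gestational_age_days)
                ),
                birthweight_g=(
                    None if pd.isna(row.birthweight_g) else float(row.birthweight_g)
                ),
                head_circumference_cm=(
                    None
                    if pd.isna(row.head_circumference_cm)
                    else float(row.head_circumference_cm)
                ),
                neonatal_death_day=(
                    None
                    if pd.isna(row.neonatal_death_day)
                    else int(row.neonatal_death_day)
                ),
                infection_subtype=(
                    "none" if pd.isna(row.infection_subtype) else str(row.infection_subtype)
                ),
                site_flags=frozenset(f for f in str(flags).split(";") if f),
            )
        )
    return records
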