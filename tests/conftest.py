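import datetime as dt

import pytest

from perisurv import (
    BirthRecord,
    ClassificationConfig,
    GrowthReference,
    SiteProfile,
)


@pytest.fixture(scope="session")
def reference() -> GrowthReference:
    return GrowthReference.packaged()


@pytest.fixture(scope="session")
def config() -> ClassificationConfig:
    return ClassificationConfig()


def make_profile(**overrides) -> SiteProfile:
    defaults = dict(
        site_id="testsite",
        annual_births=2000,
        stillbirth_prob=0.02,
        preterm_prob=0.10,
        neonatal_death_prob=0.01,
        infection_prob=0.02,
    )
    defaults.update(overrides)
    return SiteProfile(**defaults)


@pytest.fixture
def profile_factory():
    return make_profile


def make_livebirth(**overrides) -> BirthRecord:
    defaults = dict(
        site_id="s1",
        birth_date=dt.date(2019, 6, 1),
        delivery_outcome="livebirth",
        sex="male",
        gestational_age_days=280,
        birthweight_g=3200.0,
        head_circumference_cm=34.5,
    )
    defaults.update(overrides)
    return BirthRecord(**defaults)


@pytest.fixture
def livebirth_factory():
    return make_livebirth
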