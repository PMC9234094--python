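"""Standardized outcome classification: thresholds, reference lookups."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from perisurv import (
    BirthRecord,
    ClassificationConfig,
    Outcome,
    classify_birth,
    classify_cohort,
    lookup_reference,
)
from perisurv.outcome_rules import ReferenceRangeError, microcephaly_cutoff


class TestReferenceLookup:
    def test_exact_row_lookup_returns_packaged_value(self, reference):
        row = reference.table.query("sex == 'male' and ga_week == 40").iloc[0]
        assert lookup_reference(reference, "male", 280, "weight_p10") == pytest.approx(
            row["weight_p10_g"]
        )

    def test_midweek_lookup_is_mean_of_adjacent_rows(self, reference):
        r40 = reference.table.query("sex == 'female' and ga_week == 40").iloc[0]
        r41 = reference.table.query("sex == 'female' and ga_week == 41").iloc[0]
        got = lookup_reference(reference, "female", 283.5, "weight_p10")
        assert got == pytest.approx((r40["weight_p10_g"] + r41["weight_p10_g"]) / 2)

    @pytest.mark.parametrize("measure", ["weight_p10", "hc_p3"])
    def test_interpolation_matches_piecewise_linear_oracle(self, reference, measure):
        """Any gestational age agrees with a brute-force piecewise evaluator."""
        col = {"weight_p10": "weight_p10_g", "hc_p3": "hc_p3_cm"}[measure]
        sub = reference.table.query("sex == 'male'")
        weeks = sub["ga_week"].to_numpy(float)
        vals = sub[col].to_numpy(float)

        def oracle(ga_days: float) -> float:
            w = min(max(ga_days / 7.0, weeks[0]), weeks[-1])
            for i in range(len(weeks) - 1):
                if weeks[i] <= w <= weeks[i + 1]:
                    frac = (w - weeks[i]) / (weeks[i + 1] - weeks[i])
                    return vals[i] + frac * (vals[i + 1] - vals[i])
            raise AssertionError  # pragma: no cover

        rng = np.random.default_rng(5)
        for ga in rng.uniform(160, 300, size=40):
            assert lookup_reference(reference, "male", ga, measure) == pytest.approx(
                oracle(ga), abs=1e-9
            )

    def test_hc_mean_sd_returns_pair(self, reference):
        med, sd = lookup_reference(reference, "male", 280, "hc_mean_sd")
        row = reference.table.query("sex == 'male' and ga_week == 40").iloc[0]
        assert (med, sd) == (pytest.approx(row["hc_median_cm"]), pytest.approx(row["hc_sd_cm"]))

    def test_missing_sex_and_out_of_span_errors(self, reference):
        with pytest.raises(ValueError):
            lookup_reference(reference, None, 280, "weight_p10")
        with pytest.raises(ReferenceRangeError):
            lookup_reference(reference, "male", 150, "weight_p10", clamp=False)


class TestClassifyBirth:
    @pytest.mark.parametrize(
        "birthweight,expected", [(2499.0, True), (2500.0, False), (2501.0, False)]
    )
    def test_low_birthweight_strict_threshold(
        self, livebirth_factory, config, reference, birthweight, expected
    ):
        labels = classify_birth(livebirth_factory(birthweight_g=birthweight), config, reference)
        assert (Outcome.LOW_BIRTHWEIGHT in labels) is expected

    @pytest.mark.parametrize("ga,expected", [(258, True), (259, False)])
    def test_preterm_37_completed_weeks_boundary(
        self, livebirth_factory, config, reference, ga, expected
    ):
        labels = classify_birth(livebirth_factory(gestational_age_days=ga), config, reference)
        assert (Outcome.PRETERM in labels) is expected

    def test_sga_boundary_against_packaged_percentile(self, livebirth_factory, config, reference):
        p10 = lookup_reference(reference, "male", 280, "weight_p10")
        below = livebirth_factory(birthweight_g=p10 - 1)
        at = livebirth_factory(birthweight_g=p10)
        assert Outcome.SGA in classify_birth(below, config, reference)
        assert Outcome.SGA not in classify_birth(at, config, reference)

    @pytest.mark.parametrize("rule", ["p3", "minus2sd", "minus3sd"])
    def test_microcephaly_rule_cutoffs_strict(self, livebirth_factory, reference, rule):
        cfg = ClassificationConfig(microcephaly_rule=rule)
        cutoff = float(microcephaly_cutoff(reference, ["male"], [280], rule)[0])
        small = livebirth_factory(head_circumference_cm=cutoff - 0.1)
        at = livebirth_factory(head_circumference_cm=cutoff)
        assert Outcome.MICROCEPHALY in classify_birth(small, cfg, reference)
        assert Outcome.MICROCEPHALY not in classify_birth(at, cfg, reference)

    def test_stillbirth_excludes_all_livebirth_labels(self, config, reference):
        record = BirthRecord(
            site_id="s1",
            birth_date=dt.date(2019, 7, 1),
            delivery_outcome="stillbirth",
            sex="female",
            gestational_age_days=240,
            birthweight_g=1500.0,
        )
        assert classify_birth(record, config, reference) == {Outcome.STILLBIRTH}

    def test_stillbirth_gestational_age_floor(self, config, reference):
        early = BirthRecord(
            site_id="s1",
            birth_date=dt.date(2019, 7, 1),
            delivery_outcome="stillbirth",
            gestational_age_days=195,
        )
        missing_ga = BirthRecord(
            site_id="s1", birth_date=dt.date(2019, 7, 1), delivery_outcome="stillbirth"
        )
        assert classify_birth(early, config, reference) == set()
        # GA unknown counts as stillbirth under the default policy
        assert classify_birth(missing_ga, config, reference) == {Outcome.STILLBIRTH}
        strict = ClassificationConfig(stillbirth_when_ga_missing=False)
        assert classify_birth(missing_ga, strict, reference) == set()

    @pytest.mark.parametrize("day,expected", [(0, True), (27, True)])
    def test_neonatal_death_within_neonatal_period(
        self, livebirth_factory, config, reference, day, expected
    ):
        labels = classify_birth(livebirth_factory(neonatal_death_day=day), config, reference)
        assert (Outcome.NEONATAL_DEATH in labels) is expected

    def test_infection_label_from_subtype(self, livebirth_factory, config, reference):
        rec = livebirth_factory(infection_subtype="meningitis")
        assert Outcome.NEONATAL_INFECTION in classify_birth(rec, config, reference)

    def test_missing_measurement_means_no_label(self, livebirth_factory, config, reference):
        rec = livebirth_factory(birthweight_g=None, head_circumference_cm=None)
        labels = classify_birth(rec, config, reference)
        assert Outcome.LOW_BIRTHWEIGHT not in labels
        assert Outcome.SGA not in labels
        assert Outcome.MICROCEPHALY not in labels

    @settings(derandomize=True, max_examples=40)
    @given(
        bw=st.floats(min_value=300, max_value=4500),
        drop=st.floats(min_value=0.1, max_value=1500),
    )
    def test_lowering_birthweight_never_removes_lbw_or_sga(self, bw, drop):
        from perisurv import GrowthReference

        reference = GrowthReference.packaged()
        config = ClassificationConfig()
        high = classify_birth(
            BirthRecord(
                site_id="s",
                birth_date=dt.date(2019, 6, 1),
                delivery_outcome="livebirth",
                sex="male",
                gestational_age_days=280,
                birthweight_g=bw,
            ),
            config,
            reference,
        )
        low = classify_birth(
            BirthRecord(
                site_id="s",
                birth_date=dt.date(2019, 6, 1),
                delivery_outcome="livebirth",
                sex="male",
                gestational_age_days=280,
                birthweight_g=max(bw - drop, 150.0),
            ),
            config,
            reference,
        )
        for label in (Outcome.LOW_BIRTHWEIGHT, Outcome.SGA):
            if label in high:
                assert label in low


class TestClassifyCohort:
    def test_denominators_split_live_and_total_births(self, livebirth_factory, config, reference):
        records = [
            livebirth_factory(),
            BirthRecord(
                site_id="s1",
                birth_date=dt.date(2019, 7, 1),
                delivery_outcome="stillbirth",
                gestational_age_days=230,
            ),
        ]
        counts = classify_cohort(records, config, reference).counts
        sb = counts.query("outcome == 'stillbirth'").iloc[0]
        lbw = counts.query("outcome == 'low_birthweight'").iloc[0]
        assert sb["denominator"] == 2 and sb["denominator_kind"] == "total_births"
        assert lbw["denominator"] == 1 and lbw["denominator_kind"] == "livebirths"

    def test_all_livebirth_cohort_has_equal_denominators(
        self, livebirth_factory, config, reference
    ):
        records = [livebirth_factory() for _ in range(5)]
        counts = classify_cohort(records, config, reference).counts
        assert counts.query("outcome == 'stillbirth'")["numerator"].iloc[0] == 0
        assert counts["denominator"].nunique() == 1

    def test_counts_equal_sum_of_per_record_labels(self, livebirth_factory, config, reference):
        records = [
            livebirth_factory(birthweight_g=2000.0),
            livebirth_factory(birthweight_g=2499.0),
            livebirth_factory(birthweight_g=3500.0),
        ]
        result = classify_cohort(records, config, reference)
        from_sets = sum(Outcome.LOW_BIRTHWEIGHT in s for s in result.label_sets)
        table = result.counts.query("outcome == 'low_birthweight'")["numerator"].iloc[0]
        assert from_sets == table == 2

    def test_unassessable_tally_keeps_denominator(self, livebirth_factory, config, reference):
        records = [livebirth_factory(birthweight_g=None), livebirth_factory()]
        counts = classify_cohort(records, config, reference).counts
        lbw = counts.query("outcome == 'low_birthweight'").iloc[0]
        assert lbw["unassessable"] == 1 and lbw["denominator"] == 2

    def test_empty_cohort_yields_empty_counts(self, config, reference):
        result = classify_cohort([], config, reference)
        assert result.counts.empty and result.label_sets == []
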