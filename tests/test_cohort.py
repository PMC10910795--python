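"""Encounter merging, lab-window attachment, record selection, filters."""

import numpy as np
import pandas as pd
import pytest

import seasonri as sri
from seasonri.cohort import (EmptyCohortError, apply_cohort_filters, attach_labs,
                             merge_encounters, select_most_abnormal, truncate_code)

from conftest import make_encounter, make_record

H = pd.Timedelta(hours=1)
T0 = pd.Timestamp("2012-03-01 09:00:00")


def simple_admissions(*windows):
    rows = []
    for i, (pid, start) in enumerate(windows):
        rows.append({"admission_id": f"A{i}", "patient_id": pid,
                     "start": pd.Timestamp(start), "end": pd.Timestamp(start) + 48 * H,
                     "codes": "", "death_date": pd.NaT, "sex": "F",
                     "age_at_start": 50, "n_encounters": 1})
    return pd.DataFrame(rows)


class TestMergeEncounters:
    def test_gap_under_24h_merges(self):
        enc = pd.DataFrame([
            make_encounter("P1", "2012-01-01 08:00", "2012-01-01 09:00"),
            make_encounter("P1", "2012-01-02 08:00", "2012-01-02 10:00"),  # 23 h gap
        ])
        assert len(merge_encounters(enc)) == 1

    def test_gap_of_25h_does_not_merge(self):
        enc = pd.DataFrame([
            make_encounter("P1", "2012-01-01 08:00", "2012-01-01 09:00"),
            make_encounter("P1", "2012-01-02 10:00", "2012-01-02 11:00"),  # 25 h gap
        ])
        assert len(merge_encounters(enc)) == 2

    def test_exactly_24h_gap_is_not_merged(self):
        enc = pd.DataFrame([
            make_encounter("P1", "2012-01-01 08:00", "2012-01-01 09:00"),
            make_encounter("P1", "2012-01-02 09:00", "2012-01-02 11:00"),
        ])
        assert len(merge_encounters(enc)) == 2

    def test_six_encounters_two_patients_chain_to_four_admissions(self):
        # gaps P1: {2 h, 30 h, 5 h} -> 2 admissions; P2: {40 h} -> 2 admissions
        t = pd.Timestamp("2012-05-01 00:00")
        enc = pd.DataFrame([
            make_encounter("P1", t, t + 3 * H, codes="I21.0"),
            make_encounter("P1", t + 5 * H, t + 8 * H),           # 2 h after prev end
            make_encounter("P1", t + 38 * H, t + 40 * H),         # 30 h gap
            make_encounter("P1", t + 45 * H, t + 46 * H, codes="I50"),  # 5 h gap
            make_encounter("P2", t, t + 1 * H),
            make_encounter("P2", t + 41 * H, t + 42 * H),         # 40 h gap
        ])
        adm = merge_encounters(enc)
        assert len(adm) == 4
        counts = adm.sort_values(["patient_id", "start"])["n_encounters"].tolist()
        assert counts == [2, 2, 1, 1]
        first = adm.sort_values(["patient_id", "start"]).iloc[0]
        assert first["codes"] == "I21.0"
        assert first["end"] == t + 8 * H  # max end over members

    def test_merge_is_idempotent(self, small_sim):
        _, _, enc, _ = small_sim
        adm = merge_encounters(enc)
        again = merge_encounters(adm.rename(columns={})[
            ["patient_id", "start", "end", "codes", "death_date", "sex", "age_at_start"]])
        assert len(again) == len(adm)
        pd.testing.assert_series_equal(again["start"].reset_index(drop=True),
                                       adm["start"].reset_index(drop=True))

    def test_overlapping_encounters_merge(self):
        enc = pd.DataFrame([
            make_encounter("P1", "2012-01-01 08:00", "2012-01-05 09:00"),
            make_encounter("P1", "2012-01-02 08:00", "2012-01-03 09:00"),  # nested
        ])
        adm = merge_encounters(enc)
        assert len(adm) == 1
        assert adm.loc[0, "end"] == pd.Timestamp("2012-01-05 09:00")

    def test_invalid_interval_rejected(self):
        enc = pd.DataFrame([make_encounter("P1", "2012-01-02 08:00", "2012-01-01 08:00")])
        with pytest.raises(ValueError, match="start > end"):
            merge_encounters(enc)


class TestAttachLabs:
    def test_window_boundaries(self):
        adm = simple_admissions(("P1", T0))
        rec = pd.DataFrame([
            make_record("P1", "A", 1, T0 + 23.9 * H),   # inside
            make_record("P1", "A", 2, T0 + 24.1 * H),   # outside
            make_record("P1", "A", 3, T0 - 1 * H),      # before admission
            make_record("P1", "A", 4, T0 + 24 * H),     # closed boundary
        ])
        out = attach_labs(adm, rec)
        assert sorted(out["value"]) == [1.0, 4.0]

    def test_record_goes_to_earliest_qualifying_admission(self):
        adm = simple_admissions(("P1", T0), ("P1", T0 + 20 * H))
        rec = pd.DataFrame([make_record("P1", "A", 1, T0 + 21 * H)])
        out = attach_labs(adm, rec)
        assert out.loc[0, "admission_id"] == "A0"

    def test_total_attached_plus_dropped_conserved(self, small_sim):
        _, rec, enc, _ = small_sim
        adm = merge_encounters(enc)
        out = attach_labs(adm, rec)
        assert len(out) <= len(rec)
        assert out["admission_id"].notna().all()
        # no record attaches twice: output rows are unique record instances
        assert len(out) == len(out.drop_duplicates(["patient_id", "test_name", "timestamp", "value"]))


class TestSelectMostAbnormal:
    def bounds(self, g):
        return np.full(len(g), 10.0), np.full(len(g), 20.0)

    def test_abnormal_beats_normal(self):
        g = pd.DataFrame([make_record("P1", "A", 15, T0),
                          make_record("P1", "A", 21, T0 + H)])
        assert select_most_abnormal(g, self.bounds)["value"] == 21

    def test_all_normal_returns_last_by_timestamp(self):
        g = pd.DataFrame([make_record("P1", "A", 15, T0 + H),
                          make_record("P1", "A", 16, T0)])
        assert select_most_abnormal(g, self.bounds)["value"] == 15

    def test_deeper_low_beats_shallow_high(self):
        # relative depths: (10-6)/10 = 0.4 below vs (21-20)/10 = 0.1 above
        g = pd.DataFrame([make_record("P1", "A", 6, T0),
                          make_record("P1", "A", 21, T0 + H)])
        assert select_most_abnormal(g, self.bounds)["value"] == 6

    def test_order_invariant_for_distinct_deviations(self):
        rows = [make_record("P1", "A", v, T0 + i * H) for i, v in enumerate([6, 21, 25, 15])]
        g = pd.DataFrame(rows)
        picks = {select_most_abnormal(g.sample(frac=1, random_state=s), self.bounds)["value"]
                 for s in range(5)}
        assert picks == {25.0}


class TestFilters:
    def build(self, n_adm=10, test_in=2):
        adm = simple_admissions(*[(f"P{i}", T0 + i * 100 * H) for i in range(n_adm)])
        recs = []
        for i in range(n_adm):
            recs.append(make_record(f"P{i}", "B", 15, T0 + i * 100 * H + H))
            if i < test_in:
                recs.append(make_record(f"P{i}", "A", 15, T0 + i * 100 * H + 2 * H))
        rec = pd.DataFrame(recs)
        rec["admission_id"] = [f"A{int(r.patient_id[1:])}" for r in rec.itertuples()]
        return rec, adm

    def test_age_rule_removes_minors(self):
        rec, adm = self.build()
        rec.loc[rec["patient_id"] == "P0", "age_at_draw"] = 19
        adm.loc[adm["patient_id"] == "P0", "age_at_start"] = 19
        out_rec, out_adm, _, _, report = apply_cohort_filters(rec, adm, [], min_patients=1)
        assert report.removed_admissions_age == 1
        assert "P0" not in set(out_rec["patient_id"])

    def test_codes_truncated_to_level3(self):
        assert truncate_code("I21.2") == "I21"
        rec, adm = self.build()
        adm.loc[0, "codes"] = "I21.2;Z00.1"
        _, out_adm, _, _, _ = apply_cohort_filters(rec, adm, [], min_patients=1)
        assert out_adm.loc[0, "codes"] == "I21;Z00"

    def test_low_coverage_test_dropped(self):
        rec, adm = self.build(n_adm=10, test_in=1)  # A in 1/10 < 20%
        out_rec, _, _, _, report = apply_cohort_filters(rec, adm, [], min_patients=1)
        assert report.tests_dropped == ["A"]
        assert set(out_rec["test_name"]) == {"B"}
        assert report.removed_records_coverage == 1

    def test_coverage_boundary_is_inclusive(self):
        # 2/10 == 0.2 exactly: the rule keeps tests measured in >= 20%
        rec, adm = self.build(n_adm=10, test_in=2)
        _, _, _, _, report = apply_cohort_filters(rec, adm, [], min_patients=1,
                                                  coverage_frac=0.2)
        assert "A" in report.tests_kept

    def test_outcome_prevalence_rule(self):
        rec, adm = self.build()
        adm.loc[:2, "codes"] = "I21"
        adm.loc[3:, "codes"] = "I50"
        _, _, kept, _, report = apply_cohort_filters(rec, adm, ["I21", "I50"], min_patients=5)
        assert kept == ["I50"]
        assert report.outcomes_dropped == ["I21"]

    def test_survivor_mask_excludes_deaths_within_28_days(self):
        rec, adm = self.build()
        adm.loc[adm["patient_id"] == "P1", "death_date"] = T0 + 100 * H + pd.Timedelta(days=10)
        out_rec, _, _, fit_mask, report = apply_cohort_filters(rec, adm, [], min_patients=1)
        died = out_rec.loc[~fit_mask, "patient_id"].unique()
        assert list(died) == ["P1"]
        assert report.records_excluded_from_fitting == int((~fit_mask).sum()) > 0
        # but the records remain in the ML tables
        assert "P1" in set(out_rec["patient_id"])

    def test_empty_cohort_is_an_error(self):
        rec, adm = self.build()
        rec["age_at_draw"] = 18
        adm["age_at_start"] = 18
        with pytest.raises(EmptyCohortError):
            apply_cohort_filters(rec, adm, [], min_patients=1)

    def test_report_counts_are_consistent(self):
        rec, adm = self.build(n_adm=10, test_in=2)
        out_rec, out_adm, _, _, r = apply_cohort_filters(rec, adm, [], min_patients=1)
        assert r.n_records_in == len(rec)
        assert r.n_records_out == len(out_rec)
        assert r.n_records_in - r.removed_records_age - r.removed_records_coverage == r.n_records_out
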