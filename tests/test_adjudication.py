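"""Exacerbation adjudication rules: candidate extraction, attribution,
merging, follow-up variants, pneumonia, utilization, and adherence."""

import numpy as np
import pandas as pd
import pytest

from copdce.adjudicate import (
    adjudicate_cohort,
    adjudicate_record,
    apply_attribution,
    compute_adherence,
    count_exacerbations,
    detect_pneumonia,
    extract_candidates,
    length_of_stay,
    medication_flags,
    merge_events,
    tally_utilization,
    time_to_first,
)
from copdce.cohort import FollowUpSpec
from copdce.simulate import generate_toy_fixtures

from conftest import make_database, random_micro_stream, stream_to_database
from reference_adjudicator import brute_force_adjudicate

SPEC = FollowUpSpec("fixed_12mo")


def _single_patient_db(medical=None, pharmacy=None):
    med = []
    for j, c in enumerate(medical or []):
        row = dict(claim_id=f"M{j}", patient_id="P1", diagnoses=c["dxs"],
                   place_of_service=c["place"],
                   service_date=c.get("adm", c.get("date")))
        if c["place"] == "inpatient":
            row["admission_date"] = c["adm"]
            row["discharge_date"] = c["disch"]
        med.append(row)
    rx = [dict(claim_id=f"R{j}", patient_id="P1", fill_date=f["date"],
               drug_class=f["class"], days_supply=f.get("days_supply", 7))
          for j, f in enumerate(pharmacy or [])]
    return make_database(
        patients=[dict(patient_id="P1", birth_year=1950, sex="male", region="west")],
        enrollment=[dict(patient_id="P1", start_date=500, end_date=1500,
                         medical_eligible=True, pharmacy_eligible=True)],
        medical=med, pharmacy=rx)


RECORD = {"patient_id": "P1", "index_date": 1000, "index_drug": "BFC"}


class TestExtractCandidates:
    @pytest.mark.parametrize("fill_day,expect", [(1030, 1), (1031, 0)])
    def test_ten_day_fill_window_boundary(self, fill_day, expect):
        db = _single_patient_db(
            medical=[dict(place="office", date=1020, dxs=["491.21"])],
            pharmacy=[dict({"class": "OCS"}, date=fill_day)])
        cands = extract_candidates(db, RECORD, SPEC)
        assert len(cands) == expect
        if expect:
            assert cands.iloc[0]["onset_date"] == 1020
            assert cands.iloc[0]["type"] == "outpatient_rx"

    def test_inpatient_requires_primary_copd(self):
        db = _single_patient_db(medical=[dict(place="inpatient", adm=1010,
                                              disch=1014, dxs=["428.0", "491.21"])])
        assert len(extract_candidates(db, RECORD, SPEC)) == 0

    def test_ed_accepts_any_position(self):
        db = _single_patient_db(medical=[dict(place="ed", date=1010,
                                              dxs=["786.09", "491.21"])])
        cands = extract_candidates(db, RECORD, SPEC)
        assert list(cands["type"]) == ["ed"]

    def test_onset_outside_window_dropped(self):
        db = _single_patient_db(medical=[dict(place="ed", date=990, dxs=["496"]),
                                         dict(place="ed", date=2000, dxs=["496"])])
        assert len(extract_candidates(db, RECORD, SPEC)) == 0


class TestAttribution:
    def test_ed_during_inpatient_stay_dropped(self):
        db = _single_patient_db(
            medical=[dict(place="inpatient", adm=1007, disch=1012, dxs=["491.21"]),
                     dict(place="ed", date=1007, dxs=["496"])])
        cands = apply_attribution(extract_candidates(db, RECORD, SPEC))
        assert list(cands["type"]) == ["inpatient"]

    def test_fill_near_hospitalization_absorbed(self):
        # office visit day 1005, OCS fill day 1012, admission day 1003:
        # |1012 - 1003| = 9 <= 14 so the outpatient candidate is absorbed
        db = _single_patient_db(
            medical=[dict(place="inpatient", adm=1003, disch=1006, dxs=["492.8"]),
                     dict(place="office", date=1005, dxs=["491.21"])],
            pharmacy=[dict({"class": "OCS"}, date=1012)])
        cands = apply_attribution(extract_candidates(db, RECORD, SPEC))
        assert list(cands["type"]) == ["inpatient"]

    def test_multiple_fills_one_event_per_visit(self):
        db = _single_patient_db(
            medical=[dict(place="office", date=1005, dxs=["491.21"])],
            pharmacy=[dict({"class": "OCS"}, date=1006),
                      dict({"class": "ANTIBIOTIC"}, date=1009)])
        cands = apply_attribution(extract_candidates(db, RECORD, SPEC))
        assert len(cands) == 1 and cands.iloc[0]["onset_date"] == 1005


class TestMerge:
    def _cands(self, onsets, types=None):
        types = types or ["outpatient_rx"] * len(onsets)
        return pd.DataFrame({"patient_id": "P1", "onset_date": onsets,
                             "type": types})

    def test_anchored_merge_three_candidates(self):
        events = merge_events(self._cands([0, 10, 20]))
        assert list(events["onset_date"]) == [0, 20]

    def test_boundary_fourteen_days_merges(self):
        events = merge_events(self._cands([0, 14]))
        assert list(events["onset_date"]) == [0]
        events = merge_events(self._cands([0, 15]))
        assert list(events["onset_date"]) == [0, 15]

    def test_single_candidate_identity(self):
        events = merge_events(self._cands([42], ["inpatient"]))
        assert len(events) == 1
        assert events.iloc[0]["onset_date"] == 42
        assert bool(events.iloc[0]["severe"])

    def test_merged_type_is_most_severe(self):
        events = merge_events(self._cands([0, 5, 9],
                                          ["outpatient_rx", "inpatient", "ed"]))
        assert list(events["type"]) == ["inpatient"]
        assert list(events["onset_date"]) == [0]

    def test_chained_variant_extends_cluster(self):
        cands = self._cands([0, 12, 24])
        assert len(merge_events(cands, chained=False)) == 2
        assert len(merge_events(cands, chained=True)) == 1


class TestFollowUpVariants:
    def _db(self):
        return _single_patient_db(
            medical=[dict(place="office", date=1030, dxs=["491.21"]),
                     dict(place="inpatient", adm=1100, disch=1104, dxs=["496"]),
                     dict(place="inpatient", adm=1300, disch=1302, dxs=["491.21"])],
            pharmacy=[dict({"class": "OCS"}, date=1030),
                      dict({"class": "OTHER_ICS_LABA"}, date=1090, days_supply=30)])

    def test_fixed_followup_counts_and_time_to_first(self):
        db = self._db()
        count, py = count_exacerbations(db, RECORD, SPEC)
        assert (count, py) == (3, 1.0)
        days, flag = time_to_first(db, RECORD, SPEC)
        assert (days, flag) == (30, True)

    def test_censor_at_switch(self):
        db = self._db()
        spec = FollowUpSpec("censor_at_switch")
        count, py = count_exacerbations(db, RECORD, spec)
        assert count == 1
        assert py == pytest.approx(90 / 365)

    def test_severe_only_subset(self):
        db = self._db()
        count, py = count_exacerbations(db, RECORD, FollowUpSpec("severe_only"))
        assert (count, py) == (2, 1.0)

    def test_all_available_uses_enrollment_end(self):
        db = self._db()
        spec = FollowUpSpec("all_available", study_end=5000)
        count, py = count_exacerbations(db, RECORD, spec)
        assert count == 3
        assert py == pytest.approx((1500 - 1000 + 1) / 365)

    def test_monotonicity_of_variants(self):
        db = self._db()
        full, _ = count_exacerbations(db, RECORD, SPEC)
        censored, _ = count_exacerbations(db, RECORD, FollowUpSpec("censor_at_switch"))
        severe, _ = count_exacerbations(db, RECORD, FollowUpSpec("severe_only"))
        assert censored <= full and severe <= full


class TestPneumoniaUtilizationAdherence:
    def test_pneumonia_any_position_and_place(self):
        db = _single_patient_db(medical=[dict(place="ed", date=1100,
                                              dxs=["786.09", "482.1"])])
        res = detect_pneumonia(db, RECORD)
        assert res["any"] and res["ed"] and not res["inpatient"]
        assert res["first_date"] == 1100

    def test_pneumonia_pre_index_only_is_negative(self):
        db = _single_patient_db(medical=[dict(place="office", date=900, dxs=["486"])])
        res = detect_pneumonia(db, RECORD)
        assert not res["any"] and res["first_date"] is None

    @pytest.mark.parametrize("adm,disch,expected", [(1010, 1010, 1), (1010, 1017, 7)])
    def test_length_of_stay_same_day_counts_one(self, adm, disch, expected):
        assert length_of_stay(adm, disch) == expected

    def test_utilization_scope(self):
        db = _single_patient_db(
            medical=[dict(place="inpatient", adm=1010, disch=1014,
                          dxs=["428.0", "491.21"])])
        copd = tally_utilization(db, RECORD, "copd_related")
        allc = tally_utilization(db, RECORD, "all_cause")
        assert copd["inpatient_stays"] == 0
        assert allc["inpatient_stays"] == 1 and allc["inpatient_los"] == 4

    def test_adherence_formula_and_category(self):
        fills = [dict({"class": "BFC"}, date=1000 + 30 * j, days_supply=30)
                 for j in range(4)]
        db = _single_patient_db(pharmacy=fills)
        adh = compute_adherence(db, RECORD)
        assert adh.n_index_fills == 4
        assert adh.fill_category == "4+"
        assert adh.pdc == pytest.approx(120 / 365)

    def test_pdc_caps_at_one(self):
        fills = [dict({"class": "BFC"}, date=1000 + 28 * j, days_supply=34)
                 for j in range(12)]
        db = _single_patient_db(pharmacy=fills)
        assert compute_adherence(db, RECORD).pdc == 1.0

    def test_medication_flags_window(self):
        db = _single_patient_db(pharmacy=[dict({"class": "LAMA"}, date=1100,
                                               days_supply=30),
                                          dict({"class": "SABA"}, date=900,
                                               days_supply=30)])
        flags = medication_flags(db, RECORD)
        assert flags["LAMA"] and not flags["SABA"]


class TestOracleAgreement:
    def test_driver_and_single_record_agree_with_bruteforce(self):
        rng = np.random.default_rng(20240917)
        streams = [random_micro_stream(rng) for _ in range(300)]
        db, cohort = stream_to_database(streams)
        events, outcomes = adjudicate_cohort(db, cohort, SPEC)
        by_pid = dict(iter(events.groupby("patient_id")))
        for i, (med, rx) in enumerate(streams):
            pid = f"S{i:05d}"
            expected = brute_force_adjudicate(med, rx, 1000, 1364)
            got = by_pid.get(pid)
            got_list = ([] if got is None else
                        [(int(r.onset_date), {"inpatient": 2, "ed": 1,
                                              "outpatient_rx": 0}[r.type])
                         for r in got.itertuples()])
            assert got_list == expected, f"driver mismatch on stream {i}"
            if i < 60:  # single-record API spot check
                rec = {"patient_id": pid, "index_date": 1000, "index_drug": "BFC"}
                single = adjudicate_record(db, rec, SPEC)
                assert [(int(r.onset_date),
                         {"inpatient": 2, "ed": 1, "outpatient_rx": 0}[r.type])
                        for r in single.itertuples()] == expected

    def test_retained_events_pairwise_separated(self):
        rng = np.random.default_rng(5)
        db, cohort = stream_to_database([random_micro_stream(rng) for _ in range(200)])
        events, _ = adjudicate_cohort(db, cohort, SPEC)
        for _, grp in events.groupby("patient_id"):
            gaps = np.diff(np.sort(grp["onset_date"].to_numpy()))
            assert (gaps > 14).all()

    def test_adding_claims_never_decreases_candidates(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            med, rx = random_micro_stream(rng)
            db1, _ = stream_to_database([(med, rx)])
            extra = dict(place="office", date=1040, dxs=["491.21"])
            db2, _ = stream_to_database([(med + [extra],
                                          rx + [dict({"class": "OCS"}, date=1041)])])
            rec = {"patient_id": "S00000", "index_date": 1000, "index_drug": "BFC"}
            n1 = len(extract_candidates(db1, rec, SPEC))
            n2 = len(extract_candidates(db2, rec, SPEC))
            assert n2 >= n1


class TestToyFixtures:
    @pytest.mark.parametrize("name", ["empty", "ed_collapse", "fill_absorb",
                                      "multi_fill_single_event", "merge_14d",
                                      "switch_censor", "severe_only"])
    def test_fixture_matches_hand_enumeration(self, name):
        fx = generate_toy_fixtures()[name]
        rec = {"patient_id": "P1", "index_date": fx["index_date"],
               "index_drug": fx["index_drug"]}
        events = adjudicate_record(fx["db"], rec, SPEC)
        exp = fx["expected"]
        assert len(events) == exp["n_events"]
        assert list(events["onset_date"]) == exp["onsets"]
        assert list(events["type"]) == exp["types"]
        if "severe_count" in exp:
            count, _ = count_exacerbations(fx["db"], rec, FollowUpSpec("severe_only"),
                                           events=events)
            assert count == exp["severe_count"]
        if "censored_count" in exp:
            spec = FollowUpSpec("censor_at_switch")
            count, py = count_exacerbations(fx["db"], rec, spec)
            assert count == exp["censored_count"]
            assert py == pytest.approx(exp["censored_person_years"])
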