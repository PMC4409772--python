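"""Index-date identification, inclusion/exclusion criteria, attrition
accounting, and pre-index covariates."""

import numpy as np
import pandas as pd
import pytest

from copdce.cohort import (
    CohortParams,
    FollowUpSpec,
    apply_criteria,
    build_cohort,
    find_index,
)
from copdce.simulate import SimulationConfig, generate

from conftest import make_database


def _base_patient(pid="P1", birth_year=1948, index=1000):
    """Scaffolding that satisfies every criterion: enrollment around the
    index day and a two-office-visit diagnosis pathway."""
    return dict(
        patients=[dict(patient_id=pid, birth_year=birth_year, sex="female",
                       region="south")],
        enrollment=[dict(patient_id=pid, start_date=index - 400,
                         end_date=index + 400, medical_eligible=True,
                         pharmacy_eligible=True)],
        medical=[dict(claim_id=f"{pid}V1", patient_id=pid, service_date=index - 300,
                      place_of_service="office", diagnoses=["491.21"]),
                 dict(claim_id=f"{pid}V2", patient_id=pid, service_date=index - 200,
                      place_of_service="office", diagnoses=["496"])],
        pharmacy=[dict(claim_id=f"{pid}F1", patient_id=pid, fill_date=index,
                       drug_class="BFC", days_supply=30)])


def _merge(*parts):
    out = {k: [] for k in ("patients", "enrollment", "medical", "pharmacy")}
    for p in parts:
        for k in out:
            out[k].extend(p.get(k, []))
    return out


class TestFindIndex:
    def test_earliest_fill_wins(self):
        db = make_database(
            patients=[dict(patient_id="P1", birth_year=1950, sex="male",
                           region="west")],
            pharmacy=[dict(claim_id="F1", patient_id="P1", fill_date=100,
                           drug_class="FSC", days_supply=30),
                      dict(claim_id="F2", patient_id="P1", fill_date=200,
                           drug_class="BFC", days_supply=30)])
        out = find_index(db, (0, 1000))
        assert out.iloc[0]["index_date"] == 100
        assert out.iloc[0]["index_drug"] == "FSC"
        assert not out.iloc[0]["dual_initiator"]

    def test_same_day_dual_initiation_flagged(self):
        db = make_database(
            patients=[dict(patient_id="P1", birth_year=1950, sex="male",
                           region="west")],
            pharmacy=[dict(claim_id="F1", patient_id="P1", fill_date=50,
                           drug_class="BFC", days_supply=30),
                      dict(claim_id="F2", patient_id="P1", fill_date=50,
                           drug_class="FSC", days_supply=30)])
        assert bool(find_index(db, (0, 1000)).iloc[0]["dual_initiator"])

    def test_fill_outside_window_no_candidate(self):
        db = make_database(
            patients=[dict(patient_id="P1", birth_year=1950, sex="male",
                           region="west")],
            pharmacy=[dict(claim_id="F1", patient_id="P1", fill_date=1100,
                           drug_class="BFC", days_supply=30)])
        assert len(find_index(db, (0, 1000))) == 0


class TestCriteria:
    def _run(self, parts, **params):
        db = make_database(**parts)
        candidates = find_index(db, (0, 2000))
        return apply_criteria(db, candidates, params=CohortParams(**params))

    def test_fully_eligible_patient_included(self):
        res = self._run(_base_patient())
        assert list(res.cohort["patient_id"]) == ["P1"]
        assert res.audit.iloc[0]["eligible"]

    def test_single_office_claim_fails_diagnosis_criterion(self):
        parts = _base_patient()
        parts["medical"] = parts["medical"][:1]
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "diagnosis"

    def test_two_claims_same_date_fail_distinct_dates_rule(self):
        parts = _base_patient()
        parts["medical"][1]["service_date"] = parts["medical"][0]["service_date"]
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "diagnosis"
        res2 = self._run(parts, other_claims_distinct_dates=False)
        assert res2.audit.iloc[0]["eligible"]

    def test_inclusion_via_inpatient_or_ed_pathway(self):
        for place in ("inpatient", "ed"):
            parts = _base_patient()
            parts["medical"] = parts["medical"][:1]
            claim = dict(claim_id="P1X", patient_id="P1", service_date=800,
                         place_of_service=place, diagnoses=["491.21"])
            if place == "inpatient":
                claim.update(admission_date=800, discharge_date=803)
            parts["medical"].append(claim)
            assert self._run(parts).audit.iloc[0]["eligible"], place

    def test_ocs_180_day_boundary(self):
        parts = _base_patient()
        parts["pharmacy"] += [
            dict(claim_id="O1", patient_id="P1", fill_date=800, drug_class="OCS",
                 days_supply=90),
            dict(claim_id="O2", patient_id="P1", fill_date=900, drug_class="OCS",
                 days_supply=90)]
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "ocs_180"  # 180 >= 180
        parts["pharmacy"][-1]["days_supply"] = 89
        assert self._run(parts).audit.iloc[0]["eligible"]

    def test_prior_combination_fill_fails_new_user_rule(self):
        parts = _base_patient()
        parts["pharmacy"].append(dict(claim_id="C1", patient_id="P1", fill_date=700,
                                      drug_class="OTHER_ICS_LABA", days_supply=30))
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "prior_ics_laba"

    def test_age_under_40_excluded(self):
        parts = _base_patient(birth_year=1975)  # age 33 at day 1000
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "age_lt_40"

    def test_enrollment_gap_excluded(self):
        parts = _base_patient()
        parts["enrollment"] = [
            dict(patient_id="P1", start_date=600, end_date=900,
                 medical_eligible=True, pharmacy_eligible=True),
            dict(patient_id="P1", start_date=950, end_date=1400,
                 medical_eligible=True, pharmacy_eligible=True)]
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "enrollment"
        # an allowable-gap parameter bridges it
        res2 = self._run(parts, enrollment_gap_days=60)
        assert res2.audit.iloc[0]["eligible"]

    def test_cancer_diagnosis_excluded(self):
        parts = _base_patient()
        parts["medical"].append(dict(claim_id="K1", patient_id="P1",
                                     service_date=850, place_of_service="office",
                                     diagnoses=["162.9"]))
        res = self._run(parts)
        assert res.audit.iloc[0]["exclusion_reason"] == "cancer"

    def test_attrition_counts_sum(self):
        db, _ = generate(SimulationConfig(n_patients=400, seed=9, decoy_share=0.25))
        res = build_cohort(db, (400, 1130))
        att = res.attrition
        n0 = att.iloc[0]["n_remaining"]
        assert n0 - att.iloc[1:]["n_removed"].sum() == len(res.cohort)
        assert att.iloc[-1]["n_remaining"] == len(res.cohort)


class TestCovariates:
    def test_index_day_fill_not_counted_as_prior(self):
        parts = _base_patient()
        parts["pharmacy"] += [
            dict(claim_id=f"O{j}", patient_id="P1", fill_date=day,
                 drug_class="OCS", days_supply=7)
            for j, day in enumerate([700, 800, 900, 1000])]
        db = make_database(**parts)
        res = apply_criteria(db, find_index(db, (0, 2000)))
        assert res.cohort.iloc[0]["prior_ocs_fills"] == 3

    def test_long_stay_flag(self):
        parts = _base_patient()
        parts["medical"].append(dict(claim_id="H1", patient_id="P1",
                                     service_date=800, place_of_service="inpatient",
                                     admission_date=800, discharge_date=806,
                                     diagnoses=["428.0"]))
        db = make_database(**parts)
        res = apply_criteria(db, find_index(db, (0, 2000)))
        assert res.cohort.iloc[0]["long_stay"] == 1  # LOS 6 > 5

    def test_no_pre_index_claims_all_zero(self):
        parts = _base_patient()
        db = make_database(**parts)
        res = apply_criteria(db, find_index(db, (0, 2000)))
        row = res.cohort.iloc[0]
        for c in ("prior_ocs_fills", "prior_copd_inpatient", "prior_copd_ed",
                  "pre_exacerbations", "prior_lama_fills"):
            assert row[c] == 0, c

    def test_covariates_ignore_post_index_information(self):
        """Shifting every post-index claim must leave covariates unchanged."""
        db, _ = generate(SimulationConfig(n_patients=150, seed=21, decoy_share=0.0))
        res1 = build_cohort(db, (400, 1130))
        idx = res1.cohort.set_index("patient_id")["index_date"]
        med = db.medical.copy()
        rx = db.pharmacy.copy()
        imap = idx.reindex(med["patient_id"])
        post = (med["service_date"].to_numpy() >= imap.to_numpy())
        post &= ~np.isnan(imap.to_numpy())
        med.loc[post, "service_date"] += 37
        inpt = post & med["place_of_service"].eq("inpatient").to_numpy()
        med.loc[inpt, "admission_date"] += 37
        med.loc[inpt, "discharge_date"] += 37
        imap_rx = idx.reindex(rx["patient_id"])
        post_rx = (rx["fill_date"].to_numpy() > imap_rx.to_numpy())
        post_rx &= ~np.isnan(imap_rx.to_numpy())
        rx.loc[post_rx, "fill_date"] += 37
        import dataclasses as dc
        db2 = dc.replace(db, medical=med, pharmacy=rx)
        res2 = build_cohort(db2, (400, 1130))
        cov_cols = [c for c in res1.cohort.columns]
        pd.testing.assert_frame_equal(
            res1.cohort[cov_cols].reset_index(drop=True),
            res2.cohort[cov_cols].reset_index(drop=True))


class TestGroundTruthRecovery:
    def test_exclusion_reasons_recovered_exactly(self):
        db, truth = generate(SimulationConfig(n_patients=600, seed=13,
                                              decoy_share=0.3))
        res = build_cohort(db, (400, 1130))
        audit = res.audit.set_index("patient_id")
        tp = truth.patients.set_index("patient_id").loc[audit.index]
        assert audit["eligible"].equals(tp["eligible"])
        decoys = tp[~tp["eligible"]]
        assert audit.loc[decoys.index, "exclusion_reason"].equals(
            decoys["exclusion_reason"])
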