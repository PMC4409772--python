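"""New-user cohort construction: index dates, inclusion/exclusion criteria,
attrition accounting, and pre-index covariate extraction.

The index date is a patient's first fill of either study combination (BFC
or FSC) inside the intake window.  Inclusion requires: no ICS/LABA
combination fill in the prior year (new-user design), age >= 40 at index,
continuous medical+pharmacy enrollment over [index-365, index+365], and a
pre-index COPD diagnosis pathway (>=1 inpatient stay with primary COPD, or
>=1 ED visit with COPD in any position, or >=2 other medical claims with
COPD in any position).  Exclusions: any pre-index cancer diagnosis, >=180
total days of pre-index OCS supply, and same-day initiation of both study
drugs.  The pre-index window is [index-365, index-1]; the index day itself
belongs to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from copdce.adjudicate import _adjudicate_arrays, length_of_stay
from copdce.data_model import (
    COMBO_CLASSES,
    ClaimsDatabase,
    CodeSet,
    default_codeset,
    medical_condition_mask,
)


@dataclass
class FollowUpSpec:
    """Follow-up window rule for outcome ascertainment."""

    variant: str = "fixed_12mo"  # fixed_12mo | censor_at_switch | all_available | severe_only
    study_end: int | None = None  # day index; caps all_available follow-up

    def __post_init__(self):
        allowed = ("fixed_12mo", "censor_at_switch", "all_available", "severe_only")
        if self.variant not in allowed:
            raise ValueError(f"variant must be one of {allowed}, got {self.variant!r}")


@dataclass
class CohortParams:
    pre_days: int = 365
    post_days: int = 365
    enrollment_gap_days: int = 0     # allowable gap when merging spans; 0 = strictly continuous
    min_other_claims: int = 2        # "at least two other medical claims"
    other_claims_distinct_dates: bool = True
    ocs_threshold_days: int = 180
    epoch_year: int = 2006           # maps day index 0 to a calendar year for age


#: exclusion steps in the order reported in the attrition table
CRITERIA = [
    ("prior_ics_laba", "ICS/LABA combination fill in prior year"),
    ("age_lt_40", "younger than 40 at index"),
    ("enrollment", "lacking continuous enrollment +/- 12 months"),
    ("diagnosis", "COPD diagnosis criteria not met"),
    ("cancer", "cancer diagnosis pre-index"),
    ("ocs_180", ">=180 days of pre-index OCS supply"),
    ("dual_initiation", "initiated both study drugs on the same date"),
]

#: covariates every cohort carries; the pipeline validates pre-specified
#: matching variables against this dictionary
COVARIATE_DICTIONARY = [
    "age", "female", "prior_asthma",
    "prior_copd_inpatient", "prior_copd_ed",
    "prior_ocs_fills", "prior_antibiotic_fills", "prior_saba_sama_fills",
    "prior_laba_fills", "prior_lama_fills", "prior_ics_fills",
    "pre_exacerbations", "pre_exac_any", "pre_exac_inpatient",
    "pre_exac_ed", "pre_exac_outpatient",
    "prior_pneumonia", "hypertension", "diabetes", "pvd", "cad",
    "depression_anxiety", "chf", "ltra_category", "long_stay",
    "region", "specialty", "index_month",
]


@dataclass
class CohortResult:
    cohort: pd.DataFrame      # eligible patients with covariates
    attrition: pd.DataFrame   # per-criterion counts removed, Figure-1 style
    audit: pd.DataFrame       # every candidate with per-criterion pass flags


def find_index(db: ClaimsDatabase, intake_window: tuple[int, int]) -> pd.DataFrame:
    """Per-patient candidate (index_date, index_drug) = earliest BFC or FSC
    fill inside the intake window; patients whose earliest BFC and FSC fills
    share that date are flagged dual initiators."""
    lo, hi = intake_window
    ph = db.pharmacy
    f = ph[ph["drug_class"].isin(("BFC", "FSC"))
           & (ph["fill_date"] >= lo) & (ph["fill_date"] <= hi)]
    if not len(f):
        return pd.DataFrame(columns=["patient_id", "index_date", "index_drug",
                                     "dual_initiator"])
    first = (f.groupby(["patient_id", "drug_class"])["fill_date"].min()
             .reset_index())
    idx = first.groupby("patient_id")["fill_date"].min().rename("index_date")
    first = first.merge(idx, on="patient_id")
    at_index = first[first["fill_date"] == first["index_date"]]
    n_classes = at_index.groupby("patient_id")["drug_class"].nunique()
    drug = at_index.groupby("patient_id")["drug_class"].min().rename("index_drug")
    out = pd.concat([idx, drug, (n_classes > 1).rename("dual_initiator")], axis=1)
    return out.reset_index().sort_values("patient_id").reset_index(drop=True)


def _join_window(df: pd.DataFrame, date_col: str, index_dates: pd.Series,
                 lo: int, hi: int) -> pd.DataFrame:
    """Rows of df whose date falls in [index+lo, index+hi] for that patient."""
    sub = df.merge(index_dates.rename("index_date"), left_on="patient_id",
                   right_index=True, how="inner")
    sub.index.name = None
    rel = sub[date_col] - sub["index_date"]
    return sub[(rel >= lo) & (rel <= hi)]


def _count_by_patient(df: pd.DataFrame, index: pd.Index) -> pd.Series:
    if df.index.name is not None:
        df = df.reset_index(drop=True)
    return df.groupby("patient_id").size().reindex(index, fill_value=0)


def apply_criteria(db: ClaimsDatabase, candidates: pd.DataFrame,
                   codeset: CodeSet | None = None,
                   params: CohortParams | None = None) -> CohortResult:
    """Apply every inclusion/exclusion rule.  Eligibility is conjunctive
    (order independent); the attrition table removes sequentially in
    CRITERIA order for reproducible reporting."""
    codeset = codeset or default_codeset()
    params = params or CohortParams()
    cand = candidates.set_index("patient_id")
    idx_dates = cand["index_date"]
    pre_lo, pre_hi = -params.pre_days, -1

    med = db.medical
    ph = db.pharmacy

    # (a) naive to ICS/LABA combinations in the prior year
    combo = _join_window(ph[ph["drug_class"].isin(COMBO_CLASSES)], "fill_date",
                         idx_dates, pre_lo, pre_hi)
    fail_a = _count_by_patient(combo, cand.index) > 0

    # (b) age >= 40 at index
    byear = db.patients.set_index("patient_id")["birth_year"].reindex(cand.index)
    age = params.epoch_year + idx_dates // 365 - byear
    fail_b = age < 40

    # (c) continuous enrollment over [index - pre, index + post]
    fail_c = ~_enrollment_ok(db, idx_dates, params)

    # (d) diagnosis pathway
    copd_primary = medical_condition_mask(med, "COPD", "primary", codeset)
    copd_any = medical_condition_mask(med, "COPD", "any", codeset)
    inpt = med[med["place_of_service"].eq("inpatient") & copd_primary]
    ed = med[med["place_of_service"].eq("ed") & copd_any]
    other = med[~med["place_of_service"].isin(("inpatient", "ed")) & copd_any]
    n_inpt = _count_by_patient(_join_window(inpt, "service_date", idx_dates, pre_lo, pre_hi),
                               cand.index)
    n_ed = _count_by_patient(_join_window(ed, "service_date", idx_dates, pre_lo, pre_hi),
                             cand.index)
    other_w = _join_window(other, "service_date", idx_dates, pre_lo, pre_hi)
    if params.other_claims_distinct_dates:
        n_other = (other_w.drop_duplicates(["patient_id", "service_date"])
                   .groupby("patient_id").size().reindex(cand.index, fill_value=0))
    else:
        n_other = _count_by_patient(other_w, cand.index)
    fail_d = ~((n_inpt >= 1) | (n_ed >= 1) | (n_other >= params.min_other_claims))

    # (e) cancer diagnosis pre-index
    cancer_mask = medical_condition_mask(med, "CANCER", "any", codeset)
    cancer = _join_window(med[cancer_mask], "service_date", idx_dates, pre_lo, pre_hi)
    fail_e = _count_by_patient(cancer, cand.index) > 0

    # (f) >= 180 days of OCS supply pre-index
    ocs = _join_window(ph[ph["drug_class"].eq("OCS")], "fill_date",
                       idx_dates, pre_lo, pre_hi)
    ocs_days = ocs.groupby("patient_id")["days_supply"].sum().reindex(cand.index, fill_value=0)
    fail_f = ocs_days >= params.ocs_threshold_days

    # (g) dual initiators
    fail_g = cand["dual_initiator"].astype(bool)

    fails = pd.DataFrame({
        "prior_ics_laba": fail_a, "age_lt_40": fail_b, "enrollment": fail_c,
        "diagnosis": fail_d, "cancer": fail_e, "ocs_180": fail_f,
        "dual_initiation": fail_g,
    })
    eligible = ~fails.any(axis=1)

    audit = cand.copy()
    for key, _ in CRITERIA:
        audit[f"pass_{key}"] = ~fails[key]
    audit["eligible"] = eligible
    audit["exclusion_reason"] = ""
    remaining = pd.Series(True, index=cand.index)
    rows = [("candidates", int(len(cand)), int(len(cand)))]
    for key, label in CRITERIA:
        removed = remaining & fails[key]
        audit.loc[removed & audit["exclusion_reason"].eq(""), "exclusion_reason"] = key
        remaining &= ~fails[key]
        rows.append((key, int(removed.sum()), int(remaining.sum())))
    attrition = pd.DataFrame(rows, columns=["criterion", "n_removed", "n_remaining"])

    cohort = cand[eligible].copy()
    cohort = cohort.reset_index()
    covs = extract_covariates(db, cohort, codeset, params)
    cohort = cohort.merge(covs, on="patient_id")
    return CohortResult(cohort=cohort, attrition=attrition,
                        audit=audit.reset_index())


def _enrollment_ok(db: ClaimsDatabase, idx_dates: pd.Series, params: CohortParams
                   ) -> pd.Series:
    """Day-level coverage of [index-pre, index+post] by medical+pharmacy
    eligible spans, after merging spans separated by at most the allowable
    gap."""
    en = db.enrollment
    en = en[en["medical_eligible"] & en["pharmacy_eligible"]]
    en = en.sort_values(["patient_id", "start_date"])
    starts = en["start_date"].to_numpy()
    ends = en["end_date"].to_numpy()
    spans = {pid: idx for pid, idx in en.groupby("patient_id", sort=False).indices.items()}
    ok = {}
    gap = params.enrollment_gap_days
    for pid, index in idx_dates.items():
        lo, hi = index - params.pre_days, index + params.post_days
        covered = False
        rows = spans.get(pid)
        if rows is not None:
            cur_s, cur_e = None, None
            for i in rows:
                s, e = starts[i], ends[i]
                if cur_e is not None and s <= cur_e + 1 + gap:
                    cur_e = max(cur_e, e)
                else:
                    if cur_s is not None and cur_s <= lo and cur_e >= hi:
                        covered = True
                    cur_s, cur_e = s, e
            if cur_s is not None and cur_s <= lo and cur_e >= hi:
                covered = True
        ok[pid] = covered
    return pd.Series(ok).reindex(idx_dates.index)


def extract_covariates(db: ClaimsDatabase, cohort: pd.DataFrame,
                       codeset: CodeSet | None = None,
                       params: CohortParams | None = None) -> pd.DataFrame:
    """Pre-index covariates over [index-365, index-1] for included records.

    Counts never use the index day or anything after it; fill categories are
    coded 0/1/2+; long_stay flags any all-cause inpatient stay longer than 5
    days (discharge - admission > 5)."""
    codeset = codeset or default_codeset()
    params = params or CohortParams()
    idx_dates = cohort.set_index("patient_id")["index_date"]
    pidx = idx_dates.index
    pre_lo, pre_hi = -params.pre_days, -1
    med, ph = db.medical, db.pharmacy

    out = pd.DataFrame(index=pidx)
    pat = db.patients.set_index("patient_id").reindex(pidx)
    out["female"] = pat["sex"].eq("female").astype(int)
    out["region"] = pat["region"]
    out["age"] = (params.epoch_year + idx_dates // 365 - pat["birth_year"]).astype(int)

    copd_primary = medical_condition_mask(med, "COPD", "primary", codeset)
    copd_any = medical_condition_mask(med, "COPD", "any", codeset)
    inpt_all = med["place_of_service"].eq("inpatient")
    out["prior_copd_inpatient"] = _count_by_patient(
        _join_window(med[inpt_all & copd_primary], "service_date", idx_dates, pre_lo, pre_hi), pidx)
    out["prior_copd_ed"] = _count_by_patient(
        _join_window(med[med["place_of_service"].eq("ed") & copd_any], "service_date",
                     idx_dates, pre_lo, pre_hi), pidx)

    fill_counts = {
        "prior_ocs_fills": ("OCS",), "prior_antibiotic_fills": ("ANTIBIOTIC",),
        "prior_saba_sama_fills": ("SABA", "SAMA", "SABA_SAMA"),
        "prior_laba_fills": ("LABA",), "prior_lama_fills": ("LAMA",),
        "prior_ics_fills": ("ICS",),
    }
    for name, classes in fill_counts.items():
        sub = _join_window(ph[ph["drug_class"].isin(classes)], "fill_date",
                           idx_dates, pre_lo, pre_hi)
        out[name] = _count_by_patient(sub, pidx)
    ltra = _count_by_patient(
        _join_window(ph[ph["drug_class"].eq("LTRA")], "fill_date", idx_dates,
                     pre_lo, pre_hi), pidx)
    out["ltra_category"] = np.minimum(ltra, 2).astype(str)
    out.loc[ltra >= 2, "ltra_category"] = "2+"

    for name, cond in (("prior_asthma", "ASTHMA"), ("prior_pneumonia", "PNEUMONIA"),
                       ("hypertension", "HYPERTENSION"), ("diabetes", "DIABETES"),
                       ("pvd", "PVD"), ("cad", "CAD"),
                       ("depression_anxiety", "DEPRESSION_ANXIETY"), ("chf", "CHF")):
        m = medical_condition_mask(med, cond, "any", codeset)
        sub = _join_window(med[m], "service_date", idx_dates, pre_lo, pre_hi)
        out[name] = (_count_by_patient(sub, pidx) > 0).astype(int)

    stays = _join_window(med[inpt_all], "service_date", idx_dates, pre_lo, pre_hi)
    if len(stays):
        los = length_of_stay(stays["admission_date"].astype(int),
                             stays["discharge_date"].astype(int))
        long = stays.loc[np.asarray(los) > 5].groupby("patient_id").size()
        out["long_stay"] = (long.reindex(pidx, fill_value=0) > 0).astype(int)
    else:
        out["long_stay"] = 0

    out = _pre_index_exacerbations(db, idx_dates, codeset, params, out)

    # prescriber specialty: the most recent pre-index medical claim's
    # specialty stands in for the index prescriber
    pre_med = _join_window(med, "service_date", idx_dates, pre_lo, pre_hi)
    last = (pre_med.sort_values(["patient_id", "service_date", "claim_id"])
            .groupby("patient_id")["provider_specialty"].last())
    out["specialty"] = last.reindex(pidx).fillna("other")
    out["index_month"] = np.minimum(idx_dates % 365 // 30, 11).astype(int)
    return out.reset_index().rename(columns={"index": "patient_id"})


def _pre_index_exacerbations(db: ClaimsDatabase, idx_dates: pd.Series,
                             codeset: CodeSet, params: CohortParams,
                             out: pd.DataFrame) -> pd.DataFrame:
    """Adjudicate exacerbations over the pre-index window with the same
    candidate/attribution/merge rules used post-index."""
    med, ph = db.medical, db.pharmacy
    copd_primary = medical_condition_mask(med, "COPD", "primary", codeset)
    copd_any = medical_condition_mask(med, "COPD", "any", codeset)
    inpt = med[med["place_of_service"].eq("inpatient") & copd_primary]
    ed = med[med["place_of_service"].eq("ed") & copd_any]
    visit = med[med["place_of_service"].isin(("office", "outpatient")) & copd_any]
    fill = ph[ph["drug_class"].isin(("OCS", "ANTIBIOTIC"))]

    def _groups(df, cols):
        d = {}
        for pid, idx in df.groupby("patient_id", sort=False).indices.items():
            d[pid] = tuple(df[c].to_numpy()[idx] for c in cols)
        return d

    g_inpt = _groups(inpt, ["admission_date", "discharge_date"])
    g_ed = _groups(ed, ["service_date"])
    g_visit = _groups(visit, ["service_date"])
    g_fill = _groups(fill, ["fill_date"])
    empty = np.empty(0, dtype=np.int64)

    total, t_in, t_ed, t_out = {}, {}, {}, {}
    for pid, index in idx_dates.items():
        lo, hi = index - params.pre_days, index - 1
        ia, idsch = g_inpt.get(pid, (empty, empty))
        ia = np.asarray(ia, dtype=np.int64)
        idsch = np.asarray(idsch, dtype=np.int64)
        keep = (ia >= lo) & (ia <= hi)
        (ed_d,) = g_ed.get(pid, (empty,))
        ed_d = np.asarray(ed_d, dtype=np.int64)
        (v_d,) = g_visit.get(pid, (empty,))
        v_d = np.asarray(v_d, dtype=np.int64)
        (f_d,) = g_fill.get(pid, (empty,))
        f_d = np.asarray(f_d, dtype=np.int64)
        events = _adjudicate_arrays(ia[keep], idsch[keep],
                                    ed_d[(ed_d >= lo) & (ed_d <= hi)],
                                    v_d[(v_d >= lo) & (v_d <= hi)],
                                    f_d[f_d <= hi], chained=False)
        total[pid] = len(events)
        t_in[pid] = sum(1 for _, s, _ in events if s == 2)
        t_ed[pid] = sum(1 for _, s, _ in events if s == 1)
        t_out[pid] = sum(1 for _, s, _ in events if s == 0)
    out["pre_exacerbations"] = pd.Series(total).reindex(out.index, fill_value=0)
    out["pre_exac_any"] = (out["pre_exacerbations"] > 0).astype(int)
    out["pre_exac_inpatient"] = (pd.Series(t_in).reindex(out.index, fill_value=0) > 0).astype(int)
    out["pre_exac_ed"] = (pd.Series(t_ed).reindex(out.index, fill_value=0) > 0).astype(int)
    out["pre_exac_outpatient"] = (pd.Series(t_out).reindex(out.index, fill_value=0) > 0).astype(int)
    return out


def build_cohort(db: ClaimsDatabase, intake_window: tuple[int, int],
                 codeset: CodeSet | None = None,
                 params: CohortParams | None = None) -> CohortResult:
    """find_index + apply_criteria + covariates in one call."""
    candidates = find_index(db, intake_window)
    return apply_criteria(db, candidates, codeset, params)
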