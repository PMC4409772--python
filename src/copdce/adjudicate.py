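"""Claims-based COPD exacerbation adjudication, pneumonia events,
utilization tallies, medication-use flags, and adherence.

An exacerbation is operationalized from raw claims as one of three event
types:

* ``inpatient``   — an inpatient stay with a *primary* COPD diagnosis
                    (onset = admission date);
* ``ed``          — an emergency-department visit with a COPD diagnosis in
                    *any* position (onset = service date);
* ``outpatient_rx`` — an office/outpatient visit with a COPD diagnosis in any
                    position paired with an OCS or antibiotic fill on the
                    same day or within 10 days after the visit (onset =
                    visit date).

Attribution rules then remove double-counting:

(i)   an ED visit falling inside an inpatient stay counts as the
      hospitalization only;
(ii)  an OCS/antibiotic fill within 14 days (absolute gap) of an ED or
      inpatient event onset counts as that event only;
(iii) multiple qualifying fills for the same visit are one event.

Finally, events within 14 days of each other are merged into a single
event.  Merging is anchored at the cluster's first event (a candidate is
absorbed iff its onset is within 14 days of the anchor); the merged event
takes the anchor's onset and the most severe member's type
(inpatient > ed > outpatient_rx).  A chained variant (absorb within 14 days
of the previous member) is available behind ``chained=True``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from copdce.data_model import (
    COMBO_CLASSES,
    ClaimsDatabase,
    CodeSet,
    default_codeset,
    medical_condition_mask,
)

RX_WINDOW_DAYS = 10       # fill on same day or within 10 days after the visit
ABSORB_DAYS = 14          # fills within 14 days of a severe onset are absorbed
MERGE_DAYS = 14           # events within 14 days are a single event
FOLLOWUP_DAYS = 365

_SEVERITY = {"inpatient": 2, "ed": 1, "outpatient_rx": 0}

MEDICATION_FLAG_CLASSES = ("ICS", "LABA", "LAMA", "SABA", "SAMA", "SABA_SAMA",
                           "OCS", "ANTIBIOTIC", "LTRA", "ROFLUMILAST",
                           "THEOPHYLLINE", "OMALIZUMAB")


@dataclass
class AdherenceSummary:
    n_index_fills: int
    fill_category: str  # "1", "2", "3", "4+"
    pdc: float


# ---------------------------------------------------------------------------
# follow-up resolution
# ---------------------------------------------------------------------------

def resolve_followup(db: ClaimsDatabase, record, spec) -> tuple[int, int, float]:
    """Resolve (start, end_inclusive, person_years) for a cohort record under
    a follow-up spec (variant in fixed_12mo / censor_at_switch /
    all_available / severe_only)."""
    index = int(record["index_date"])
    start = index
    fixed_end = index + FOLLOWUP_DAYS - 1
    variant = spec.variant
    if variant in ("fixed_12mo", "severe_only"):
        end = fixed_end
        py = 1.0
    elif variant == "censor_at_switch":
        switch = _switch_day(db, record)
        if switch is not None and switch <= fixed_end:
            end = switch - 1
            py = (switch - index) / FOLLOWUP_DAYS
        else:
            end = fixed_end
            py = 1.0
    elif variant == "all_available":
        enroll_end = _enrollment_end(db, record)
        end = min(enroll_end, spec.study_end) if spec.study_end is not None else enroll_end
        py = (end - index + 1) / FOLLOWUP_DAYS
    else:
        raise ValueError(f"unknown follow-up variant {variant!r}")
    if end < start:
        raise ValueError(f"follow-up end {end} before start {start}")
    return start, end, py


def _switch_day(db: ClaimsDatabase, record) -> int | None:
    """First post-index fill of an ICS/LABA combination differing from the
    index drug; same-class refills never censor."""
    ph = db.pharmacy
    m = (ph["patient_id"].eq(record["patient_id"])
         & ph["drug_class"].isin(COMBO_CLASSES)
         & ph["drug_class"].ne(record["index_drug"])
         & (ph["fill_date"] > int(record["index_date"])))
    if not m.any():
        return None
    return int(ph.loc[m, "fill_date"].min())


def _enrollment_end(db: ClaimsDatabase, record) -> int:
    """End of the continuous (gap-free, merged) enrollment run containing
    the index date."""
    spans = db.enrollment[db.enrollment["patient_id"].eq(record["patient_id"])]
    spans = spans.sort_values("start_date")
    index = int(record["index_date"])
    end = None
    for _, s in spans.iterrows():
        if end is not None and s["start_date"] <= end + 1:
            end = max(end, int(s["end_date"]))
        elif s["start_date"] <= index <= s["end_date"]:
            end = int(s["end_date"])
        elif end is not None and s["start_date"] > end + 1:
            if index <= end:
                break
            end = None
    if end is None:
        raise ValueError(f"index date {index} not inside any enrollment span")
    return end


# ---------------------------------------------------------------------------
# candidate extraction / attribution / merging (single record API)
# ---------------------------------------------------------------------------

def extract_candidates(db: ClaimsDatabase, record, spec, codeset: CodeSet | None = None
                       ) -> pd.DataFrame:
    """All candidate events for one patient with onsets inside the follow-up
    window.  outpatient_rx candidates are (visit, fill) pairs before rule
    (iii) dedup; ``fill_date`` is set for those rows only."""
    codeset = codeset or default_codeset()
    start, end, _ = resolve_followup(db, record, spec)
    med = db.medical[db.medical["patient_id"].eq(record["patient_id"])]
    ph = db.pharmacy[db.pharmacy["patient_id"].eq(record["patient_id"])]
    copd_primary = medical_condition_mask(med, "COPD", "primary", codeset)
    copd_any = medical_condition_mask(med, "COPD", "any", codeset)

    rows = []
    inpt = med[(med["place_of_service"] == "inpatient") & copd_primary]
    for _, c in inpt.iterrows():
        onset = int(c["admission_date"])
        if start <= onset <= end:
            rows.append(dict(patient_id=c["patient_id"], onset_date=onset,
                             type="inpatient", claim_id=c["claim_id"],
                             discharge_date=int(c["discharge_date"]),
                             fill_date=np.nan))
    ed = med[(med["place_of_service"] == "ed") & copd_any]
    for _, c in ed.iterrows():
        onset = int(c["service_date"])
        if start <= onset <= end:
            rows.append(dict(patient_id=c["patient_id"], onset_date=onset,
                             type="ed", claim_id=c["claim_id"],
                             discharge_date=np.nan, fill_date=np.nan))
    visits = med[med["place_of_service"].isin(("office", "outpatient")) & copd_any]
    fills = ph[ph["drug_class"].isin(("OCS", "ANTIBIOTIC"))]
    for _, v in visits.iterrows():
        vd = int(v["service_date"])
        if not (start <= vd <= end):
            continue
        gap = fills["fill_date"] - vd
        for _, f in fills[(gap >= 0) & (gap <= RX_WINDOW_DAYS)].iterrows():
            rows.append(dict(patient_id=v["patient_id"], onset_date=vd,
                             type="outpatient_rx",
                             claim_id=f"{v['claim_id']}+{f['claim_id']}",
                             discharge_date=np.nan, fill_date=int(f["fill_date"])))
    cols = ["patient_id", "onset_date", "type", "claim_id", "discharge_date", "fill_date"]
    return pd.DataFrame(rows, columns=cols)


def apply_attribution(candidates: pd.DataFrame, db: ClaimsDatabase | None = None
                      ) -> pd.DataFrame:
    """Apply rules (i)-(iii) within each patient; returns one row per
    surviving candidate (outpatient_rx deduped to one per visit)."""
    out = []
    for _, grp in candidates.groupby("patient_id", sort=False):
        out.append(_attribute_group(grp))
    if not out:
        return candidates.iloc[0:0]
    return pd.concat(out, ignore_index=True)


def _attribute_group(grp: pd.DataFrame) -> pd.DataFrame:
    inpt = grp[grp["type"] == "inpatient"]
    ed = grp[grp["type"] == "ed"]
    rx = grp[grp["type"] == "outpatient_rx"]
    # (i) ED inside an inpatient stay -> hospitalization only
    keep_ed = []
    for i, c in ed.iterrows():
        inside = ((inpt["onset_date"] <= c["onset_date"])
                  & (c["onset_date"] <= inpt["discharge_date"])).any()
        if not inside:
            keep_ed.append(i)
    ed = ed.loc[keep_ed]
    # (ii) fills within 14 days of a severe onset -> severe event only
    severe_onsets = np.concatenate([inpt["onset_date"].to_numpy(float),
                                    ed["onset_date"].to_numpy(float)])
    keep_rx = []
    for i, c in rx.iterrows():
        if severe_onsets.size and np.min(np.abs(severe_onsets - c["fill_date"])) <= ABSORB_DAYS:
            continue
        keep_rx.append(i)
    rx = rx.loc[keep_rx]
    # (iii) one candidate per visit
    rx = rx.sort_values(["onset_date", "fill_date"]).drop_duplicates("onset_date")
    return pd.concat([inpt, ed, rx]).sort_values(
        "onset_date", kind="stable").reset_index(drop=True)


def merge_events(candidates: pd.DataFrame, chained: bool = False) -> pd.DataFrame:
    """Collapse candidates within 14 days of each other into single events."""
    out = []
    for _, grp in candidates.groupby("patient_id", sort=False):
        days = grp["onset_date"].to_numpy(int)
        sev = np.array([_SEVERITY[t] for t in grp["type"]])
        order = np.lexsort((-sev, days))
        days, sev = days[order], sev[order]
        for onset, top, nmerged in _merge_stream(days, sev, chained):
            out.append(dict(patient_id=grp["patient_id"].iloc[0], onset_date=onset,
                            type=_type_name(top), severe=top >= 1,
                            merged_from=nmerged))
    return pd.DataFrame(out, columns=["patient_id", "onset_date", "type",
                                      "severe", "merged_from"])


def _merge_stream(days: np.ndarray, sev: np.ndarray, chained: bool):
    """Yield (anchor_onset, max_severity, n_members) clusters from a stream
    sorted by onset."""
    events = []
    i = 0
    n = len(days)
    while i < n:
        anchor = days[i]
        top = sev[i]
        last = anchor
        j = i + 1
        while j < n:
            ref = last if chained else anchor
            if days[j] - ref <= MERGE_DAYS:
                top = max(top, sev[j])
                last = days[j]
                j += 1
            else:
                break
        events.append((int(anchor), int(top), j - i))
        i = j
    return events


def _type_name(severity: int) -> str:
    return {2: "inpatient", 1: "ed", 0: "outpatient_rx"}[severity]


def adjudicate_record(db: ClaimsDatabase, record, spec, codeset: CodeSet | None = None,
                      chained: bool = False) -> pd.DataFrame:
    """extract -> attribute -> merge for a single cohort record."""
    cands = extract_candidates(db, record, spec, codeset)
    cands = apply_attribution(cands, db)
    return merge_events(cands, chained=chained)


def count_exacerbations(db: ClaimsDatabase, record, spec,
                        codeset: CodeSet | None = None,
                        events: pd.DataFrame | None = None,
                        chained: bool = False) -> tuple[int, float]:
    """(event count, person-years) under the follow-up variant; the
    severe_only variant counts inpatient/ED events only."""
    _, _, py = resolve_followup(db, record, spec)
    if events is None:
        events = adjudicate_record(db, record, spec, codeset, chained)
    if spec.variant == "severe_only":
        return int(events["severe"].sum()), py
    return len(events), py


def time_to_first(db: ClaimsDatabase, record, spec,
                  codeset: CodeSet | None = None,
                  events: pd.DataFrame | None = None) -> tuple[int, bool]:
    """Days from index to the first counted event; censored at the window
    end (returns window length, flag False) when no event occurred."""
    start, end, _ = resolve_followup(db, record, spec)
    if events is None:
        events = adjudicate_record(db, record, spec, codeset)
    if spec.variant == "severe_only":
        events = events[events["severe"]]
    if len(events):
        return int(events["onset_date"].min() - start), True
    return end - start + 1, False


# ---------------------------------------------------------------------------
# pneumonia, utilization, medication, adherence (single record API)
# ---------------------------------------------------------------------------

def detect_pneumonia(db: ClaimsDatabase, record, codeset: CodeSet | None = None) -> dict:
    """Any-position pneumonia diagnosis (ICD-9 480-486) during the 12-month
    post-index window, overall and by place of service."""
    codeset = codeset or default_codeset()
    index = int(record["index_date"])
    med = db.medical[db.medical["patient_id"].eq(record["patient_id"])]
    m = (medical_condition_mask(med, "PNEUMONIA", "any", codeset)
         & (med["service_date"] >= index)
         & (med["service_date"] <= index + FOLLOWUP_DAYS - 1))
    hits = med[m]
    place = hits["place_of_service"]
    return {
        "any": bool(len(hits)),
        "first_date": int(hits["service_date"].min()) if len(hits) else None,
        "inpatient": bool(place.eq("inpatient").any()),
        "ed": bool(place.eq("ed").any()),
        "outpatient": bool(place.isin(("office", "outpatient", "snf")).any()),
    }


def length_of_stay(admission, discharge):
    """Days from admission to discharge; same-day admission and discharge
    count as one."""
    return np.maximum(1, np.asarray(discharge) - np.asarray(admission))


def tally_utilization(db: ClaimsDatabase, record, scope: str = "copd_related",
                      codeset: CodeSet | None = None) -> dict:
    """Counts and inpatient lengths of stay by place of service over the
    12-month post-index window.  COPD-related inpatient/ICU stays require a
    primary COPD diagnosis; other places any position."""
    if scope not in ("copd_related", "all_cause"):
        raise ValueError(f"scope must be copd_related or all_cause, got {scope!r}")
    codeset = codeset or default_codeset()
    index = int(record["index_date"])
    med = db.medical[db.medical["patient_id"].eq(record["patient_id"])]
    med = med[(med["service_date"] >= index)
              & (med["service_date"] <= index + FOLLOWUP_DAYS - 1)]
    primary = medical_condition_mask(med, "COPD", "primary", codeset)
    anypos = medical_condition_mask(med, "COPD", "any", codeset)

    def _select(place_mask, dx_mask):
        if scope == "all_cause":
            return med[place_mask]
        return med[place_mask & dx_mask]

    inpt = _select(med["place_of_service"].eq("inpatient"), primary)
    icu = inpt[inpt["icu_flag"]]
    ed = _select(med["place_of_service"].eq("ed"), anypos)
    outpt = _select(med["place_of_service"].isin(("office", "outpatient")), anypos)
    snf = _select(med["place_of_service"].eq("snf"), anypos)
    return {
        "inpatient_stays": len(inpt),
        "inpatient_los": int(length_of_stay(inpt["admission_date"].astype(int),
                                            inpt["discharge_date"].astype(int)).sum()) if len(inpt) else 0,
        "icu_stays": len(icu),
        "icu_los": int(length_of_stay(icu["admission_date"].astype(int),
                                      icu["discharge_date"].astype(int)).sum()) if len(icu) else 0,
        "ed_visits": len(ed),
        "outpatient_visits": len(outpt),
        "snf_visits": len(snf),
    }


def medication_flags(db: ClaimsDatabase, record) -> dict:
    """Per-class >=1-fill flags over the 12-month post-index window."""
    index = int(record["index_date"])
    ph = db.pharmacy[db.pharmacy["patient_id"].eq(record["patient_id"])]
    ph = ph[(ph["fill_date"] >= index) & (ph["fill_date"] <= index + FOLLOWUP_DAYS - 1)]
    present = set(ph["drug_class"])
    return {cls: cls in present for cls in MEDICATION_FLAG_CLASSES}


def compute_adherence(db: ClaimsDatabase, record) -> AdherenceSummary:
    """Index-medication fill count (including the index fill) and proportion
    of days covered: PDC = min(1, sum days_supply / 365).  Days supply is
    summed literally; overlapping fills are not shifted forward."""
    index = int(record["index_date"])
    ph = db.pharmacy[db.pharmacy["patient_id"].eq(record["patient_id"])]
    m = (ph["drug_class"].eq(record["index_drug"])
         & (ph["fill_date"] >= index)
         & (ph["fill_date"] <= index + FOLLOWUP_DAYS - 1))
    fills = ph[m]
    n = len(fills)
    pdc = min(1.0, float(fills["days_supply"].sum()) / FOLLOWUP_DAYS)
    category = str(n) if n < 4 else "4+"
    return AdherenceSummary(n_index_fills=n, fill_category=category, pdc=pdc)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------

def adjudicate_cohort(db: ClaimsDatabase, cohort: pd.DataFrame, spec,
                      codeset: CodeSet | None = None, chained: bool = False
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Adjudicate every cohort record in one pass.

    Returns (events, outcomes): events has one row per retained
    exacerbation; outcomes one row per patient with counts, person-time,
    time-to-first, pneumonia flags, medication flags, and adherence.
    """
    codeset = codeset or default_codeset()
    med = db.medical
    ph = db.pharmacy
    copd_primary = medical_condition_mask(med, "COPD", "primary", codeset)
    copd_any = medical_condition_mask(med, "COPD", "any", codeset)
    pneu_any = medical_condition_mask(med, "PNEUMONIA", "any", codeset)

    inpt_df = med[med["place_of_service"].eq("inpatient") & copd_primary]
    ed_df = med[med["place_of_service"].eq("ed") & copd_any]
    visit_df = med[med["place_of_service"].isin(("office", "outpatient")) & copd_any]
    fill_df = ph[ph["drug_class"].isin(("OCS", "ANTIBIOTIC"))]
    pneu_df = med[pneu_any]
    combo_df = ph[ph["drug_class"].isin(COMBO_CLASSES)]

    def _index(df, cols):
        groups = {}
        for pid, idx in df.groupby("patient_id", sort=False).indices.items():
            groups[pid] = tuple(df[c].to_numpy()[idx] for c in cols)
        return groups

    g_inpt = _index(inpt_df, ["admission_date", "discharge_date"])
    g_ed = _index(ed_df, ["service_date"])
    g_visit = _index(visit_df, ["service_date"])
    g_fill = _index(fill_df, ["fill_date"])
    g_pneu = _index(pneu_df, ["service_date", "place_of_service"])
    g_combo = _index(combo_df, ["fill_date", "drug_class"])
    g_ph = _index(ph, ["fill_date", "drug_class", "days_supply"])
    g_enroll = _index(db.enrollment.sort_values(["patient_id", "start_date"]),
                      ["start_date", "end_date"])

    event_rows = []
    outcome_rows = []
    empty = np.empty(0, dtype=np.int64)
    study_end = getattr(spec, "study_end", None)
    for rec in cohort.itertuples(index=False):
        pid = rec.patient_id
        index = int(rec.index_date)
        fixed_end = index + FOLLOWUP_DAYS - 1
        combo = g_combo.get(pid)
        switch = None
        if combo is not None:
            days, classes = combo
            m = (classes != rec.index_drug) & (days > index)
            if m.any():
                switch = int(days[m].min())
        # follow-up window
        if spec.variant in ("fixed_12mo", "severe_only"):
            start, end, py = index, fixed_end, 1.0
        elif spec.variant == "censor_at_switch":
            if switch is not None and switch <= fixed_end:
                start, end, py = index, switch - 1, (switch - index) / FOLLOWUP_DAYS
            else:
                start, end, py = index, fixed_end, 1.0
        elif spec.variant == "all_available":
            starts, ends = g_enroll[pid]
            enroll_end = _run_end(starts, ends, index)
            end = min(enroll_end, study_end) if study_end is not None else enroll_end
            start, py = index, (end - index + 1) / FOLLOWUP_DAYS
        else:
            raise ValueError(f"unknown follow-up variant {spec.variant!r}")

        ia, idsch = g_inpt.get(pid, (empty, empty))
        ia = np.asarray(ia, dtype=np.int64)
        idsch = np.asarray(idsch, dtype=np.int64)
        in_win = (ia >= start) & (ia <= end)
        ia, idsch = ia[in_win], idsch[in_win]
        (ed_days,) = g_ed.get(pid, (empty,))
        ed_days = np.asarray(ed_days, dtype=np.int64)
        ed_days = ed_days[(ed_days >= start) & (ed_days <= end)]
        (v_days,) = g_visit.get(pid, (empty,))
        v_days = np.asarray(v_days, dtype=np.int64)
        v_days = v_days[(v_days >= start) & (v_days <= end)]
        (f_days,) = g_fill.get(pid, (empty,))
        f_days = np.asarray(f_days, dtype=np.int64)

        events = _adjudicate_arrays(ia, idsch, ed_days, v_days, f_days, chained)

        n_all = len(events)
        n_sev = sum(1 for _, s, _ in events if s >= 1)
        counted = [e for e in events if spec.variant != "severe_only" or e[1] >= 1]
        n_counted = len(counted)
        if counted:
            ttf, observed = int(min(e[0] for e in counted) - start), True
        else:
            ttf, observed = end - start + 1, False
        by_type = {2: 0, 1: 0, 0: 0}
        for _, s, _ in events:
            by_type[s] += 1
        for onset, sev, nm in events:
            event_rows.append((pid, onset, _type_name(sev), sev >= 1, nm))

        # pneumonia over the fixed 12-month window
        pneu = g_pneu.get(pid)
        p_any = p_in = p_ed = p_out = False
        p_first = None
        if pneu is not None:
            pdays, pplaces = pneu
            pdays = np.asarray(pdays, dtype=np.int64)
            m = (pdays >= index) & (pdays <= fixed_end)
            if m.any():
                p_any = True
                p_first = int(pdays[m].min())
                pl = np.asarray(pplaces)[m]
                p_in = bool((pl == "inpatient").any())
                p_ed = bool((pl == "ed").any())
                p_out = bool(np.isin(pl, ("office", "outpatient", "snf")).any())

        # adherence / medication use over the fixed 12-month window
        fills = g_ph.get(pid)
        n_fills = 0
        pdc = 0.0
        present: set = set()
        if fills is not None:
            fdays, fclasses, fsupply = fills
            fdays = np.asarray(fdays, dtype=np.int64)
            m = (fdays >= index) & (fdays <= fixed_end)
            fclasses = np.asarray(fclasses)[m]
            fsupply = np.asarray(fsupply, dtype=np.int64)[m]
            idx_m = fclasses == rec.index_drug
            n_fills = int(idx_m.sum())
            pdc = min(1.0, float(fsupply[idx_m].sum()) / FOLLOWUP_DAYS)
            present = set(fclasses)

        outcome_rows.append(dict(
            patient_id=pid, index_date=index, arm=rec.index_drug,
            n_events=n_counted, n_events_all=n_all, n_severe=n_sev,
            n_inpatient=by_type[2], n_ed=by_type[1], n_outpatient_rx=by_type[0],
            person_years=py, time_to_first=ttf, event_observed=observed,
            switch_day=switch,
            pneumonia_any=p_any, pneumonia_first=p_first,
            pneumonia_inpatient=p_in, pneumonia_ed=p_ed, pneumonia_outpatient=p_out,
            n_index_fills=n_fills,
            fill_category=str(n_fills) if n_fills < 4 else "4+",
            pdc=pdc,
            **{f"any_{cls.lower()}": cls in present for cls in MEDICATION_FLAG_CLASSES},
        ))

    events_df = pd.DataFrame(event_rows, columns=["patient_id", "onset_date",
                                                  "type", "severe", "merged_from"])
    return events_df, pd.DataFrame(outcome_rows)


def _run_end(starts: np.ndarray, ends: np.ndarray, index: int) -> int:
    end = None
    for s, e in zip(starts, ends):
        if end is not None and s <= end + 1:
            end = max(end, int(e))
        elif s <= index <= e:
            end = int(e)
    if end is None:
        raise ValueError(f"index date {index} not inside any enrollment span")
    return end


def _adjudicate_arrays(inpt_adm: np.ndarray, inpt_disch: np.ndarray,
                       ed_days: np.ndarray, visit_days: np.ndarray,
                       fill_days: np.ndarray, chained: bool
                       ) -> list[tuple[int, int, int]]:
    """Array kernel shared by the cohort driver: candidates -> attribution
    -> merge.  Returns [(onset, severity, merged_from), ...]."""
    # (i) drop ED visits inside an inpatient stay
    if len(ed_days) and len(inpt_adm):
        inside = ((ed_days[:, None] >= inpt_adm[None, :])
                  & (ed_days[:, None] <= inpt_disch[None, :])).any(axis=1)
        ed_days = ed_days[~inside]
    severe = np.concatenate([inpt_adm, ed_days])
    # outpatient pairs + (ii) + (iii)
    rx_onsets = []
    if len(visit_days) and len(fill_days):
        for v in np.unique(visit_days):
            gaps = fill_days - v
            ok = (gaps >= 0) & (gaps <= RX_WINDOW_DAYS)
            if not ok.any():
                continue
            fd = fill_days[ok]
            if len(severe):
                fd = fd[np.abs(fd[:, None] - severe[None, :]).min(axis=1) > ABSORB_DAYS]
            if len(fd):
                rx_onsets.append(v)
    days = np.concatenate([inpt_adm, ed_days, np.asarray(rx_onsets, dtype=np.int64)])
    if not len(days):
        return []
    sev = np.concatenate([np.full(len(inpt_adm), 2), np.full(len(ed_days), 1),
                          np.full(len(rx_onsets), 0)])
    order = np.lexsort((-sev, days))
    return _merge_stream(days[order], sev[order], chained)
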