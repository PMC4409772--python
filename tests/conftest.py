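import os
import sys

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, os.path.dirname(__file__))

from copdce.data_model import (  # noqa: E402
    ClaimsDatabase,
    ENROLL_COLS,
    PATIENT_COLS,
    PHARMACY_COLS,
    build_medical_frame,
    default_codeset,
)
from copdce.simulate import SimulationConfig, generate  # noqa: E402


@pytest.fixture(scope="session")
def codeset():
    return default_codeset()


@pytest.fixture(scope="session")
def small_study():
    """One small simulated study shared across read-only tests."""
    cfg = SimulationConfig(n_patients=400, seed=7)
    db, truth = generate(cfg)
    return cfg, db, truth


def make_database(patients=None, enrollment=None, medical=None, pharmacy=None,
                  n_dx_slots=5):
    """Hand-build a ClaimsDatabase from row dicts (medical rows carry a
    ``diagnoses`` list)."""
    patients = pd.DataFrame(patients or [], columns=PATIENT_COLS)
    enrollment = pd.DataFrame(enrollment or [], columns=ENROLL_COLS)
    if enrollment.empty:
        enrollment = enrollment.astype({"start_date": "int64", "end_date": "int64"},
                                       errors="ignore")
    medical = build_medical_frame(medical or [], n_dx_slots=n_dx_slots)
    pharmacy = pd.DataFrame(pharmacy or [], columns=PHARMACY_COLS)
    return ClaimsDatabase(patients=patients, enrollment=enrollment,
                          medical=medical, pharmacy=pharmacy)


def stream_to_database(streams):
    """Convert [(medical_dicts, pharmacy_dicts)] micro-streams (one per
    patient) into a single ClaimsDatabase + cohort frame anchored at index
    day 1000."""
    med_rows, rx_rows, cohort_rows, pat_rows = [], [], [], []
    for i, (med, rx) in enumerate(streams):
        pid = f"S{i:05d}"
        pat_rows.append(dict(patient_id=pid, birth_year=1950, sex="female",
                             region="south"))
        cohort_rows.append(dict(patient_id=pid, index_date=1000, index_drug="BFC"))
        for j, c in enumerate(med):
            row = dict(claim_id=f"{pid}M{j}", patient_id=pid,
                       service_date=c["date"] if c["place"] != "inpatient" else c["adm"],
                       place_of_service=c["place"], diagnoses=c["dxs"])
            if c["place"] == "inpatient":
                row["admission_date"] = c["adm"]
                row["discharge_date"] = c["disch"]
            med_rows.append(row)
        for j, f in enumerate(rx):
            rx_rows.append(dict(claim_id=f"{pid}R{j}", patient_id=pid,
                                fill_date=f["date"], drug_class=f["class"],
                                days_supply=f.get("days_supply", 7)))
    db = make_database(patients=pat_rows, medical=med_rows, pharmacy=rx_rows)
    return db, pd.DataFrame(cohort_rows)


def random_micro_stream(rng: np.random.Generator):
    """A random claim stream of at most 12 claims around index day 1000,
    mixing COPD and non-COPD claims of every kind."""
    med, rx = [], []
    n = int(rng.integers(1, 13))
    for _ in range(n):
        day = 1000 + int(rng.integers(0, 70))
        kind = int(rng.integers(0, 6))
        if kind == 0:  # inpatient, sometimes COPD-primary
            los = int(rng.integers(1, 10))
            dx1 = ["491.21", "486", "428.0"][int(rng.integers(0, 3))]
            med.append(dict(place="inpatient", date=day, adm=day,
                            disch=day + los - 1, dxs=[dx1, "401.9"]))
        elif kind == 1:  # ED, COPD in varying position or absent
            dxs = [["491.21"], ["786.09", "496"], ["786.09"]][int(rng.integers(0, 3))]
            med.append(dict(place="ed", date=day, dxs=dxs))
        elif kind == 2:  # office visit
            dxs = [["492.8"], ["401.9"]][int(rng.integers(0, 2))]
            med.append(dict(place="office", date=day, dxs=dxs))
        elif kind == 3:
            rx.append(dict({"class": "OCS"}, date=day))
        elif kind == 4:
            rx.append(dict({"class": "ANTIBIOTIC"}, date=day))
        else:  # irrelevant fill
            rx.append(dict({"class": "SABA"}, date=day))
    return med, rx
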