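"""Claims data structures, ICD-9-CM / drug-class code sets, and CSV table I/O.

The database is four linked pandas tables (patients, enrollment spans,
medical claims, pharmacy claims).  Dates throughout the package are integer
day indices against an arbitrary epoch; diagnosis codes are ICD-9-CM strings
matched period-insensitively by prefix ("491.21" and "49121" are the same
code, both matched by the stem "491").
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

SEXES = ("female", "male")
REGIONS = ("northeast", "midwest", "south", "west")
PLACES = ("inpatient", "ed", "office", "outpatient", "snf")

#: pharmacy-claim drug classes; exposure is modeled at the class level
DRUG_CLASSES = (
    "BFC", "FSC", "OTHER_ICS_LABA",
    "ICS", "LABA", "LAMA", "SABA", "SAMA", "SABA_SAMA",
    "OCS", "ANTIBIOTIC", "LTRA", "ROFLUMILAST", "THEOPHYLLINE",
    "OMALIZUMAB", "CARDIOVASCULAR", "OTHER",
)

#: fixed-dose ICS/LABA combination classes (the "naive one year prior" rule
#: bars these, not ICS or LABA monotherapy)
COMBO_CLASSES = ("BFC", "FSC", "OTHER_ICS_LABA")

SPECIALTIES = (
    "pulmonologist", "internal_medicine", "family_medicine",
    "cardiologist", "allergist", "non_physician", "other",
)


class ClaimsValidationError(ValueError):
    """Raised when a claims table violates a structural invariant."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("\n".join(self.errors))


# ---------------------------------------------------------------------------
# code sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodeSet:
    """Named mapping condition -> ICD-9-CM code stems (3-5 characters)."""

    conditions: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for name, prefixes in self.conditions.items():
            for p in prefixes:
                stem = p.replace(".", "")
                if not (3 <= len(stem) <= 5):
                    raise ValueError(f"code stem {p!r} for {name!r} must be 3-5 characters")

    def prefixes(self, condition: str) -> tuple[str, ...]:
        try:
            return self.conditions[condition]
        except KeyError:
            raise KeyError(f"unknown condition {condition!r}; known: {sorted(self.conditions)}") from None

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({k: list(v) for k, v in self.conditions.items()}))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeSet":
        raw = yaml.safe_load(Path(path).read_text())
        return cls({str(k): tuple(str(p) for p in v) for k, v in raw.items()})


def default_codeset() -> CodeSet:
    """Default ICD-9-CM stems: COPD 491/492/496, pneumonia 480-486, cancer
    140-208, plus comorbidity sets used as covariates."""
    cancer = tuple(str(c) for c in range(140, 209))
    return CodeSet({
        "COPD": ("491", "492", "496"),
        "PNEUMONIA": tuple(str(c) for c in range(480, 487)),
        "CANCER": cancer,
        "ASTHMA": ("493",),
        "HYPERTENSION": ("401", "402", "403", "404", "405"),
        "DIABETES": ("250",),
        "PVD": ("440", "443"),
        "CAD": ("410", "411", "412", "413", "414"),
        "DEPRESSION_ANXIETY": ("296", "300", "311"),
        "CHF": ("428",),
    })


def match_code(code: str, condition: str, codeset: CodeSet) -> bool:
    """True iff ``code`` (period removed) begins with one of the condition's
    stems.  Matching is prefix-based: "491.21", "4912", "491" all match COPD;
    "49" does not."""
    if not code:
        return False
    stems = tuple(p.replace(".", "") for p in codeset.prefixes(condition))
    return code.replace(".", "").startswith(stems)


def claim_has_condition(claim, condition: str, position: str, codeset: CodeSet) -> bool:
    """Test a medical-claim row for a condition in the primary (slot 1) or
    any diagnosis position.

    ``claim`` is a mapping/Series with dx1..dxK fields.
    """
    if position not in ("primary", "any"):
        raise ValueError(f"position must be 'primary' or 'any', got {position!r}")
    dx_cols = sorted((k for k in claim.keys() if _is_dx_col(k)), key=lambda c: int(c[2:]))
    if position == "primary":
        dx_cols = dx_cols[:1]
    for c in dx_cols:
        v = claim[c]
        if isinstance(v, str) and v and match_code(v, condition, codeset):
            return True
    return False


def _is_dx_col(name: str) -> bool:
    return name.startswith("dx") and name[2:].isdigit()


_STRIP_CACHE: dict = {}  # id(df) -> (df, {col: stripped ndarray}); two entries kept


def _stripped_dx(medical: pd.DataFrame, col: str) -> np.ndarray:
    entry = _STRIP_CACHE.get(id(medical))
    if entry is None or entry[0] is not medical:
        if len(_STRIP_CACHE) > 2:
            _STRIP_CACHE.clear()
        entry = (medical, {})
        _STRIP_CACHE[id(medical)] = entry
    cols = entry[1]
    if col not in cols:
        cols[col] = (medical[col].fillna("").astype(str)
                     .str.replace(".", "", regex=False).to_numpy())
    return cols[col]


def medical_condition_mask(medical: pd.DataFrame, condition: str, position: str,
                           codeset: CodeSet) -> pd.Series:
    """Vectorized claim_has_condition over a medical-claims table."""
    if position not in ("primary", "any"):
        raise ValueError(f"position must be 'primary' or 'any', got {position!r}")
    stems = tuple(p.replace(".", "") for p in codeset.prefixes(condition))
    cols = dx_columns(medical)
    if position == "primary":
        cols = cols[:1]
    mask = np.zeros(len(medical), dtype=bool)
    for c in cols:
        stripped = _stripped_dx(medical, c)
        todo = ~mask
        mask[todo] |= np.array([s.startswith(stems) for s in stripped[todo]],
                               dtype=bool) if todo.any() else False
    return pd.Series(mask, index=medical.index)


def dx_columns(medical: pd.DataFrame) -> list[str]:
    return sorted((c for c in medical.columns if _is_dx_col(c)), key=lambda c: int(c[2:]))


# ---------------------------------------------------------------------------
# database container
# ---------------------------------------------------------------------------

PATIENT_COLS = ["patient_id", "birth_year", "sex", "region"]
ENROLL_COLS = ["patient_id", "start_date", "end_date", "medical_eligible", "pharmacy_eligible"]
MEDICAL_FIXED_COLS = ["claim_id", "patient_id", "service_date", "place_of_service",
                      "icu_flag", "admission_date", "discharge_date"]
PHARMACY_COLS = ["claim_id", "patient_id", "fill_date", "drug_class", "days_supply"]


@dataclass
class ClaimsDatabase:
    """Four linked tables; every claim's patient_id must exist in patients."""

    patients: pd.DataFrame
    enrollment: pd.DataFrame
    medical: pd.DataFrame
    pharmacy: pd.DataFrame

    @property
    def n_dx_slots(self) -> int:
        return len(dx_columns(self.medical))

    def validate(self, epoch_year: int = 2006) -> None:
        """Raise ClaimsValidationError listing every violation with its row."""
        errors: list[str] = []
        pids = set(self.patients["patient_id"])

        if self.patients["patient_id"].duplicated().any():
            for i in self.patients.index[self.patients["patient_id"].duplicated()]:
                errors.append(f"patients row {i + 1}: duplicate patient_id "
                              f"{self.patients.at[i, 'patient_id']!r}")
        bad_sex = ~self.patients["sex"].isin(SEXES)
        for i in self.patients.index[bad_sex]:
            errors.append(f"patients row {i + 1}: invalid sex {self.patients.at[i, 'sex']!r}")

        for name, table in (("enrollment", self.enrollment),
                            ("medical_claims", self.medical),
                            ("pharmacy_claims", self.pharmacy)):
            missing = ~table["patient_id"].isin(pids)
            for i in table.index[missing]:
                errors.append(f"{name} row {i + 1}: unknown patient_id "
                              f"{table.at[i, 'patient_id']!r}")

        bad_span = self.enrollment["start_date"] > self.enrollment["end_date"]
        for i in self.enrollment.index[bad_span]:
            errors.append(f"enrollment row {i + 1}: start_date after end_date")
        # spans per patient must not overlap
        es = self.enrollment.sort_values(["patient_id", "start_date"])
        same = es["patient_id"].eq(es["patient_id"].shift())
        overlap = same & (es["start_date"] <= es["end_date"].shift())
        for i in es.index[overlap.fillna(False)]:
            errors.append(f"enrollment row {i + 1}: overlapping spans for "
                          f"{es.at[i, 'patient_id']!r}")

        med = self.medical
        if len(med):
            empty_dx = med[dx_columns(med)[0]].fillna("").astype(str).eq("")
            for i in med.index[empty_dx]:
                errors.append(f"medical_claims row {i + 1}: empty primary diagnosis")
            inpt = med["place_of_service"].eq("inpatient")
            bad_adm = inpt & (med["admission_date"].isna() | med["discharge_date"].isna())
            for i in med.index[bad_adm]:
                errors.append(f"medical_claims row {i + 1}: inpatient claim missing "
                              "admission/discharge date")
            ok = inpt & med["admission_date"].notna() & med["discharge_date"].notna()
            bad_order = ok & (med["admission_date"] > med["discharge_date"]).fillna(False)
            for i in med.index[bad_order]:
                errors.append(f"medical_claims row {i + 1}: admission after discharge")
            bad_svc = ok & (med["service_date"] != med["admission_date"]).fillna(False)
            for i in med.index[bad_svc]:
                errors.append(f"medical_claims row {i + 1}: inpatient service_date "
                              "differs from admission_date")
            bad_place = ~med["place_of_service"].isin(PLACES)
            for i in med.index[bad_place]:
                errors.append(f"medical_claims row {i + 1}: invalid place_of_service "
                              f"{med.at[i, 'place_of_service']!r}")

        ph = self.pharmacy
        if len(ph):
            bad_class = ~ph["drug_class"].isin(DRUG_CLASSES)
            for i in ph.index[bad_class]:
                errors.append(f"pharmacy_claims row {i + 1}: invalid drug_class "
                              f"{ph.at[i, 'drug_class']!r}")
            bad_ds = ph["days_supply"] < 1
            for i in ph.index[bad_ds]:
                errors.append(f"pharmacy_claims row {i + 1}: days_supply < 1")

        if errors:
            raise ClaimsValidationError(errors)

    def equals(self, other: "ClaimsDatabase") -> bool:
        for a, b in ((self.patients, other.patients), (self.enrollment, other.enrollment),
                     (self.medical, other.medical), (self.pharmacy, other.pharmacy)):
            if not _normalize(a).equals(_normalize(b)):
                return False
        return True


def _normalize(df: pd.DataFrame) -> pd.DataFrame:
    out = df.reset_index(drop=True).copy()
    for c in out.columns:
        if out[c].dtype == object:
            out[c] = out[c].fillna("")
    return out


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

_FILES = {
    "patients": "patients.csv",
    "enrollment": "enrollment.csv",
    "medical": "medical_claims.csv",
    "pharmacy": "pharmacy_claims.csv",
}

_INT_COLS = {
    "patients": ["birth_year"],
    "enrollment": ["start_date", "end_date"],
    "medical": ["service_date"],
    "pharmacy": ["fill_date", "days_supply"],
}
_BOOL_COLS = {
    "enrollment": ["medical_eligible", "pharmacy_eligible"],
    "medical": ["icu_flag"],
}


def write_claims(db: ClaimsDatabase, dir_path: str | Path) -> None:
    """Write the four tables as CSV (dates as integers, flags as 0/1,
    absent admission/discharge blank)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    for attr, fname in _FILES.items():
        df = getattr(db, attr).copy()
        for c in _BOOL_COLS.get(attr, []):
            df[c] = df[c].astype(bool).astype(int)
        if attr == "medical":
            df["admission_date"] = df["admission_date"].astype("Int64")
            df["discharge_date"] = df["discharge_date"].astype("Int64")
        df.to_csv(dir_path / fname, index=False)


def read_claims(dir_path: str | Path, validate: bool = True) -> ClaimsDatabase:
    """Read a claims directory; raises on missing files/columns, malformed
    integers, or (if ``validate``) any structural violation."""
    dir_path = Path(dir_path)
    frames = {}
    for attr, fname in _FILES.items():
        path = dir_path / fname
        if not path.exists():
            raise FileNotFoundError(f"missing claims table: {path}")
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        expected = {"patients": PATIENT_COLS, "enrollment": ENROLL_COLS,
                    "pharmacy": PHARMACY_COLS}.get(attr)
        if attr == "medical":
            missing = [c for c in MEDICAL_FIXED_COLS + ["provider_specialty"]
                       if c not in df.columns]
            if not any(_is_dx_col(c) for c in df.columns):
                missing.append("dx1")
        else:
            missing = [c for c in expected if c not in df.columns]
        if missing:
            raise ValueError(f"{fname}: missing columns {missing}")
        for c in _INT_COLS[attr]:
            df[c] = _to_int(df, c, fname)
        for c in _BOOL_COLS.get(attr, []):
            df[c] = _to_int(df, c, fname).astype(bool)
        if attr == "medical":
            for c in ("admission_date", "discharge_date"):
                blank = df[c].eq("")
                vals = _to_int(df[~blank], c, fname) if (~blank).any() else []
                out = pd.Series(pd.NA, index=df.index, dtype="Int64")
                out[~blank] = vals
                df[c] = out
        frames[attr] = df
    db = ClaimsDatabase(**frames)
    if validate:
        db.validate()
    return db


def _to_int(df: pd.DataFrame, col: str, fname: str) -> pd.Series:
    try:
        return df[col].astype(np.int64)
    except (ValueError, TypeError) as exc:
        bad = df.index[~df[col].astype(str).str.fullmatch(r"-?\d+")]
        row = int(bad[0]) + 1 if len(bad) else "?"
        raise ValueError(f"{fname} row {row}: malformed integer in column {col!r}") from exc


def build_medical_frame(rows: list[dict], n_dx_slots: int = 5) -> pd.DataFrame:
    """Assemble a medical-claims frame from dicts with a ``diagnoses`` list."""
    recs = []
    for r in rows:
        r = dict(r)
        dxs = list(r.pop("diagnoses"))
        for j in range(n_dx_slots):
            r[f"dx{j + 1}"] = dxs[j] if j < len(dxs) else ""
        r.setdefault("icu_flag", False)
        r.setdefault("admission_date", pd.NA)
        r.setdefault("discharge_date", pd.NA)
        r.setdefault("provider_specialty", "other")
        recs.append(r)
    cols = MEDICAL_FIXED_COLS + [f"dx{j + 1}" for j in range(n_dx_slots)] + ["provider_specialty"]
    df = pd.DataFrame(recs, columns=cols)
    df["admission_date"] = df["admission_date"].astype("Int64")
    df["discharge_date"] = df["discharge_date"].astype("Int64")
    df["icu_flag"] = df["icu_flag"].astype(bool)
    df["service_date"] = df["service_date"].astype(np.int64)
    return df


def empty_database(n_dx_slots: int = 5) -> ClaimsDatabase:
    med_cols = MEDICAL_FIXED_COLS + [f"dx{j+1}" for j in range(n_dx_slots)] + ["provider_specialty"]
    return ClaimsDatabase(
        patients=pd.DataFrame(columns=PATIENT_COLS),
        enrollment=pd.DataFrame(columns=ENROLL_COLS),
        medical=pd.DataFrame(columns=med_cols),
        pharmacy=pd.DataFrame(columns=PHARMACY_COLS),
    )
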