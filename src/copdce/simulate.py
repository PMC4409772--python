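"""Synthetic administrative-claims generator with known ground truth.

Emulates a US managed-care claims source for COPD patients initiating one
of two ICS/LABA combinations (BFC vs FSC): demographics and pre-index
clinical history drive a confounded treatment assignment, post-index
exacerbation counts follow a gamma-frailty (negative binomial) process, and
every intended event is realized as the minimal claim bundle its type
requires.  Default marginals are calibrated to the study population this
package emulates: age mean 64, 53% female, 37% BFC share, FSC exacerbation
rate 0.86/person-year split 7% hospitalization / 15% ED / 78%
outpatient-Rx, ~18% with a pneumonia diagnosis, 33% single-fill patients
with ~3.9 index fills and PDC ~0.33 on average.

Ground-truth stability: intended event onsets are re-spaced to >= 15 days
apart, and outpatient-Rx fill offsets are constrained so no qualifying fill
falls within 14 days of a severe (inpatient/ED) onset.  Consequently the
adjudication rules neither merge nor absorb intended events, and with noise
toggles off (and for the planted decoy kinds, on) the adjudicated event
stream equals the intended one exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from copdce.data_model import (
    ClaimsDatabase,
    ENROLL_COLS,
    MEDICAL_FIXED_COLS,
    PATIENT_COLS,
    PHARMACY_COLS,
    REGIONS,
    SPECIALTIES,
    build_medical_frame,
)

MIN_EVENT_GAP = 15          # intended onsets at least this far apart
POST_SPAN = 350             # intended post-index onsets in [index, index+350]
PRE_LO, PRE_HI = -350, -15  # intended pre-index onsets

DECOY_REASONS = ("prior_ics_laba", "age_lt_40", "enrollment",
                 "cancer", "ocs_180", "dual_initiation")

COPD_CODES = ("491.21", "492.8", "496")
PNEUMONIA_CODES = ("481", "482.0", "485", "486")
COMORBIDITY_CODES = {
    "hypertension": "401.9", "diabetes": "250.00", "pvd": "443.9",
    "cad": "414.01", "depression_anxiety": "300.00", "chf": "428.0",
}
FILLER_DX = "786.09"  # dyspnea; matches no study code set


@dataclass
class SimulationConfig:
    n_patients: int = 12000
    seed: int = 0
    bfc_share: float = 0.37

    # covariate model
    age_mean: float = 64.0
    age_sd: float = 11.5
    age_min: int = 40
    age_max: int = 95
    p_female: float = 0.53
    p_asthma: float = 0.35
    p_prior_pneumonia: float = 0.23
    prior_exac_mean: float = 1.06
    prior_exac_dispersion: float = 0.4
    #: per-class squared coefficient of variation of the severity frailty
    #: multiplying pre-index fill intensities; claims fill counts are
    #: heavily overdispersed and mutually correlated through severity
    fill_dispersion: dict = field(default_factory=lambda: {
        "OCS": 1.5, "ANTIBIOTIC": 1.0, "SABA": 2.0, "SABA_SAMA": 2.0,
        "SAMA": 2.0, "LABA": 6.0, "LAMA": 3.0, "ICS": 2.0,
        "THEOPHYLLINE": 2.0, "CARDIOVASCULAR": 0.5})
    comorbidity_prev: dict = field(default_factory=lambda: {
        "hypertension": 0.68, "diabetes": 0.25, "pvd": 0.12,
        "cad": 0.20, "depression_anxiety": 0.20, "chf": 0.10})
    ltra_probs: tuple = (0.85, 0.08, 0.07)       # 0 / 1 / 2+ pre-index fills
    region_probs: tuple = (0.20, 0.25, 0.35, 0.20)
    specialty_probs: tuple = (0.25, 0.25, 0.30, 0.05, 0.03, 0.05, 0.07)

    # treatment assignment (log-odds per covariate; nonzero = confounded;
    # the intercept is solved so the BFC share matches bfc_share).
    # "severity" is the latent frailty shared by the whole pre-index
    # history, so channeling by severity shifts every prior-use covariate
    # between arms at once, echoing the modest pre-matching differences of
    # the emulated population (age about -1.3 y, asthma about +4 pp, prior
    # exacerbations about +0.14 in the BFC arm)
    treatment_coefs: dict = field(default_factory=lambda: {
        "age": -0.006, "female": -0.05, "asthma": 0.15,
        "severity": 0.30, "prior_exac": 0.05, "prior_pneumonia": -0.05})
    #: severity tilt (log-odds per unit severity) on pre-index event types:
    #: sicker patients' histories hold more hospitalizations and ED visits
    pre_type_severity_tilt: tuple = (0.5, 0.25, 0.0)
    #: multiplier on asthma patients' fill intensity for asthma-typical
    #: classes, giving asthma a medication signature the propensity model
    #: can exploit
    asthma_fill_multiplier: dict = field(default_factory=lambda: {
        "SABA": 1.6, "ICS": 2.5, "LTRA": 2.5, "SABA_SAMA": 1.3})

    # outcome model (log rate per covariate; intercept normalized so the
    # FSC-arm marginal rate equals fsc_rate over eligible patients)
    fsc_rate: float = 0.86
    true_rr: float = 1.0
    dispersion: float = 1.2                      # gamma-frailty NB2 dispersion
    outcome_coefs: dict = field(default_factory=lambda: {
        "age": 0.012, "female": -0.05, "asthma": 0.15,
        "prior_exac": 0.25, "prior_pneumonia": 0.15})
    event_type_split: tuple = (0.07, 0.15, 0.78)  # inpatient / ED / outpatient-Rx
    crude_rr_margin: float = 1.02                 # confounding the design must exceed

    # post-index concomitant medication use (Poisson fill counts per class;
    # means chosen so >=1-fill proportions echo the study population)
    post_fill_means: dict = field(default_factory=lambda: {
        "LAMA": 0.40, "SABA": 0.67, "SAMA": 0.048, "SABA_SAMA": 0.19,
        "ICS": 0.062, "LABA": 0.022, "LTRA": 0.13, "ROFLUMILAST": 0.005,
        "THEOPHYLLINE": 0.03, "OMALIZUMAB": 0.0015, "OCS": 0.25,
        "ANTIBIOTIC": 0.85, "CARDIOVASCULAR": 1.0})

    # pneumonia
    pneumonia_prob: float = 0.18
    pneumonia_place_split: tuple = (0.45, 0.05, 0.50)  # inpatient / ED / outpatient

    # index-medication fill process
    single_fill_share: float = 0.33
    mean_index_fills: float = 3.9
    days_supply: int = 30
    refill_interval: int = 30
    max_index_fills: int = 13

    # switching / enrollment
    switch_prob: float = 0.15
    dropout_hazard: float = 0.0      # 0 for the fixed 12-month design
    extra_enrollment_mean: float = 365.0

    # calendar (day indices)
    intake_start: int = 400
    intake_end: int = 1130
    study_end: int = 2200
    epoch_year: int = 2006

    # noise toggles
    noise_ed_inpatient_pairs: bool = False
    noise_decoy_fills: bool = False
    noise_duplicate_fills: bool = False
    decoy_share: float = 0.08        # share of planted ineligible patients

    def validate(self) -> None:
        props = [self.bfc_share, self.p_female, self.p_asthma,
                 self.p_prior_pneumonia, self.single_fill_share,
                 self.pneumonia_prob, self.switch_prob, self.decoy_share,
                 *self.comorbidity_prev.values()]
        if any(not (0.0 <= p <= 1.0) for p in props):
            raise ValueError("all proportions must lie in [0, 1]")
        if self.fsc_rate <= 0 or self.prior_exac_mean <= 0:
            raise ValueError("rates must be positive")
        if self.dispersion < 0 or self.true_rr <= 0:
            raise ValueError("dispersion must be >= 0 and true_rr > 0")
        if abs(sum(self.event_type_split) - 1) > 1e-9:
            raise ValueError("event_type_split must sum to 1")
        if not (1 < self.mean_index_fills < self.max_index_fills):
            raise ValueError("mean_index_fills must be in (1, max_index_fills)")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")

    def with_noise(self, on: bool = True) -> "SimulationConfig":
        return dataclasses.replace(self, noise_ed_inpatient_pairs=on,
                                   noise_decoy_fills=on, noise_duplicate_fills=on)


@dataclass
class GroundTruth:
    """Intended per-patient truth used as the recovery-testing oracle."""

    patients: pd.DataFrame  # arm, covariates, eligibility + reason, switch, fills
    events: pd.DataFrame    # intended post-index exacerbations (onset, type)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _spaced_days(rng: np.random.Generator, counts: np.ndarray, span: int,
                 min_gap: int = MIN_EVENT_GAP) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient sorted day offsets in [0, span] with gaps >= min_gap.

    counts must satisfy span - min_gap*(count-1) >= 0.
    """
    counts = np.asarray(counts)
    pat = np.repeat(np.arange(len(counts)), counts)
    bounds = np.repeat(span - min_gap * (counts - 1), counts)
    u = rng.integers(0, bounds + 1)
    order = np.lexsort((u, pat))
    pat_s, u_s = pat[order], u[order]
    starts = np.r_[0, np.cumsum(counts)[:-1]]
    rank = np.arange(len(pat_s)) - np.repeat(starts, counts)
    return pat_s, u_s + min_gap * rank


def _event_types(rng, n, split):
    # codes: 2 = inpatient, 1 = ed, 0 = outpatient_rx
    return rng.choice(np.array([2, 1, 0]), size=n, p=list(split))


def _tilted_event_types(rng, z, split, tilt):
    """Per-event type draw with severity-tilted log-odds
    (inpatient, ed, outpatient order in both split and tilt)."""
    logits = np.log(np.asarray(split)) + np.outer(z, np.asarray(tilt))
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(len(z))
    code = np.where(u < p[:, 0], 2, np.where(u < p[:, 0] + p[:, 1], 1, 0))
    return code


def _fill_offsets(rng, pat, days, types):
    """Offsets (0-10 days) for outpatient-Rx fills, constrained so the fill
    stays > 14 days from the next severe onset (the previous one is
    automatically satisfied by the >= 15-day spacing)."""
    n = len(days)
    next_day = np.r_[days[1:], 0]
    next_pat = np.r_[pat[1:], -1]
    next_sev = np.r_[types[1:] >= 1, False]
    same = next_pat == pat
    allow = np.full(n, 10)
    constrained = same & next_sev
    allow[constrained] = np.minimum(10, next_day[constrained] - days[constrained]
                                    - MIN_EVENT_GAP)
    allow = np.maximum(allow, 0)
    return np.floor(rng.random(n) * (allow + 1)).astype(np.int64)


class _ClaimBuffer:
    """Accumulates medical/pharmacy claim batches as column arrays."""

    def __init__(self):
        self.med: list[dict] = []
        self.rx: list[dict] = []

    def medical(self, pid, service, place, dx1, dx2=None, adm=None, disch=None,
                icu=None, specialty=None):
        n = len(pid)
        self.med.append(dict(
            patient_id=np.asarray(pid),
            service_date=np.asarray(service, dtype=np.int64),
            place_of_service=np.broadcast_to(np.asarray(place), (n,)).copy(),
            dx1=np.asarray(dx1, dtype=object),
            dx2=np.asarray(dx2, dtype=object) if dx2 is not None
                else np.full(n, "", dtype=object),
            admission_date=(np.asarray(adm, dtype=float) if adm is not None
                            else np.full(n, np.nan)),
            discharge_date=(np.asarray(disch, dtype=float) if disch is not None
                            else np.full(n, np.nan)),
            icu_flag=(np.asarray(icu, dtype=bool) if icu is not None
                      else np.zeros(n, dtype=bool)),
            provider_specialty=np.asarray(specialty, dtype=object),
        ))

    def pharmacy(self, pid, fill, drug_class, days_supply):
        n = len(pid)
        self.rx.append(dict(
            patient_id=np.asarray(pid),
            fill_date=np.asarray(fill, dtype=np.int64),
            drug_class=np.broadcast_to(np.asarray(drug_class), (n,)).copy(),
            days_supply=np.broadcast_to(np.asarray(days_supply, dtype=np.int64),
                                        (n,)).copy(),
        ))


# ---------------------------------------------------------------------------
# generator
# ---------------------------------------------------------------------------

def generate(config: SimulationConfig) -> tuple[ClaimsDatabase, GroundTruth]:
    """Generate a ClaimsDatabase plus the GroundTruth it was built from.

    Deterministic: the same config (including seed) yields identical tables.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    pids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    n_decoy = int(round(cfg.decoy_share * n))
    decoy_reason = np.full(n, "", dtype=object)
    if n_decoy:
        decoy_reason[n - n_decoy:] = [DECOY_REASONS[i % len(DECOY_REASONS)]
                                      for i in range(n_decoy)]
    eligible = decoy_reason == ""

    # --- covariates -------------------------------------------------------
    lo = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    hi = (cfg.age_max - cfg.age_mean) / cfg.age_sd
    u = norm.cdf(lo) + rng.random(n) * (norm.cdf(hi) - norm.cdf(lo))
    age = np.floor(cfg.age_mean + cfg.age_sd * norm.ppf(u)).astype(np.int64)
    young = decoy_reason == "age_lt_40"
    age[young] = rng.integers(25, 40, young.sum())

    female = rng.random(n) < cfg.p_female
    asthma = rng.random(n) < cfg.p_asthma
    prior_pneu = rng.random(n) < cfg.p_prior_pneumonia
    comorb = {name: rng.random(n) < prev
              for name, prev in cfg.comorbidity_prev.items()}
    # latent severity drives the whole pre-index history (and treatment
    # channeling); per-channel lognormal frailties share this factor
    z_sev = rng.standard_normal(n)
    lam = cfg.prior_exac_mean * _lognormal_frailty(z_sev, cfg.prior_exac_dispersion)
    prior_exac = np.minimum(rng.poisson(lam),
                            (PRE_HI - PRE_LO) // MIN_EVENT_GAP + 1)
    ltra_base = rng.choice(np.array([0, 1, 2]), size=n, p=list(cfg.ltra_probs))
    ltra_high = rng.choice(np.array([0, 1, 2]), size=n, p=[0.70, 0.15, 0.15])
    ltra_n = np.where(asthma, ltra_high, ltra_base)
    region = rng.choice(np.array(REGIONS, dtype=object), size=n,
                        p=list(cfg.region_probs))
    specialty = rng.choice(np.array(SPECIALTIES, dtype=object), size=n,
                           p=list(cfg.specialty_probs))

    index_date = rng.integers(cfg.intake_start, cfg.intake_end + 1, n)
    birth_year = cfg.epoch_year + index_date // 365 - age

    # --- treatment assignment --------------------------------------------
    tc = cfg.treatment_coefs
    xb = (tc.get("age", 0.0) * (age - cfg.age_mean)
          + tc.get("female", 0.0) * female
          + tc.get("asthma", 0.0) * asthma
          + tc.get("severity", 0.0) * z_sev
          + tc.get("prior_exac", 0.0) * prior_exac
          + tc.get("prior_pneumonia", 0.0) * prior_pneu)
    xb_e = xb[eligible]
    b0 = brentq(lambda b: expit(b + xb_e).mean() - cfg.bfc_share, -20, 20)
    arm_bfc = rng.random(n) < expit(b0 + xb)

    # --- outcome process --------------------------------------------------
    oc = cfg.outcome_coefs
    eta = (oc.get("age", 0.0) * (age - cfg.age_mean)
           + oc.get("female", 0.0) * female
           + oc.get("asthma", 0.0) * asthma
           + oc.get("prior_exac", 0.0) * prior_exac
           + oc.get("prior_pneumonia", 0.0) * prior_pneu)
    base = cfg.fsc_rate * np.exp(eta) / np.exp(eta[eligible]).mean()
    rate = base * np.where(arm_bfc, cfg.true_rr, 1.0)
    k = cfg.dispersion
    frailty = rng.gamma(1.0 / k, k, n) if k > 0 else np.ones(n)
    max_events = POST_SPAN // MIN_EVENT_GAP + 1
    counts = np.minimum(rng.poisson(rate * frailty), max_events)
    counts[~eligible] = 0

    # intended post-index events
    ev_pat, ev_rel = _spaced_days(rng, counts, POST_SPAN)
    ev_type = _event_types(rng, len(ev_pat), cfg.event_type_split)
    ev_abs = index_date[ev_pat] + ev_rel
    ev_g = _fill_offsets(rng, ev_pat, ev_rel, ev_type)

    # pre-index exacerbation history (all patients, decoys included)
    pre_counts = prior_exac.copy()
    pre_pat, pre_off = _spaced_days(rng, pre_counts, PRE_HI - PRE_LO)
    pre_rel = PRE_LO + pre_off
    pre_type = _tilted_event_types(rng, z_sev[pre_pat], cfg.event_type_split,
                                   cfg.pre_type_severity_tilt)
    pre_abs = index_date[pre_pat] + pre_rel
    pre_g = _fill_offsets(rng, pre_pat, pre_rel, pre_type)

    buf = _ClaimBuffer()
    _realize_events(rng, buf, cfg, pids, specialty, ev_pat, ev_abs, ev_type, ev_g)
    _realize_events(rng, buf, cfg, pids, specialty, pre_pat, pre_abs, pre_type, pre_g)

    # routine pre-index office visits with a COPD diagnosis: two distinct
    # dates for everyone, guaranteeing the "two other medical claims" pathway
    r1 = rng.integers(PRE_LO, PRE_HI + 1, n)
    r2 = rng.integers(PRE_LO, PRE_HI + 1, n)
    r2 = np.where(r2 == r1, np.where(r1 < PRE_HI, r1 + 1, r1 - 1), r2)
    dx_r1 = rng.choice(np.array(COPD_CODES, dtype=object), size=n)
    dx_r2 = rng.choice(np.array(COPD_CODES, dtype=object), size=n)
    buf.medical(pids, index_date + r1, "office", dx_r1, specialty=specialty)
    buf.medical(pids, index_date + r2, "office", dx_r2, specialty=specialty)

    # comorbidity / asthma / prior-pneumonia diagnosis claims
    for name, flags in [("asthma", asthma), ("prior_pneumonia", prior_pneu),
                        *comorb.items()]:
        m = flags.astype(bool)
        if not m.any():
            continue
        code = {"asthma": "493.20",
                "prior_pneumonia": "486"}.get(name, COMORBIDITY_CODES.get(name))
        days = index_date[m] + rng.integers(PRE_LO, PRE_HI + 1, int(m.sum()))
        buf.medical(pids[m], days, "office", np.full(int(m.sum()), code, dtype=object),
                    specialty=specialty[m])

    _pre_index_fills(rng, buf, cfg, pids, ltra_n, z_sev, asthma, index_date)

    # --- index fills & switching -----------------------------------------
    single = rng.random(n) < cfg.single_fill_share
    mean_multi = (cfg.mean_index_fills - cfg.single_fill_share) / (1 - cfg.single_fill_share)
    p_geo = 1.0 / (mean_multi - 1.0)
    n_fills = np.where(single, 1, np.minimum(1 + rng.geometric(p_geo, n),
                                             cfg.max_index_fills))
    drug = np.where(arm_bfc, "BFC", "FSC").astype(object)
    fp = np.repeat(np.arange(n), n_fills)
    starts = np.r_[0, np.cumsum(n_fills)[:-1]]
    j = np.arange(len(fp)) - np.repeat(starts, n_fills)
    buf.pharmacy(pids[fp], index_date[fp] + cfg.refill_interval * j, drug[fp],
                 cfg.days_supply)

    # post-index concomitant fills.  Stray OCS/antibiotic fills are safe for
    # ground-truth stability: a stray fill pairing with an intended visit is
    # deduplicated per visit, and one pairing with a planted decoy visit
    # necessarily lies within 14 days of its severe onset and is absorbed.
    for cls, mean in cfg.post_fill_means.items():
        c = rng.poisson(mean, n)
        pat = np.repeat(np.arange(n), c)
        days = index_date[pat] + rng.integers(0, 365, len(pat))
        supply = (rng.integers(5, 15, len(pat)) if cls == "OCS"
                  else rng.integers(7, 11, len(pat)) if cls == "ANTIBIOTIC"
                  else np.full(len(pat), 30))
        buf.pharmacy(pids[pat], days, cls, supply)

    switch = eligible & (rng.random(n) < cfg.switch_prob)
    switch_day = np.where(switch, index_date + rng.integers(30, 365, n), -1)
    other = np.where(arm_bfc, "FSC", "BFC").astype(object)
    sw_class = np.where(rng.random(n) < 0.5, other,
                        np.full(n, "OTHER_ICS_LABA", dtype=object))
    m = switch
    buf.pharmacy(pids[m], switch_day[m], sw_class[m], cfg.days_supply)

    # --- pneumonia --------------------------------------------------------
    pneu = eligible & (rng.random(n) < cfg.pneumonia_prob)
    pneu_day = np.where(pneu, index_date + rng.integers(0, 365, n), -1)
    pneu_place_code = rng.choice(np.array(["inpatient", "ed", "outpatient"],
                                          dtype=object),
                                 size=n, p=list(cfg.pneumonia_place_split))
    pneu_dx = rng.choice(np.array(PNEUMONIA_CODES, dtype=object), size=n)
    pneu_los = rng.integers(1, 11, n)
    for place in ("inpatient", "ed", "outpatient"):
        m = pneu & (pneu_place_code == place)
        if not m.any():
            continue
        if place == "inpatient":
            buf.medical(pids[m], pneu_day[m], "inpatient", pneu_dx[m],
                        adm=pneu_day[m], disch=pneu_day[m] + pneu_los[m] - 1,
                        icu=rng.random(int(m.sum())) < 0.15,
                        specialty=specialty[m])
        else:
            buf.medical(pids[m], pneu_day[m], "ed" if place == "ed" else "office",
                        pneu_dx[m], specialty=specialty[m])

    # --- planted ineligible decoys ----------------------------------------
    _decoy_claims(rng, buf, cfg, pids, index_date, decoy_reason, other, specialty)

    # --- claim-level noise -------------------------------------------------
    if cfg.noise_ed_inpatient_pairs:
        m = ev_type == 2
        dx = rng.choice(np.array(COPD_CODES, dtype=object), size=int(m.sum()))
        buf.medical(pids[ev_pat[m]], ev_abs[m], "ed", dx,
                    specialty=specialty[ev_pat[m]])
    if cfg.noise_decoy_fills:
        m = ev_type >= 1
        dx = rng.choice(np.array(COPD_CODES, dtype=object), size=int(m.sum()))
        buf.medical(pids[ev_pat[m]], ev_abs[m] + 2, "office", dx,
                    specialty=specialty[ev_pat[m]])
        buf.pharmacy(pids[ev_pat[m]], ev_abs[m] + 3, "OCS", 7)
    if cfg.noise_duplicate_fills:
        m = ev_type == 0
        buf.pharmacy(pids[ev_pat[m]], ev_abs[m] + ev_g[m], "ANTIBIOTIC", 7)

    # --- enrollment --------------------------------------------------------
    start = index_date - 365 - rng.integers(5, 40, n)
    extra = np.minimum(rng.exponential(cfg.extra_enrollment_mean, n), 1500).astype(np.int64)
    end = index_date + 365 + extra
    if cfg.dropout_hazard > 0:
        drop = index_date + rng.geometric(cfg.dropout_hazard, n)
        dropped = eligible & (drop < index_date + 365)
        end = np.where(dropped, drop, end)
        decoy_reason = decoy_reason.copy()
        decoy_reason[dropped] = "enrollment"
        eligible = decoy_reason == ""
        counts[dropped] = 0  # their events may fall outside enrollment
    gap = decoy_reason == "enrollment"
    rows = []
    for i in np.flatnonzero(~gap):
        rows.append((pids[i], start[i], end[i]))
    enroll = pd.DataFrame(rows, columns=["patient_id", "start_date", "end_date"])
    gap_rows = []
    for i in np.flatnonzero(gap):
        gap_rows.append((pids[i], start[i], index_date[i] - 100))
        gap_rows.append((pids[i], index_date[i] - 40, end[i]))
    enroll = pd.concat([enroll, pd.DataFrame(gap_rows, columns=enroll.columns)],
                       ignore_index=True)
    enroll["medical_eligible"] = True
    enroll["pharmacy_eligible"] = True

    db = _assemble(buf, pids, birth_year, female, region, enroll)

    truth_patients = pd.DataFrame({
        "patient_id": pids,
        "eligible": eligible,
        "exclusion_reason": decoy_reason,
        "arm": np.where(arm_bfc, "BFC", "FSC"),
        "index_date": index_date,
        "age": age, "female": female.astype(int), "asthma": asthma.astype(int),
        "prior_pneumonia": prior_pneu.astype(int), "prior_exac": prior_exac,
        "severity": z_sev,
        **{name: flags.astype(int) for name, flags in comorb.items()},
        "true_rate": rate,
        "n_events": counts,
        "switch_day": pd.array(np.where(switch, switch_day, pd.NA), dtype="Int64"),
        "pneumonia_day": pd.array(np.where(pneu, pneu_day, pd.NA), dtype="Int64"),
        "pneumonia_place": np.where(pneu, pneu_place_code, ""),
        "n_index_fills": n_fills,
        "pdc": np.minimum(1.0, n_fills * cfg.days_supply / 365.0),
    })
    keep = eligible[ev_pat]
    truth_events = pd.DataFrame({
        "patient_id": pids[ev_pat[keep]],
        "onset_date": ev_abs[keep],
        "rel_day": ev_rel[keep],
        "type": np.array(["outpatient_rx", "ed", "inpatient"], dtype=object)[ev_type[keep]],
        "severe": ev_type[keep] >= 1,
    }).sort_values(["patient_id", "onset_date"]).reset_index(drop=True)
    return db, GroundTruth(patients=truth_patients, events=truth_events)


def _realize_events(rng, buf: _ClaimBuffer, cfg, pids, specialty,
                    pat, days, types, g):
    """Materialize intended events as minimal claim bundles."""
    m_in = types == 2
    if m_in.any():
        los = rng.integers(1, 15, int(m_in.sum()))
        dx = rng.choice(np.array(COPD_CODES, dtype=object), size=int(m_in.sum()))
        buf.medical(pids[pat[m_in]], days[m_in], "inpatient", dx,
                    adm=days[m_in], disch=days[m_in] + los - 1,
                    icu=rng.random(int(m_in.sum())) < 0.10,
                    specialty=specialty[pat[m_in]])
    m_ed = types == 1
    if m_ed.any():
        n_ed = int(m_ed.sum())
        copd = rng.choice(np.array(COPD_CODES, dtype=object), size=n_ed)
        primary_pos = rng.random(n_ed) < 0.5
        dx1 = np.where(primary_pos, copd, FILLER_DX).astype(object)
        dx2 = np.where(primary_pos, "", copd).astype(object)
        buf.medical(pids[pat[m_ed]], days[m_ed], "ed", dx1, dx2=dx2,
                    specialty=specialty[pat[m_ed]])
    m_rx = types == 0
    if m_rx.any():
        n_rx = int(m_rx.sum())
        dx = rng.choice(np.array(COPD_CODES, dtype=object), size=n_rx)
        buf.medical(pids[pat[m_rx]], days[m_rx], "office", dx,
                    specialty=specialty[pat[m_rx]])
        is_ocs = rng.random(n_rx) < 0.6
        supply = np.where(is_ocs, rng.integers(5, 15, n_rx), rng.integers(7, 11, n_rx))
        cls = np.where(is_ocs, "OCS", "ANTIBIOTIC").astype(object)
        buf.pharmacy(pids[pat[m_rx]], days[m_rx] + g[m_rx], cls, supply)


def _lognormal_frailty(z: np.ndarray, variance: float) -> np.ndarray:
    """Unit-mean lognormal frailty exp(sigma z - sigma^2/2) with the given
    variance, sharing the severity factor z."""
    if variance <= 0:
        return np.ones_like(z)
    sigma = np.sqrt(np.log1p(variance))
    return np.exp(sigma * z - sigma ** 2 / 2)


#: pre-index standalone fill intensities (fills per patient-year)
PRE_FILL_MEANS = {"OCS": 0.7, "ANTIBIOTIC": 2.2, "SABA": 2.0, "SABA_SAMA": 0.9,
                  "SAMA": 0.15, "LABA": 0.17, "LAMA": 1.1, "ICS": 0.5,
                  "THEOPHYLLINE": 0.05, "CARDIOVASCULAR": 1.0}


def _pre_index_fills(rng, buf, cfg, pids, ltra_n, z_sev, asthma, index_date):
    """Standalone pre-index medication fills (covariate history), each
    class Poisson with a severity-shared lognormal frailty.  OCS days
    supply is capped well below the 180-day exclusion threshold for
    non-decoy patients."""
    n = len(pids)
    for cls, mean in PRE_FILL_MEANS.items():
        frailty = _lognormal_frailty(z_sev, cfg.fill_dispersion.get(cls, 0.0))
        mult = np.where(asthma, cfg.asthma_fill_multiplier.get(cls, 1.0), 1.0)
        c = rng.poisson(mean * mult * frailty)
        if cls == "OCS":
            c = np.minimum(c, 8)  # keeps total supply far below 180 days
        pat = np.repeat(np.arange(n), c)
        days = index_date[pat] + rng.integers(-355, -9, len(pat))
        if cls == "OCS":
            supply = rng.integers(5, 15, len(pat))
        elif cls == "ANTIBIOTIC":
            supply = rng.integers(7, 11, len(pat))
        else:
            supply = np.full(len(pat), 30)
        buf.pharmacy(pids[pat], days, cls, supply)
    pat = np.repeat(np.arange(n), ltra_n)
    days = index_date[pat] + rng.integers(-355, -9, len(pat))
    buf.pharmacy(pids[pat], days, "LTRA", 30)


def _decoy_claims(rng, buf, cfg, pids, index_date, decoy_reason, other_drug,
                  specialty):
    m = decoy_reason == "prior_ics_laba"
    if m.any():
        buf.pharmacy(pids[m], index_date[m] - rng.integers(30, 300, int(m.sum())),
                     "OTHER_ICS_LABA", 30)
    m = decoy_reason == "cancer"
    if m.any():
        buf.medical(pids[m], index_date[m] - rng.integers(30, 300, int(m.sum())),
                    "office", np.full(int(m.sum()), "162.9", dtype=object),
                    specialty=specialty[m])
    m = decoy_reason == "ocs_180"
    if m.any():
        buf.pharmacy(pids[m], index_date[m] - 200, "OCS", 90)
        buf.pharmacy(pids[m], index_date[m] - 100, "OCS", 95)
    m = decoy_reason == "dual_initiation"
    if m.any():
        buf.pharmacy(pids[m], index_date[m], other_drug[m], cfg.days_supply)


def _assemble(buf: _ClaimBuffer, pids, birth_year, female, region,
              enroll: pd.DataFrame) -> ClaimsDatabase:
    patients = pd.DataFrame({
        "patient_id": pids,
        "birth_year": birth_year,
        "sex": np.where(female, "female", "male"),
        "region": region,
    })
    med_parts = [pd.DataFrame(b) for b in buf.med]
    med = pd.concat(med_parts, ignore_index=True) if med_parts else pd.DataFrame()
    med["dx3"] = ""
    med["dx4"] = ""
    med["dx5"] = ""
    med = med.sort_values(["patient_id", "service_date", "place_of_service", "dx1"],
                          kind="stable").reset_index(drop=True)
    med.insert(0, "claim_id", [f"M{i:07d}" for i in range(len(med))])
    med["admission_date"] = med["admission_date"].astype("Int64")
    med["discharge_date"] = med["discharge_date"].astype("Int64")
    med = med[MEDICAL_FIXED_COLS + [f"dx{i}" for i in range(1, 6)] + ["provider_specialty"]]

    rx_parts = [pd.DataFrame(b) for b in buf.rx]
    rx = pd.concat(rx_parts, ignore_index=True)
    rx = rx.sort_values(["patient_id", "fill_date", "drug_class"],
                        kind="stable").reset_index(drop=True)
    rx.insert(0, "claim_id", [f"R{i:07d}" for i in range(len(rx))])
    rx = rx[PHARMACY_COLS]

    enroll = enroll.sort_values(["patient_id", "start_date"]).reset_index(drop=True)
    enroll["start_date"] = enroll["start_date"].astype(np.int64)
    enroll["end_date"] = enroll["end_date"].astype(np.int64)
    return ClaimsDatabase(patients=patients, enrollment=enroll[ENROLL_COLS],
                          medical=med, pharmacy=rx)


def write_ground_truth(truth: GroundTruth, dir_path) -> None:
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    truth.patients.to_csv(dir_path / "ground_truth_patients.csv", index=False)
    truth.events.to_csv(dir_path / "ground_truth_events.csv", index=False)


# ---------------------------------------------------------------------------
# implied marginals (calibration targets)
# ---------------------------------------------------------------------------

def expected_marginals(config: SimulationConfig) -> dict:
    """Exact marginals implied by the generator for eligible patients,
    used as calibration targets (integer-age truncated normal; enumerated,
    capped fill distribution; arm-mixed exacerbation rate)."""
    cfg = config
    ks = np.arange(cfg.age_min, cfg.age_max)
    pk = (norm.cdf((ks + 1 - cfg.age_mean) / cfg.age_sd)
          - norm.cdf((ks - cfg.age_mean) / cfg.age_sd))
    pk = pk / pk.sum()
    age_mean = float((ks * pk).sum())

    s = cfg.single_fill_share
    mean_multi = (cfg.mean_index_fills - s) / (1 - s)
    p = 1.0 / (mean_multi - 1.0)
    ns = np.arange(1, cfg.max_index_fills + 1)
    probs = np.zeros(len(ns))
    probs[0] = s
    for j, nn in enumerate(ns[1:-1], start=1):
        probs[j] = (1 - s) * p * (1 - p) ** (nn - 2)
    probs[-1] = (1 - s) * (1 - p) ** (cfg.max_index_fills - 2)
    pdc = np.minimum(1.0, ns * cfg.days_supply / 365.0)

    rate = cfg.fsc_rate * ((1 - cfg.bfc_share) + cfg.bfc_share * cfg.true_rr)
    return {
        "age_mean": age_mean,
        "p_female": cfg.p_female,
        "exacerbation_rate": rate,
        "event_type_split": tuple(cfg.event_type_split),
        "p_pneumonia": cfg.pneumonia_prob,
        "mean_index_fills": float((ns * probs).sum()),
        "single_fill_share": s,
        "pdc_mean": float((pdc * probs).sum()),
    }


# ---------------------------------------------------------------------------
# hand-auditable toy fixtures
# ---------------------------------------------------------------------------

def generate_toy_fixtures() -> dict:
    """Tiny (<= 10 patient) databases, one per adjudication rule, each with
    the hand-enumerated expected outcome attached.

    Returns name -> dict(db, index_date, index_drug, expected).
    """
    fixtures = {}

    def make(name, med_rows, rx_rows, expected):
        idx = 1000
        med = [dict(patient_id="P1", service_date=idx - 300, place_of_service="office",
                    diagnoses=["491.21"]),
               dict(patient_id="P1", service_date=idx - 200, place_of_service="office",
                    diagnoses=["496"])] + med_rows
        rx = [dict(patient_id="P1", fill_date=idx, drug_class="BFC", days_supply=30)] + rx_rows
        med_df = build_medical_frame([dict(claim_id=f"M{i:03d}", **r)
                                      for i, r in enumerate(med)])
        rx_df = pd.DataFrame([dict(claim_id=f"R{i:03d}", **r) for i, r in enumerate(rx)],
                             columns=PHARMACY_COLS)
        db = ClaimsDatabase(
            patients=pd.DataFrame([dict(patient_id="P1", birth_year=1948,
                                        sex="female", region="south")],
                                  columns=PATIENT_COLS),
            enrollment=pd.DataFrame([dict(patient_id="P1", start_date=idx - 400,
                                          end_date=idx + 400, medical_eligible=True,
                                          pharmacy_eligible=True)], columns=ENROLL_COLS),
            medical=med_df, pharmacy=rx_df)
        fixtures[name] = dict(db=db, index_date=idx, index_drug="BFC",
                              expected=expected)

    make("empty", [], [], dict(n_events=0, onsets=[], types=[]))

    make("ed_collapse",
         [dict(patient_id="P1", service_date=1005, place_of_service="inpatient",
               admission_date=1005, discharge_date=1009, diagnoses=["491.21"]),
          dict(patient_id="P1", service_date=1005, place_of_service="ed",
               diagnoses=["496"])],
         [],
         dict(n_events=1, onsets=[1005], types=["inpatient"]))

    make("fill_absorb",
         [dict(patient_id="P1", service_date=1003, place_of_service="inpatient",
               admission_date=1003, discharge_date=1006, diagnoses=["492.8"]),
          dict(patient_id="P1", service_date=1005, place_of_service="office",
               diagnoses=["491.21"])],
         [dict(patient_id="P1", fill_date=1012, drug_class="OCS", days_supply=7)],
         dict(n_events=1, onsets=[1003], types=["inpatient"]))

    make("multi_fill_single_event",
         [dict(patient_id="P1", service_date=1005, place_of_service="office",
               diagnoses=["491.21"])],
         [dict(patient_id="P1", fill_date=1006, drug_class="OCS", days_supply=7),
          dict(patient_id="P1", fill_date=1009, drug_class="ANTIBIOTIC", days_supply=10)],
         dict(n_events=1, onsets=[1005], types=["outpatient_rx"]))

    make("merge_14d",
         [dict(patient_id="P1", service_date=1000 + d, place_of_service="office",
               diagnoses=["491.21"]) for d in (0, 10, 20)],
         [dict(patient_id="P1", fill_date=1000 + d, drug_class="OCS", days_supply=7)
          for d in (0, 10, 20)],
         dict(n_events=2, onsets=[1000, 1020],
              types=["outpatient_rx", "outpatient_rx"]))

    make("switch_censor",
         [dict(patient_id="P1", service_date=1030, place_of_service="office",
               diagnoses=["491.21"]),
          dict(patient_id="P1", service_date=1100, place_of_service="inpatient",
               admission_date=1100, discharge_date=1104, diagnoses=["496"]),
          dict(patient_id="P1", service_date=1300, place_of_service="inpatient",
               admission_date=1300, discharge_date=1302, diagnoses=["491.21"])],
         [dict(patient_id="P1", fill_date=1030, drug_class="OCS", days_supply=7),
          dict(patient_id="P1", fill_date=1090, drug_class="OTHER_ICS_LABA",
               days_supply=30)],
         dict(n_events=3, onsets=[1030, 1100, 1300],
              types=["outpatient_rx", "inpatient", "inpatient"],
              censored_count=1, censored_person_years=90 / 365))

    make("severe_only",
         [dict(patient_id="P1", service_date=1050, place_of_service="inpatient",
               admission_date=1050, discharge_date=1053, diagnoses=["491.21"]),
          dict(patient_id="P1", service_date=1200, place_of_service="office",
               diagnoses=["492.8"])],
         [dict(patient_id="P1", fill_date=1205, drug_class="OCS", days_supply=7)],
         dict(n_events=2, onsets=[1050, 1200], types=["inpatient", "outpatient_rx"],
              severe_count=1))

    return fixtures
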