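"""Outcome models: negative binomial rate models with marginal
standardization, Cox time-to-event with Kaplan-Meier curves, logistic,
ordinal logistic and linear models, and the negative-binomial sample-size
calculation.

Every fit returns an :class:`OutcomeEstimate` with the effect measure on
its natural scale, a Wald 95% CI formed on the link scale, the p-value of
the arm contrast, and adjusted per-arm summaries.  Patients are treated as
independent (matched-pair correlation is ignored in the standard errors,
mirroring conventional practice for propensity-matched claims analyses);
no multiple-testing adjustment is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.stats import norm
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.miscmodels.ordinal_model import OrderedModel


@dataclass
class OutcomeEstimate:
    measure: str              # rate_ratio | odds_ratio | hazard_ratio | mean_difference
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    arm_summary: dict = field(default_factory=dict)  # adjusted per-arm rates/props/means
    covariates: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)
    converged: bool = True


def _design(arm: pd.Series, covariates: pd.DataFrame | None) -> pd.DataFrame:
    X = pd.DataFrame({"arm": np.asarray(arm, dtype=float)})
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True)
        for c in cov.columns:
            if not pd.api.types.is_numeric_dtype(cov[c]):
                dummies = pd.get_dummies(cov[c].astype(str), prefix=c, drop_first=True)
                cov = cov.drop(columns=[c]).join(dummies[sorted(dummies.columns)])
        X = pd.concat([X, cov.astype(float)], axis=1)
    return sm.add_constant(X, has_constant="add")


def _wald(params, bse, name, log_scale=True):
    est, se = float(params[name]), float(bse[name])
    z = norm.ppf(0.975)
    lo, hi = est - z * se, est + z * se
    p = 2 * norm.sf(abs(est) / se) if se > 0 else np.nan
    if log_scale:
        with np.errstate(over="ignore"):
            return float(np.exp(est)), float(np.exp(lo)), float(np.exp(hi)), p
    return est, lo, hi, p


def encode_arm(arm: pd.Series) -> pd.Series:
    """BFC = 1, FSC = 0 (FSC is the reference group)."""
    if arm.dtype == object or isinstance(arm.dtype, pd.CategoricalDtype):
        return arm.eq("BFC").astype(float)
    return arm.astype(float)


# ---------------------------------------------------------------------------
# negative binomial rate model
# ---------------------------------------------------------------------------

def fit_rate_model(counts, arm, covariates: pd.DataFrame | None = None,
                   person_time=None, alpha: float | None = None) -> OutcomeEstimate:
    """NB regression of event counts on arm + covariates with a
    log(person-time) offset.

    ``alpha`` fixes the NB2 dispersion; ``alpha=0`` fits Poisson; the
    default (None) estimates dispersion by maximum likelihood jointly with
    the coefficients.  The rate ratio is the exponentiated arm coefficient;
    adjusted per-arm rates come from marginal standardization (average
    predicted rate with everyone assigned to each arm in turn).
    """
    counts = np.asarray(counts, dtype=float)
    arm = encode_arm(pd.Series(np.asarray(arm)).reset_index(drop=True))
    if person_time is None:
        person_time = np.ones_like(counts)
    person_time = np.asarray(person_time, dtype=float)
    if (person_time <= 0).any():
        raise ValueError("person_time must be positive")
    X = _design(arm, covariates)
    by_arm_total = {a: counts[arm == a].sum() for a in (0.0, 1.0)}
    flagged = any(v == 0 for v in by_arm_total.values())

    offset = np.log(person_time)
    converged = True
    est_alpha = alpha
    if alpha is None:
        model = NegativeBinomial(counts, X, offset=offset, loglike_method="nb2")
        try:
            with np.errstate(all="ignore"):
                res = model.fit(disp=0, maxiter=200, method="bfgs")
            converged = bool(res.mle_retvals.get("converged", True))
            est_alpha = float(res.params["alpha"])
        except Exception:
            converged = False
            res = None
        if res is None or not np.isfinite(res.params.drop("alpha")).all() \
                or est_alpha is None or est_alpha < 0:
            # fall back to Poisson when the NB likelihood degenerates
            res = sm.GLM(counts, X, family=sm.families.Poisson(),
                         offset=offset).fit()
            est_alpha = 0.0
        params, bse = res.params, res.bse
    elif alpha == 0:
        res = sm.GLM(counts, X, family=sm.families.Poisson(), offset=offset).fit()
        params, bse = res.params, res.bse
    else:
        res = sm.GLM(counts, X, family=sm.families.NegativeBinomial(alpha=alpha),
                     offset=offset).fit()
        params, bse = res.params, res.bse

    rr, lo, hi, p = _wald(params, bse, "arm", log_scale=True)
    # marginal standardization over the analysis sample, per person-year
    beta = params.drop("alpha") if "alpha" in params.index else params
    rates = {}
    for a, label in ((1.0, "BFC"), (0.0, "FSC")):
        Xa = X.copy()
        Xa["arm"] = a
        rates[label] = float(np.exp(Xa.to_numpy() @ beta.to_numpy()).mean())
    return OutcomeEstimate(
        measure="rate_ratio", estimate=rr, ci_low=lo, ci_high=hi, p_value=p,
        arm_summary={"adjusted_rate_bfc": rates["BFC"],
                     "adjusted_rate_fsc": rates["FSC"]},
        covariates=list(covariates.columns) if covariates is not None else [],
        metadata={"alpha": est_alpha, "one_arm_all_zero": flagged},
        converged=converged)


# ---------------------------------------------------------------------------
# time to event
# ---------------------------------------------------------------------------

def fit_time_to_event(times, event_flags, arm, covariates: pd.DataFrame | None = None
                      ) -> tuple[OutcomeEstimate, dict]:
    """Cox proportional hazards (Efron ties) plus per-arm Kaplan-Meier
    step functions."""
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    arm = encode_arm(pd.Series(np.asarray(arm)).reset_index(drop=True))
    if not flags[arm == 1].any() and not flags[arm == 0].any():
        raise ValueError("no events in either arm")
    df = pd.DataFrame({"time": times, "event": flags.astype(int), "arm": arm})
    if covariates is not None:
        X = _design(arm, covariates).drop(columns=["const", "arm"])
        df = pd.concat([df, X], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr, lo, hi, p = _wald(cph.params_, cph.standard_errors_, "arm", log_scale=True)
    curves = {}
    for a, label in ((1.0, "BFC"), (0.0, "FSC")):
        km = KaplanMeierFitter()
        km.fit(times[arm == a], flags[arm == a], label=label)
        sf = km.survival_function_
        curves[label] = (sf.index.to_numpy(), sf[label].to_numpy())
    est = OutcomeEstimate(measure="hazard_ratio", estimate=hr, ci_low=lo,
                          ci_high=hi, p_value=p,
                          arm_summary={"events_bfc": int(flags[arm == 1].sum()),
                                       "events_fsc": int(flags[arm == 0].sum())},
                          covariates=list(covariates.columns) if covariates is not None else [],
                          metadata={"ties": "efron"})
    return est, curves


# ---------------------------------------------------------------------------
# binary / ordinal / linear
# ---------------------------------------------------------------------------

def fit_binary_model(flags, arm, covariates: pd.DataFrame | None = None
                     ) -> OutcomeEstimate:
    """Logistic regression; OR = exponentiated arm coefficient."""
    y = np.asarray(flags, dtype=float)
    arm = encode_arm(pd.Series(np.asarray(arm)).reset_index(drop=True))
    X = _design(arm, covariates)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    separation = bool((np.abs(res.params) > 15).any())
    or_, lo, hi, p = _wald(res.params, res.bse, "arm", log_scale=True)
    beta = res.params
    props = {}
    for a, label in ((1.0, "BFC"), (0.0, "FSC")):
        Xa = X.copy()
        Xa["arm"] = a
        props[label] = float(1 / (1 + np.exp(-(Xa.to_numpy() @ beta.to_numpy()))).mean())
    return OutcomeEstimate(measure="odds_ratio", estimate=or_, ci_low=lo,
                           ci_high=hi, p_value=p,
                           arm_summary={"adjusted_prop_bfc": props["BFC"],
                                        "adjusted_prop_fsc": props["FSC"]},
                           covariates=list(covariates.columns) if covariates is not None else [],
                           metadata={"possible_separation": separation},
                           converged=not separation)


def fit_ordinal_model(categories, arm, covariates: pd.DataFrame | None = None
                      ) -> OutcomeEstimate:
    """Proportional-odds ordinal logistic regression for ordered categories
    (e.g. index-fill counts 1/2/3/4+).  The proportional-odds assumption is
    not tested; this is recorded in the metadata."""
    cats = pd.Series(np.asarray(categories)).reset_index(drop=True)
    arm = encode_arm(pd.Series(np.asarray(arm)).reset_index(drop=True))
    levels = sorted(cats.astype(str).unique())
    if len(levels) < 2:
        return OutcomeEstimate(measure="odds_ratio", estimate=np.nan,
                               ci_low=np.nan, ci_high=np.nan, p_value=np.nan,
                               metadata={"degenerate": True,
                                         "reason": "single outcome category"},
                               converged=False)
    endog = pd.Series(pd.Categorical(cats.astype(str), categories=levels,
                                     ordered=True))
    X = _design(arm, covariates).drop(columns=["const"])
    model = OrderedModel(endog, X, distr="logit")
    with np.errstate(all="ignore"):
        res = model.fit(method="bfgs", disp=0, maxiter=200)
    or_, lo, hi, p = _wald(res.params, res.bse, "arm", log_scale=True)
    return OutcomeEstimate(measure="odds_ratio", estimate=or_, ci_low=lo,
                           ci_high=hi, p_value=p,
                           covariates=list(covariates.columns) if covariates is not None else [],
                           metadata={"proportional_odds_tested": False},
                           converged=bool(res.mle_retvals.get("converged", True)))


def fit_linear_model(values, arm, covariates: pd.DataFrame | None = None
                     ) -> OutcomeEstimate:
    """Normal linear regression; mean difference (BFC - FSC) with Wald CI."""
    y = np.asarray(values, dtype=float)
    arm = encode_arm(pd.Series(np.asarray(arm)).reset_index(drop=True))
    X = _design(arm, covariates)
    res = sm.OLS(y, X).fit()
    diff, lo, hi, p = _wald(res.params, res.bse, "arm", log_scale=False)
    return OutcomeEstimate(measure="mean_difference", estimate=diff,
                           ci_low=lo, ci_high=hi, p_value=p,
                           arm_summary={"mean_bfc": float(y[arm == 1].mean()),
                                        "mean_fsc": float(y[arm == 0].mean())},
                           covariates=list(covariates.columns) if covariates is not None else [])


# ---------------------------------------------------------------------------
# sample size for two negative binomial rates
# ---------------------------------------------------------------------------

@dataclass
class SampleSizeSpec:
    base_rate: float          # mu0, events per person-year in the reference arm
    rate_reduction: float     # proportionate reduction in the treated arm
    alpha: float = 0.05       # two-sided level
    power: float = 0.90
    dispersion: float = 1.2   # NB2 dispersion k
    follow_up: float = 1.0    # years per patient

    def validate(self):
        if not (0 < self.rate_reduction < 1):
            raise ValueError("rate_reduction must be in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0.5 < self.power < 1):
            raise ValueError("power must be in (0.5, 1)")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.base_rate <= 0 or self.follow_up <= 0:
            raise ValueError("base_rate and follow_up must be positive")


def sample_size_nb(spec: SampleSizeSpec) -> int:
    """Per-group sample size for detecting a rate reduction between two
    negative binomial rates.

    Uses the log-rate-ratio Wald variance with per-arm contribution
    1/(mu t) + k:

        n = ceil[ (z_{1-a/2} + z_{1-b})^2 ((1/(mu0 t) + k) + (1/(mu1 t) + k))
                  / ln(mu1/mu0)^2 ],   mu1 = mu0 (1 - reduction).
    """
    spec.validate()
    mu0 = spec.base_rate
    mu1 = mu0 * (1 - spec.rate_reduction)
    t, k = spec.follow_up, spec.dispersion
    z = norm.ppf(1 - spec.alpha / 2) + norm.ppf(spec.power)
    n = z ** 2 * ((1 / (mu0 * t) + k) + (1 / (mu1 * t) + k)) / math.log(mu1 / mu0) ** 2
    return int(math.ceil(n))
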