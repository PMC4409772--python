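"""End-to-end study pipeline: simulate -> build cohort -> adjudicate ->
match -> analyze -> report.

All analyses are intent-to-treat (patients analyzed by initiated drug);
the per-protocol flavor exists only through the censor_at_switch follow-up
variant.  Outcome models follow the residual-imbalance covariate policy:
every variable still unbalanced after matching enters all models, together
with the analogous pre-index variable for the outcome at hand.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from copdce.adjudicate import adjudicate_cohort
from copdce.cohort import COVARIATE_DICTIONARY, CohortParams, FollowUpSpec, build_cohort
from copdce.data_model import ClaimsDatabase, default_codeset, read_claims
from copdce.matching import balance_table, estimate_propensity, match_1to1, unbalanced_variables
from copdce.models import (
    fit_binary_model,
    fit_linear_model,
    fit_ordinal_model,
    fit_rate_model,
    fit_time_to_event,
)
from copdce.simulate import SimulationConfig, generate

#: matching variables fixed a priori
PRESPECIFIED_VARIABLES = [
    "age", "female", "prior_asthma",
    "prior_copd_inpatient", "prior_copd_ed",
    "prior_ocs_fills", "prior_antibiotic_fills", "prior_saba_sama_fills",
    "prior_laba_fills", "prior_lama_fills",
]

#: additional balance variables reported (and used in the propensity model)
OPTIONAL_VARIABLES = [
    "pre_exacerbations", "pre_exac_any", "prior_pneumonia",
    "hypertension", "diabetes", "pvd", "cad", "depression_anxiety", "chf",
    "ltra_category", "long_stay", "region", "specialty", "index_month",
    "prior_ics_fills",
]

#: outcome -> analogous pre-index covariate
ANALOGOUS = {
    "exacerbation_rate": "pre_exacerbations",
    "exacerbation_inpatient": "prior_copd_inpatient",
    "exacerbation_ed": "prior_copd_ed",
    "exacerbation_outpatient_rx": "pre_exacerbations",
    "time_to_first_exacerbation": "pre_exacerbations",
    "pneumonia_any": "prior_pneumonia",
    "pneumonia_inpatient": "prior_pneumonia",
    "pneumonia_ed": "prior_pneumonia",
    "pneumonia_outpatient": "prior_pneumonia",
}


@dataclass
class StudyConfig:
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    data_dir: str | None = None          # read claims instead of simulating
    intake_window: tuple[int, int] | None = None
    prespecified: list[str] = field(default_factory=lambda: list(PRESPECIFIED_VARIABLES))
    optional: list[str] = field(default_factory=lambda: list(OPTIONAL_VARIABLES))
    variants: tuple = ("fixed_12mo", "censor_at_switch", "all_available", "severe_only")
    n_trees: int = 500
    min_samples_leaf: int = 25
    caliper_sd_logit: float | None = 0.2
    match_seed: int = 0
    cohort: CohortParams = field(default_factory=CohortParams)

    def validate(self) -> None:
        unknown = [v for v in self.prespecified + self.optional
                   if v not in COVARIATE_DICTIONARY]
        if unknown:
            raise ValueError(f"variables not in the covariate dictionary: {unknown}")
        if not set(PRESPECIFIED_VARIABLES) <= set(self.prespecified):
            missing = sorted(set(PRESPECIFIED_VARIABLES) - set(self.prespecified))
            raise ValueError(f"pre-specified matching variables missing: {missing}")


@dataclass
class RunResult:
    cohort: pd.DataFrame
    attrition: pd.DataFrame
    balance: pd.DataFrame
    pairs: pd.DataFrame
    outcomes: pd.DataFrame       # matched per-patient outcomes (fixed 12-month)
    estimates: pd.DataFrame
    km_curves: dict
    manifest: dict


def config_hash(config: StudyConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)
    return hashlib.sha256(json.dumps(dataclasses.asdict(config), default=enc,
                                     sort_keys=True).encode()).hexdigest()[:16]


def _estimate_row(outcome: str, est) -> dict:
    return dict(outcome=outcome, measure=est.measure, estimate=est.estimate,
                ci_low=est.ci_low, ci_high=est.ci_high, p_value=est.p_value,
                converged=est.converged,
                **{k: v for k, v in est.arm_summary.items()},
                covariates=",".join(est.covariates))


def crude_rate_ratio(outcomes: pd.DataFrame) -> float:
    """Unadjusted BFC/FSC ratio of event rates (events per person-year)."""
    g = outcomes.groupby("arm").apply(
        lambda d: d["n_events"].sum() / d["person_years"].sum(),
        include_groups=False)
    return float(g["BFC"] / g["FSC"])


def run(config: StudyConfig, out_dir: str | Path | None = None,
        db: ClaimsDatabase | None = None) -> RunResult:
    """Execute the full study; deterministic given config (all seeds live
    in the config)."""
    config.validate()
    codeset = default_codeset()

    if db is None:
        if config.data_dir is not None:
            db = read_claims(config.data_dir)
        else:
            db, _ = generate(config.sim)
    intake = config.intake_window or (config.sim.intake_start, config.sim.intake_end)

    result = build_cohort(db, intake, codeset, config.cohort)
    cohort = result.cohort

    ps_covs = config.prespecified + [v for v in config.optional
                                     if v not in config.prespecified]
    prop = estimate_propensity(cohort, ps_covs, n_trees=config.n_trees,
                               seed=config.sim.seed,
                               min_samples_leaf=config.min_samples_leaf)
    arms = cohort.set_index("patient_id")["index_drug"]
    match = match_1to1(prop.scores, arms, config.caliper_sd_logit,
                       seed=config.match_seed)
    balance = balance_table(cohort, match.pairs, ps_covs)
    unbalanced = unbalanced_variables(balance)

    matched_ids = pd.concat([match.pairs["bfc_patient_id"],
                             match.pairs["fsc_patient_id"]])
    matched = cohort.set_index("patient_id").loc[matched_ids].reset_index()

    estimates = []
    km_curves = {}
    outcomes_fixed = None
    for variant in config.variants:
        spec = FollowUpSpec(variant=variant, study_end=config.sim.study_end)
        _, outcomes = adjudicate_cohort(db, matched, spec, codeset)
        outcomes = outcomes.merge(matched, on=["patient_id", "index_date"])
        name = {"fixed_12mo": "exacerbation_rate",
                "censor_at_switch": "exacerbation_rate_censor_at_switch",
                "all_available": "exacerbation_rate_all_followup",
                "severe_only": "exacerbation_rate_severe"}[variant]
        covs = _model_covariates(outcomes, unbalanced, "exacerbation_rate")
        est = fit_rate_model(outcomes["n_events"], outcomes["arm"], covs,
                             outcomes["person_years"])
        estimates.append(_estimate_row(name, est))
        if variant == "fixed_12mo":
            outcomes_fixed = outcomes
    out = outcomes_fixed

    # by event type
    for t, name in (("n_inpatient", "exacerbation_inpatient"),
                    ("n_ed", "exacerbation_ed"),
                    ("n_outpatient_rx", "exacerbation_outpatient_rx")):
        covs = _model_covariates(out, unbalanced, name)
        est = fit_rate_model(out[t], out["arm"], covs, out["person_years"])
        estimates.append(_estimate_row(name, est))

    # time to first exacerbation
    covs = _model_covariates(out, unbalanced, "time_to_first_exacerbation")
    tte = out["time_to_first"].clip(lower=1)
    est, curves = fit_time_to_event(tte, out["event_observed"], out["arm"], covs)
    estimates.append(_estimate_row("time_to_first_exacerbation", est))
    km_curves["exacerbation"] = curves

    # pneumonia, three ways
    covs = _model_covariates(out, unbalanced, "pneumonia_any")
    est = fit_binary_model(out["pneumonia_any"], out["arm"], covs)
    estimates.append(_estimate_row("pneumonia_any", est))
    for place in ("inpatient", "ed", "outpatient"):
        col = f"pneumonia_{place}"
        if out[col].any():
            est = fit_binary_model(out[col], out["arm"],
                                   _model_covariates(out, unbalanced, col))
            estimates.append(_estimate_row(col, est))
    pneu_time = np.where(out["pneumonia_any"],
                         (out["pneumonia_first"].fillna(0) - out["index_date"]),
                         365).clip(min=1)
    est, curves = fit_time_to_event(pneu_time, out["pneumonia_any"], out["arm"],
                                    _model_covariates(out, unbalanced, "pneumonia_any"))
    estimates.append(_estimate_row("time_to_first_pneumonia", est))
    km_curves["pneumonia"] = curves

    # adherence and medication use
    covs = _model_covariates(out, unbalanced, "pdc")
    estimates.append(_estimate_row("pdc", fit_linear_model(out["pdc"], out["arm"], covs)))
    estimates.append(_estimate_row(
        "index_fill_distribution",
        fit_ordinal_model(out["fill_category"], out["arm"], covs)))
    for cls in ("lama", "saba", "ocs", "antibiotic"):
        estimates.append(_estimate_row(
            f"any_{cls}_fill",
            fit_binary_model(out[f"any_{cls}"], out["arm"],
                             _model_covariates(out, unbalanced, f"any_{cls}"))))

    estimates_df = pd.DataFrame(estimates)
    import copdce
    manifest = dict(package_version=copdce.__version__, seed=config.sim.seed,
                    match_seed=config.match_seed, config_hash=config_hash(config),
                    n_candidates=int(result.attrition.iloc[0]["n_remaining"]),
                    n_cohort=len(cohort), n_pairs=len(match.pairs),
                    unbalanced_after_matching=unbalanced)
    res = RunResult(cohort=cohort, attrition=result.attrition, balance=balance,
                    pairs=match.pairs, outcomes=out, estimates=estimates_df,
                    km_curves=km_curves, manifest=manifest)
    if out_dir is not None:
        _write_bundle(res, Path(out_dir))
    return res


def _model_covariates(outcomes: pd.DataFrame, unbalanced: list[str],
                      outcome_name: str) -> pd.DataFrame | None:
    cols = list(dict.fromkeys(unbalanced))
    analogous = ANALOGOUS.get(outcome_name)
    if analogous and analogous not in cols:
        cols.append(analogous)
    cols = [c for c in cols if c in outcomes.columns]
    if not cols:
        return None
    return outcomes[cols].reset_index(drop=True)


def _write_bundle(res: RunResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    res.attrition.to_csv(out_dir / "attrition.csv", index=False)
    res.balance.to_csv(out_dir / "balance.csv", index=False)
    res.pairs.to_csv(out_dir / "pairs.csv", index=False)
    res.estimates.to_csv(out_dir / "estimates.csv", index=False)
    res.outcomes.to_csv(out_dir / "outcomes.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(res.manifest, indent=2))
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        for ax, (name, curves) in zip(axes, res.km_curves.items()):
            for label, (t, s) in curves.items():
                ax.step(t, s, where="post", label=label)
            ax.set_title(f"Time to first {name}")
            ax.set_xlabel("days since index")
            ax.set_ylabel("event-free probability")
            ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "kaplan_meier.png", dpi=120)
        plt.close(fig)
    except Exception:
        pass
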