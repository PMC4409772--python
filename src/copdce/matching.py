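"""Random-forest propensity scores, greedy 1:1 matching, and covariate
balance diagnostics.

The propensity score is the estimated probability of receiving BFC given
baseline covariates, from a random-forest classifier.  Out-of-bag class
probabilities are used (avoiding in-bag overfitting) and clipped inside the
open unit interval.  Matching is greedy nearest-neighbor without
replacement on the logit of the score, processing BFC patients in a seeded
random order with an optional caliper (default 0.2 SD of the logit scores,
the dominant convention).  Balance is assessed variable-by-variable with
pooled-variance t-tests (continuous) or chi-square tests (categorical) plus
standardized mean differences; a variable is called balanced when p > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier


@dataclass
class PropensityResult:
    scores: pd.Series          # indexed by patient_id, open interval (0, 1)
    covariates: list[str]
    n_trees: int
    seed: int
    feature_names: list[str] = field(default_factory=list)


@dataclass
class MatchResult:
    pairs: pd.DataFrame        # bfc_patient_id, fsc_patient_id, distance
    unmatched_bfc: list
    unmatched_fsc: list
    caliper: float | None


def design_matrix(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix: passthrough numerics, one-hot categoricals
    with deterministic column order."""
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ValueError(f"covariates not in cohort: {missing}")
    parts = []
    for c in covariates:
        col = cohort[c]
        if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
            parts.append(col.astype(float).rename(c))
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=c)
            parts.append(dummies[sorted(dummies.columns)].astype(float))
    return pd.concat(parts, axis=1)


def estimate_propensity(cohort: pd.DataFrame, covariates: list[str],
                        n_trees: int = 500, seed: int = 0,
                        min_samples_leaf: int = 10) -> PropensityResult:
    """Out-of-bag P(BFC | covariates) from a random forest, clipped to
    [1/(2N), 1 - 1/(2N)].  Deterministic under a fixed seed."""
    arms = cohort["index_drug"] if "index_drug" in cohort.columns else cohort["arm"]
    y = arms.eq("BFC").to_numpy()
    if y.all() or not y.any():
        raise ValueError("propensity estimation needs patients in both arms")
    X = design_matrix(cohort, covariates)
    rf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                min_samples_leaf=min_samples_leaf,
                                random_state=seed, n_jobs=1)
    rf.fit(X.to_numpy(), y)
    probs = rf.oob_decision_function_[:, list(rf.classes_).index(True)]
    never_oob = ~np.isfinite(probs)
    if never_oob.any():
        probs[never_oob] = rf.predict_proba(X.to_numpy()[never_oob])[:, 1]
    n = len(y)
    probs = np.clip(probs, 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
    scores = pd.Series(probs, index=cohort["patient_id"].to_numpy(), name="propensity")
    return PropensityResult(scores=scores, covariates=list(covariates),
                            n_trees=n_trees, seed=seed,
                            feature_names=list(X.columns))


def match_1to1(scores: pd.Series, arms: pd.Series,
               caliper_sd_logit: float | None = 0.2, seed: int = 0) -> MatchResult:
    """Greedy nearest-neighbor 1:1 matching without replacement on
    logit(score).

    BFC patients are processed in a seeded random order; each takes the
    closest still-available FSC patient (ties between the nearest lower and
    higher score broken toward the lower patient id), subject to the
    caliper when one is set.
    """
    arms = arms.reindex(scores.index)
    logit = np.log(scores / (1 - scores))
    caliper = None
    if caliper_sd_logit is not None:
        caliper = caliper_sd_logit * float(np.std(logit, ddof=1)) if len(logit) > 1 else 0.0
    is_bfc = arms.eq("BFC").to_numpy()
    ids = scores.index.to_numpy()
    lg = logit.to_numpy()
    bfc_ids, bfc_lg = ids[is_bfc], lg[is_bfc]
    fsc_ids, fsc_lg = ids[~is_bfc], lg[~is_bfc]
    # sort FSC by (logit, id) so neighbor scans are deterministic
    order = np.lexsort((fsc_ids, fsc_lg))
    fsc_ids, fsc_lg = fsc_ids[order], fsc_lg[order]
    m = len(fsc_ids)
    alive = np.ones(m, dtype=bool)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(bfc_ids))
    pairs = []
    unmatched_bfc = []
    remaining = m
    for bi in perm:
        pid, x = bfc_ids[bi], bfc_lg[bi]
        if remaining == 0:
            unmatched_bfc.append(pid)
            continue
        j = int(np.searchsorted(fsc_lg, x))
        right = j
        while right < m and not alive[right]:
            right += 1
        left = j - 1
        while left >= 0 and not alive[left]:
            left -= 1
        dl = x - fsc_lg[left] if left >= 0 else np.inf
        dr = fsc_lg[right] - x if right < m else np.inf
        tied = (np.isfinite(dl) and np.isfinite(dr)
                and abs(dl - dr) <= 1e-12 * max(1.0, abs(dl)))
        if tied:
            best = left if fsc_ids[left] < fsc_ids[right] else right
            dist = min(dl, dr)
        elif dl < dr:
            best, dist = left, dl
        elif dr < dl:
            best, dist = right, dr
        else:
            unmatched_bfc.append(pid)
            continue
        if caliper is not None and dist > caliper:
            unmatched_bfc.append(pid)
            continue
        pairs.append((pid, fsc_ids[best], float(dist)))
        alive[best] = False
        remaining -= 1
    unmatched_fsc = list(fsc_ids[alive])
    pairs_df = pd.DataFrame(pairs, columns=["bfc_patient_id", "fsc_patient_id",
                                            "distance"])
    return MatchResult(pairs=pairs_df, unmatched_bfc=unmatched_bfc,
                       unmatched_fsc=unmatched_fsc, caliper=caliper)


def standardized_mean_difference(x1: np.ndarray, x0: np.ndarray) -> float:
    m1, m0 = np.mean(x1), np.mean(x0)
    v1, v0 = np.var(x1, ddof=1) if len(x1) > 1 else 0.0, \
        np.var(x0, ddof=1) if len(x0) > 1 else 0.0
    denom = np.sqrt((v1 + v0) / 2)
    if denom == 0:
        return 0.0
    return float((m1 - m0) / denom)


def _test_variable(col: pd.Series, is_bfc: pd.Series) -> tuple[float, float, float, float]:
    """(mean_bfc, mean_fsc, p, smd) for one variable on one sample."""
    x1 = col[is_bfc]
    x0 = col[~is_bfc]
    if pd.api.types.is_numeric_dtype(col) or pd.api.types.is_bool_dtype(col):
        a1 = x1.astype(float).to_numpy()
        a0 = x0.astype(float).to_numpy()
        if np.var(a1) == 0 and np.var(a0) == 0 and np.mean(a1) == np.mean(a0):
            return float(np.mean(a1)), float(np.mean(a0)), 1.0, 0.0
        _, p = stats.ttest_ind(a1, a0, equal_var=True)
        return float(np.mean(a1)), float(np.mean(a0)), float(p), \
            standardized_mean_difference(a1, a0)
    # categorical: chi-square on the levels x arm table, SMD = max level-wise
    levels = sorted(col.astype(str).unique())
    t1 = x1.astype(str).value_counts().reindex(levels, fill_value=0)
    t0 = x0.astype(str).value_counts().reindex(levels, fill_value=0)
    table = np.array([t1.to_numpy(), t0.to_numpy()])
    if len(levels) < 2 or table.sum(axis=0).min() == 0:
        return np.nan, np.nan, 1.0, 0.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    smds = [abs(standardized_mean_difference(
        x1.astype(str).eq(lv).astype(float).to_numpy(),
        x0.astype(str).eq(lv).astype(float).to_numpy())) for lv in levels]
    return np.nan, np.nan, float(p), float(max(smds))


def balance_table(cohort: pd.DataFrame, pairs: pd.DataFrame,
                  variables: list[str], alpha: float = 0.05) -> pd.DataFrame:
    """Pre- vs post-match balance for each variable.

    Post-match uses the matched sample (both members of every pair).  A
    variable with zero variance in both arms is reported balanced with
    p = 1.  The ``balanced_post`` column flags p > alpha; unbalanced
    variables are forwarded as outcome-model covariates.
    """
    arm_col = "index_drug" if "index_drug" in cohort.columns else "arm"
    idx = cohort.set_index("patient_id")
    matched_ids = pd.concat([pairs["bfc_patient_id"], pairs["fsc_patient_id"]])
    matched = idx.loc[matched_ids]
    rows = []
    for v in variables:
        pre_m1, pre_m0, pre_p, pre_smd = _test_variable(idx[v], idx[arm_col].eq("BFC"))
        post_m1, post_m0, post_p, post_smd = _test_variable(
            matched[v], matched[arm_col].eq("BFC"))
        rows.append(dict(variable=v,
                         pre_mean_bfc=pre_m1, pre_mean_fsc=pre_m0,
                         pre_p=pre_p, pre_smd=pre_smd,
                         post_mean_bfc=post_m1, post_mean_fsc=post_m0,
                         post_p=post_p, post_smd=post_smd,
                         balanced_post=post_p > alpha))
    return pd.DataFrame(rows)


def unbalanced_variables(balance: pd.DataFrame) -> list[str]:
    return balance.loc[~balance["balanced_post"], "variable"].tolist()
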