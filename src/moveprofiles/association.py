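"""Profile-mortality association: age-as-timescale Cox models and diagnostics.

The time axis is attained age: participants enter the risk set at their entry
age (left truncation / delayed entry) and exit at the age of death or
censoring.  Profile membership enters as indicator variables against a
reference profile, with three sequential adjustment levels:

1. sociodemographic factors (sex, ethnicity, marital status, education,
   occupational position) — age is handled by the timescale;
2. additionally lifestyle factors (smoking, alcohol, fruit & vegetable
   consumption);
3. additionally health-related factors (obesity, hypertension,
   hyperlipidaemia, diabetes, morbidity count).

Partial-likelihood fitting (Efron ties) is delegated to lifelines; the global
proportional-hazards test is the Grambsch-Therneau scaled-Schoenfeld
chi-square with a rank time transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats

from .cohort import HEALTH, LIFESTYLE, SOCIODEMOGRAPHIC

MODEL_COVARIATES = {
    1: SOCIODEMOGRAPHIC,
    2: SOCIODEMOGRAPHIC + LIFESTYLE,
    3: SOCIODEMOGRAPHIC + LIFESTYLE + HEALTH,
}


@dataclass
class CoxResult:
    model_level: int
    reference: str
    hr: pd.DataFrame  # index = profile, columns HR / lo / hi / p
    n: int
    n_events: int
    unstable: bool
    schoenfeld_global_p: float | None = None
    fitter: CoxPHFitter | None = field(default=None, repr=False)
    design: pd.DataFrame | None = field(default=None, repr=False)


def _design(records: pd.DataFrame, model_level: int, reference: str) -> tuple[pd.DataFrame, list[str]]:
    profiles = sorted(records["profile"].unique())
    if reference not in profiles:
        raise ValueError(f"reference profile {reference!r} not present")
    others = [p for p in profiles if p != reference]
    df = pd.DataFrame(index=records.index)
    for p in others:
        df[f"profile_{p}"] = (records["profile"] == p).astype(float)
    for c in MODEL_COVARIATES[model_level]:
        df[c] = records[c].astype(float)
    df["entry_age_years"] = records["entry_age_years"].astype(float)
    df["event_age_years"] = records["event_age_years"].astype(float)
    df["event_flag"] = records["event_flag"].astype(int)
    return df, others


def cox_fit(
    records: pd.DataFrame,
    model_level: int = 3,
    reference: str = "active",
) -> CoxResult:
    """Left-truncated Cox fit of profile indicators plus covariate blocks.

    ``records`` needs columns profile, entry_age_years, event_age_years,
    event_flag and the covariates of the requested adjustment level.  Hazard
    ratios are exponentiated coefficients with Wald 95% CIs.
    """
    if records["profile"].nunique() < 2:
        raise ValueError("need at least 2 profiles")
    df, others = _design(records, model_level, reference)
    n_events = int(df["event_flag"].sum())
    if n_events <= df.shape[1] - 3:
        raise ValueError("fewer events than parameters")
    unstable = any(
        records.loc[records["profile"] == p, "event_flag"].sum() == 0 for p in others
    )
    if unstable:
        warnings.warn("profile with zero events: estimates unstable")
    cph = CoxPHFitter()
    cph.fit(
        df,
        duration_col="event_age_years",
        event_col="event_flag",
        entry_col="entry_age_years",
    )
    summ = cph.summary
    rows = {}
    for p in others:
        r = summ.loc[f"profile_{p}"]
        rows[p] = {
            "HR": float(np.exp(r["coef"])),
            "lo": float(np.exp(r["coef lower 95%"])),
            "hi": float(np.exp(r["coef upper 95%"])),
            "p": float(r["p"]),
        }
    rows[reference] = {"HR": 1.0, "lo": np.nan, "hi": np.nan, "p": np.nan}
    hr = pd.DataFrame.from_dict(rows, orient="index").loc[[reference] + others]
    return CoxResult(
        model_level=model_level,
        reference=reference,
        hr=hr,
        n=len(df),
        n_events=n_events,
        unstable=unstable,
        fitter=cph,
        design=df,
    )


def _schoenfeld_residuals(
    X: np.ndarray, entry: np.ndarray, exit_t: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Schoenfeld residuals x_k - xbar(t_k) under delayed entry.

    The risk set at event time t contains everyone with entry < t <= exit,
    weighted by exp(x beta).  Returns (event_times, residual matrix), sorted
    by event time.
    """
    w = np.exp(X @ beta)
    times = exit_t[event]
    order = np.argsort(times, kind="stable")
    times = times[order]
    Xev = X[event][order]
    resid = np.empty_like(Xev)
    for i, t in enumerate(times):
        at_risk = (entry < t) & (exit_t >= t)
        wr = w[at_risk]
        resid[i] = Xev[i] - wr @ X[at_risk] / wr.sum()
    return times, resid


def schoenfeld_test(result: CoxResult) -> tuple[float, pd.Series]:
    """Grambsch-Therneau proportional-hazards test (rank time transform).

    Returns ``(global_p, per_covariate_p)``.  The statistic correlates the
    Schoenfeld residuals with the rank of the event (age) time; the global
    version is the joint chi-square over all coefficients.
    """
    cph, df = result.fitter, result.design
    if cph is None or df is None:
        raise ValueError("CoxResult does not carry its fitter")
    if result.n_events < 2:
        raise ValueError("too few events for a proportionality test")
    covar_cols = [c for c in df.columns if c not in ("entry_age_years", "event_age_years", "event_flag")]
    X = df[covar_cols].to_numpy(float)
    times, R = _schoenfeld_residuals(
        X,
        df["entry_age_years"].to_numpy(float),
        df["event_age_years"].to_numpy(float),
        df["event_flag"].to_numpy() == 1,
        cph.params_[covar_cols].to_numpy(float),
    )
    gt = stats.rankdata(times)
    gt = gt - gt.mean()
    d = R.shape[0]
    V = cph.variance_matrix_.loc[covar_cols, covar_cols].to_numpy()
    u = d * (gt @ R) @ V  # sum of g~ * scaled residuals
    denom = float(gt @ gt)
    per_chi2 = u**2 / (d * np.diag(V) * denom)
    per_p = pd.Series(stats.chi2.sf(per_chi2, 1), index=covar_cols)
    global_chi2 = float(u @ np.linalg.solve(V, u)) / (d * denom)
    global_p = float(stats.chi2.sf(global_chi2, R.shape[1]))
    return global_p, per_p


def reference_rotation(records: pd.DataFrame, model_level: int = 3) -> pd.DataFrame:
    """k x k matrix of fully adjusted HRs, each profile as reference once.

    Entry (i, j) is the hazard of profile i versus reference profile j;
    the diagonal is 1 and HR[i][j] = 1 / HR[j][i] up to numerical error.
    """
    profiles = sorted(records["profile"].unique())
    mat = pd.DataFrame(np.ones((len(profiles), len(profiles))), index=profiles, columns=profiles)
    for ref in profiles:
        res = cox_fit(records, model_level=model_level, reference=ref)
        for p in profiles:
            if p != ref:
                mat.loc[p, ref] = res.hr.loc[p, "HR"]
    return mat


def interaction_tests(
    records: pd.DataFrame,
    modifiers: dict[str, pd.Series] | None = None,
    model_level: int = 3,
    reference: str = "active",
) -> pd.Series:
    """Likelihood-ratio tests of profile x modifier interaction terms.

    Default modifiers: age at entry (continuous), sex, obesity and morbidity
    (any vs none), each added — main effect plus interactions with the profile
    indicators — to the fully adjusted model.
    """
    if modifiers is None:
        modifiers = {
            "age": records["entry_age_years"].astype(float),
            "sex": records["female"].astype(float),
            "obesity": records["obese"].astype(float),
            "morbidity": (records["morbidity_count"] > 0).astype(float),
        }
    base_df, others = _design(records, model_level, reference)
    pvals = {}
    for name, mod in modifiers.items():
        df0 = base_df.copy()
        mvals = mod.loc[records.index].to_numpy(float)
        if name == "age":
            mvals = mvals - mvals.mean()  # centred; age level is absorbed by the timescale
        covar_cols = [
            c for c in df0.columns if c not in ("entry_age_years", "event_age_years", "event_flag")
        ]
        # add the modifier main effect unless it already is an adjustment
        # covariate (e.g. sex in model 1+, obesity in model 3)
        if not any(np.array_equal(mvals, df0[c].to_numpy(float)) for c in covar_cols):
            df0[f"mod_{name}"] = mvals
        df1 = df0.copy()
        cells_ok = True
        for p in others:
            col = df1[f"profile_{p}"].to_numpy() * mvals
            if np.allclose(col.std(), 0):
                cells_ok = False
                continue
            df1[f"profile_{p}:{name}"] = col
        if not cells_ok:
            warnings.warn(f"sparse cells for modifier {name}")
        kwargs = dict(
            duration_col="event_age_years", event_col="event_flag", entry_col="entry_age_years"
        )
        c0, c1 = CoxPHFitter(), CoxPHFitter()
        c0.fit(df0, **kwargs)
        c1.fit(df1, **kwargs)
        lr = 2.0 * (c1.log_likelihood_ - c0.log_likelihood_)
        dof = df1.shape[1] - df0.shape[1]
        pvals[name] = float(stats.chi2.sf(max(lr, 0.0), dof))
    return pd.Series(pvals)


def sensitivity_exclude_early(
    records: pd.DataFrame,
    window_years: float = 2.0,
    model_level: int = 3,
    reference: str = "active",
) -> tuple[CoxResult, int]:
    """Refit after excluding deaths within the first ``window_years`` of follow-up.

    Censored participants are retained.  Returns the refit and the number of
    excluded early deaths.
    """
    fu = records["event_age_years"] - records["entry_age_years"]
    early = (records["event_flag"] == 1) & (fu < window_years)
    kept = records.loc[~early]
    return cox_fit(kept, model_level=model_level, reference=reference), int(early.sum())


def anova_tukey(
    features: pd.DataFrame, assignments: pd.Series, alpha: float = 0.05
) -> tuple[pd.Series, dict[str, pd.DataFrame]]:
    """Per-feature one-way ANOVA across profiles, Tukey HSD when significant.

    Returns ``(anova_p, tukey)`` where ``tukey`` maps feature name to the
    pairwise Tukey HSD table (only for features with ANOVA p < alpha).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = assignments.loc[features.index]
    labels = sorted(groups.unique())
    if len(labels) < 2:
        raise ValueError("need at least 2 profiles")
    anova_p = {}
    tukey: dict[str, pd.DataFrame] = {}
    for col in features.columns:
        samples = [features.loc[groups == g, col].dropna() for g in labels]
        if any(len(s) < 2 for s in samples):
            warnings.warn(f"singleton profile: skipping {col}")
            continue
        f, p = stats.f_oneway(*samples)
        anova_p[col] = float(p)
        if p < alpha:
            keep = features[col].notna()
            t = pairwise_tukeyhsd(features.loc[keep, col], groups.loc[keep], alpha=alpha)
            tukey[col] = pd.DataFrame(
                t.summary().data[1:], columns=t.summary().data[0]
            )
    return pd.Series(anova_p), tukey
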