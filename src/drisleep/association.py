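"""Mixed-effects association between the nightly index and clinical scores.

For each clinical assessment, nightly DRI-SI-AD scores over the preceding
half-open 90-day window are summarized by their mean and sample variance
(windows with < 15 scored days are dropped, matching the window-profile
rule). Per scale, the repeated-measures model

    SCORE_ij = b0 + b1 * mean(DRI)_ij + b2 * var(DRI)_ij
               + b4 * AGE_ij + b5 * SEX_ij + u_i + e_ij

is fitted by REML with a participant random intercept u_i (statsmodels
MixedLM). Coefficients are named b0/b1/b2/b4/b5 (b3 unused). Sex is coded
0/1 (reference 0); age is in years, uncentered.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

WINDOW_DAYS = 90
MIN_DAYS = 15


def window_aggregate_dri(nightly_scores: pd.DataFrame, assessments: pd.DataFrame,
                         demographics: pd.DataFrame | None = None,
                         window_days: int = WINDOW_DAYS,
                         min_days: int = MIN_DAYS) -> pd.DataFrame:
    """Association rows: per (participant, assessment) window mean/variance.

    ``nightly_scores``: participant_id, night_date, dri_si_score.
    ``assessments``: participant_id, assessment_date, scale, score.
    ``demographics`` (optional): participant_id, age, sex — merged in.
    """
    scores = nightly_scores.copy()
    scores["night_date"] = pd.to_datetime(scores["night_date"]).dt.date
    by_pid = dict(tuple(scores.groupby("participant_id")))
    rows = []
    assess = assessments.copy()
    assess["assessment_date"] = pd.to_datetime(assess["assessment_date"]).dt.date
    for (pid, date), sub in assess.groupby(["participant_id", "assessment_date"]):
        s = by_pid.get(pid)
        if s is None:
            continue
        lo = date - dt.timedelta(days=window_days)
        win = s[(s["night_date"] >= lo) & (s["night_date"] < date)]
        if win["night_date"].nunique() < min_days:
            continue
        v = win["dri_si_score"].to_numpy(float)
        for _, r in sub.iterrows():
            rows.append(
                {"participant_id": pid, "assessment_date": date,
                 "scale": r["scale"], "score": float(r["score"]),
                 "dri_mean": float(v.mean()),
                 "dri_var": float(v.var(ddof=1)) if len(v) > 1 else 0.0}
            )
    out = pd.DataFrame(rows, columns=["participant_id", "assessment_date",
                                      "scale", "score", "dri_mean", "dri_var"])
    if demographics is not None and not out.empty:
        out = out.merge(demographics[["participant_id", "age", "sex"]],
                        on="participant_id", how="left")
    return out


@dataclass(frozen=True)
class MixedModelResult:
    scale: str
    coefficients: dict  # name -> (estimate, se, z, p)
    random_intercept_var: float
    residual_var: float
    n_obs: int
    n_participants: int
    converged: bool
    boundary_flag: bool  # random-intercept variance estimated near zero

    def beta(self, name: str) -> float:
        return self.coefficients[name][0]


_COEF_NAMES = {"Intercept": "b0", "dri_mean": "b1", "dri_var": "b2",
               "age": "b4", "sex": "b5"}


def fit_mixed_model(rows: pd.DataFrame, scale: str,
                    fix_re_zero: bool = False) -> MixedModelResult:
    """REML fit of the per-scale mixed model with participant random intercept.

    ``fix_re_zero=True`` pins the random-intercept variance at zero; in that
    limit the marginal covariance is spherical and the model reduces exactly
    to ordinary least squares, which is what this branch computes.
    A random-intercept variance estimated at (or squeezed against) zero is
    flagged via ``boundary_flag``.
    """
    d = rows[rows["scale"] == scale].dropna(
        subset=["score", "dri_mean", "dri_var", "age", "sex"]).copy()
    if len(d) < 20 or d["participant_id"].nunique() < 10:
        raise ValueError("need >= 20 rows over >= 10 participants")
    formula = "score ~ dri_mean + dri_var + age + sex"
    if fix_re_zero:
        fit = smf.ols(formula, data=d).fit()
        re_var = 0.0
        resid_var = float(fit.mse_resid)
        converged = True
    else:
        fit = smf.mixedlm(formula, data=d, groups=d["participant_id"]).fit(reml=True)
        re_var = float(np.asarray(fit.cov_re)[0, 0])
        resid_var = float(fit.scale)
        converged = bool(fit.converged)
    coefs = {}
    for raw, short in _COEF_NAMES.items():
        est = float(fit.params[raw])
        se = float(fit.bse[raw])
        z = est / se if se > 0 else np.nan
        coefs[short] = (est, se, float(z), float(fit.pvalues[raw]))
    return MixedModelResult(
        scale=scale, coefficients=coefs,
        random_intercept_var=re_var,
        residual_var=resid_var,
        n_obs=len(d), n_participants=int(d["participant_id"].nunique()),
        converged=converged,
        boundary_flag=re_var < 1e-6 * resid_var,
    )
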