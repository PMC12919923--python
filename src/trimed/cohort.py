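"""Cohort arm: trait transformations and direct risk-factor models.

The individual-level table ("CohortTable") is a pandas DataFrame with one row
per participant: identifier, age, sex, center, education, smoking and alcohol
status, a BMI-like exposure, named mediator columns, follow-up time in years,
an event indicator and (optionally) a matched-set label.

Models: linear a-path regressions of each mediator on the per-SD exposure,
Cox proportional-hazards models (Efron ties, follow-up time as the timescale)
for risk, and conditional logistic regression for matched nested case-control
sets.  All models use the same adjustment set (age, sex, center, education,
smoking, alcohol) unless told otherwise, and record it as provenance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
import statsmodels.api as sm
from statsmodels.discrete.conditional_models import ConditionalLogit

from trimed.errors import DataError, EstimationError

logger = logging.getLogger(__name__)

#: default adjustment set used in every cohort-arm model
DEFAULT_COVARIATES = ("age", "sex", "center", "education", "smoking", "alcohol")

#: columns that are treated as categorical when building design matrices
CATEGORICAL_COVARIATES = {"center", "education", "smoking", "alcohol"}


@dataclass
class EffectEstimate:
    """A single coefficient with its scale and adjustment provenance."""

    term: str
    beta: float
    se: float
    p: float
    scale: str  # linear | log_hazard | log_odds
    per_sd: bool = True
    adjustment: tuple[str, ...] = ()
    n: int = 0
    n_events: int = 0
    note: str = ""

    @property
    def ci(self) -> tuple[float, float]:
        z = stats.norm.ppf(0.975)
        return self.beta - z * self.se, self.beta + z * self.se

    @property
    def identified(self) -> bool:
        return np.isfinite(self.beta) and np.isfinite(self.se)


def transform_trait(values, method: str, blom_c: float = 3.0 / 8.0) -> np.ndarray:
    """Transform a trait: log, inverse_normal_rank, zscore or per_sd.

    ``inverse_normal_rank`` maps average ranks r to normal quantiles of
    (r - c)/(n + 1 - 2c) with the Blom offset c = 3/8 by default; ``per_sd``
    divides by the sample standard deviation without centering.
    """
    v = np.asarray(values, dtype=float)
    if method == "log":
        if np.any(v <= 0):
            raise DataError("transform_trait: log requires strictly positive values")
        return np.log(v)
    if method == "zscore":
        sd = v.std(ddof=1)
        if sd == 0:
            raise DataError("transform_trait: zero variance")
        return (v - v.mean()) / sd
    if method == "per_sd":
        sd = v.std(ddof=1)
        if sd == 0:
            raise DataError("transform_trait: zero variance")
        return v / sd
    if method == "inverse_normal_rank":
        r = stats.rankdata(v, method="average")
        n = len(v)
        return stats.norm.ppf((r - blom_c) / (n + 1 - 2 * blom_c))
    raise ValueError(f"unknown transform {method!r}")


def impute_below_lod(values, lod: float) -> tuple[np.ndarray, int]:
    """Replace values strictly below the detection limit with LOD/sqrt(2).

    Returns the imputed array and the number of replacements.
    """
    if lod <= 0:
        raise DataError("impute_below_lod: lod must be positive")
    v = np.asarray(values, dtype=float).copy()
    below = v < lod
    v[below] = lod / np.sqrt(2.0)
    n = int(below.sum())
    if n:
        logger.info("impute_below_lod: replaced %d values below %g", n, lod)
    return v, n


def _design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Build a numeric design frame, dummy-coding categorical covariates."""
    cols = []
    for cov in covariates:
        if cov not in df.columns:
            raise DataError(f"covariate {cov!r} missing from cohort table")
        if cov in CATEGORICAL_COVARIATES or df[cov].dtype == object:
            dummies = pd.get_dummies(df[cov], prefix=cov, drop_first=True, dtype=float)
            cols.append(dummies)
        else:
            cols.append(df[[cov]].astype(float))
    if not cols:
        return pd.DataFrame(index=df.index)
    return pd.concat(cols, axis=1)


def _check_collinear(x: pd.DataFrame) -> None:
    if x.shape[1] == 0:
        return
    mat = np.column_stack([np.ones(len(x)), x.to_numpy(float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        raise EstimationError(f"collinear covariates in design: columns {list(x.columns)}")


def apath_linear(
    cohort: pd.DataFrame,
    mediator: str,
    covariates=DEFAULT_COVARIATES,
    exposure: str = "bmi",
) -> EffectEstimate:
    """a-path: linear regression of a (pre-transformed) mediator on per-SD exposure."""
    df = cohort.dropna(subset=[mediator, exposure, *covariates])
    if len(df) < len(cohort):
        logger.info("apath_linear: complete-case analysis dropped %d rows", len(cohort) - len(df))
    x_sd = df[exposure].std(ddof=1)
    if x_sd == 0:
        raise DataError("apath_linear: exposure has zero variance")
    design = _design(df, covariates)
    _check_collinear(design)
    xmat = sm.add_constant(
        pd.concat([df[[exposure]] / x_sd, design], axis=1), has_constant="add"
    )
    fit = sm.OLS(df[mediator].astype(float), xmat.astype(float)).fit()
    return EffectEstimate(
        term=f"{exposure}->{mediator}",
        beta=float(fit.params[exposure]),
        se=float(fit.bse[exposure]),
        p=float(2 * stats.norm.sf(abs(fit.params[exposure] / fit.bse[exposure]))),
        scale="linear",
        per_sd=True,
        adjustment=tuple(covariates),
        n=int(fit.nobs),
    )


def cox_risk(
    cohort: pd.DataFrame,
    term: str,
    covariates=DEFAULT_COVARIATES,
    extra_adjust: str | None = None,
    time_col: str = "followup_time",
    event_col: str = "event",
) -> EffectEstimate:
    """b-path / total effect: Cox log-hazard per SD of ``term``.

    Follow-up time is the underlying timescale; ties use the Efron
    approximation (lifelines default).  ``extra_adjust`` adds one more per-SD
    continuous covariate (the mediation b-path is additionally adjusted for
    the exposure this way).  The proportional-hazards assumption is the
    caller's contract; it holds by construction for the exponential simulator.
    """
    needed = [term, time_col, event_col, *covariates]
    if extra_adjust:
        needed.append(extra_adjust)
    df = cohort.dropna(subset=needed)
    if (df[time_col] <= 0).any():
        raise DataError("cox_risk: non-positive follow-up times")
    n_events = int(df[event_col].sum())
    if n_events == 0:
        raise EstimationError("cox_risk: no events")
    parts = [pd.Series(df[term] / df[term].std(ddof=1), name=term)]
    if extra_adjust:
        parts.append(pd.Series(df[extra_adjust] / df[extra_adjust].std(ddof=1), name=extra_adjust))
    design = _design(df, covariates)
    _check_collinear(pd.concat(parts + [design], axis=1))
    fit_df = pd.concat(
        parts + [design, df[[time_col, event_col]].astype(float)], axis=1
    )
    cph = CoxPHFitter()
    cph.fit(fit_df, duration_col=time_col, event_col=event_col)
    beta = float(cph.params_[term])
    se = float(cph.standard_errors_[term])
    adjustment = tuple(covariates) + ((extra_adjust,) if extra_adjust else ())
    return EffectEstimate(
        term=term,
        beta=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(beta / se))),
        scale="log_hazard",
        per_sd=True,
        adjustment=adjustment,
        n=len(df),
        n_events=n_events,
    )


def conditional_logistic(
    cohort: pd.DataFrame,
    term: str,
    covariates=(),
    set_col: str = "matched_set",
    event_col: str = "event",
    per_sd: bool = True,
) -> EffectEstimate:
    """Matched-set analysis: conditional-likelihood log-odds per SD (or unit).

    Sets without within-set variation in ``term`` contribute nothing to the
    conditional likelihood; if no set is informative the estimate is
    non-identified and returned with NaN coefficients and an explanatory note.
    """
    df = cohort.dropna(subset=[term, set_col, event_col, *covariates]).copy()
    sizes = df.groupby(set_col)[event_col].agg(["sum", "count"])
    bad = sizes[(sizes["sum"] != 1) | (sizes["count"] < 2)]
    if len(bad):
        raise DataError(
            f"conditional_logistic: {len(bad)} matched sets without exactly one case and >=1 control"
        )
    sd = df[term].std(ddof=1) if per_sd else 1.0
    if sd == 0:
        raise DataError("conditional_logistic: term has zero variance")
    informative = df.groupby(set_col)[term].transform("nunique") > 1
    if not informative.any():
        logger.warning("conditional_logistic: no within-set variation; non-identified")
        return EffectEstimate(
            term=term,
            beta=np.nan,
            se=np.nan,
            p=np.nan,
            scale="log_odds",
            per_sd=per_sd,
            adjustment=tuple(covariates),
            n=len(df),
            n_events=int(df[event_col].sum()),
            note="non-identified: no within-set exposure variation",
        )
    xmat = pd.concat([df[[term]] / sd, _design(df, covariates)], axis=1).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ConditionalLogit(df[event_col].to_numpy(float), xmat, groups=df[set_col])
        fit = model.fit(disp=False, method="newton")
    beta = float(fit.params.iloc[0])
    se = float(fit.bse.iloc[0])
    return EffectEstimate(
        term=term,
        beta=beta,
        se=se,
        p=float(2 * stats.norm.sf(abs(beta / se))),
        scale="log_odds",
        per_sd=per_sd,
        adjustment=tuple(covariates),
        n=len(df),
        n_events=int(df[event_col].sum()),
    )
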