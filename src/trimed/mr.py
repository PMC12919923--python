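"""Two-sample Mendelian randomization estimators and sensitivity machinery.

Implements the Wald ratio, fixed/multiplicative-random IVW, MR-Egger,
Cochran's Q, the MR-PRESSO global/outlier test, Steiger directionality
filtering and multivariable MR with Sanderson-Windmeijer-style conditional F
statistics.  All estimators consume a :class:`~trimed.sumstats.HarmonizedSet`
and all p-values are two-sided normal, matching large-sample summary-data
practice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trimed.errors import DataError, EstimationError
from trimed.sumstats import HarmonizedSet

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)

#: conventional weak-instrument threshold for (conditional) F statistics
WEAK_F_THRESHOLD = 10.0


@dataclass
class MREstimate:
    """A single MR effect estimate on the outcome's analysis scale (log-OR here)."""

    method: str
    beta: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    n_variants: int
    q_statistic: float = np.nan
    q_p: float = np.nan
    exposure: str = "exposure"
    outcome: str = "outcome"
    conditional_f: float = np.nan
    weak_instruments: bool = False

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


def _estimate(method, beta, se, n_variants, q=np.nan, q_p=np.nan, **kw) -> MREstimate:
    beta, se = float(beta), float(se)
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else np.nan
    return MREstimate(
        method=method,
        beta=beta,
        se=se,
        p=p,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        n_variants=int(n_variants),
        q_statistic=float(q),
        q_p=float(q_p),
        **kw,
    )


def wald_ratio(
    beta_x: float,
    se_x: float,
    beta_y: float,
    se_y: float,
    second_order: bool = False,
) -> MREstimate:
    """Single-variant causal estimate: beta_y / beta_x.

    First-order se is |se_y / beta_x|; ``second_order`` adds the propagation of
    the exposure-beta uncertainty, sqrt(se_y^2/beta_x^2 + beta_y^2 se_x^2 / beta_x^4).
    """
    if beta_x == 0:
        raise EstimationError("wald_ratio: beta_x must be nonzero")
    beta = beta_y / beta_x
    if second_order:
        se = np.sqrt(se_y**2 / beta_x**2 + (beta_y**2 * se_x**2) / beta_x**4)
    else:
        se = abs(se_y / beta_x)
    return _estimate("wald", beta, se, 1)


def ivw(h: HarmonizedSet, model: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate over the harmonized instruments.

    Equivalent to weighted least squares of beta_outcome on beta_exposure
    through the origin with weights 1/se_outcome^2.  With the multiplicative
    random-effects model (the default) the standard error is inflated by
    sqrt(max(1, Q/(J-1))); ``model="fixed"`` reports the fixed-effect se.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW model {model!r}")
    j = len(h)
    if j == 0:
        raise DataError("ivw: empty harmonized set")
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    if j == 1:
        warnings.warn("ivw: single variant, degrading to Wald ratio", stacklevel=2)
        est = wald_ratio(bx[0], h.se_exposure[0], by[0], sy[0])
        return _estimate("ivw_" + ("fixed" if model == "fixed" else "random"),
                         est.beta, est.se, 1, q=0.0, q_p=np.nan,
                         exposure=h.exposure_names[0], outcome=h.outcome_name)
    w = bx**2 / sy**2
    ratios = by / bx
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    q = float(np.sum(w * (ratios - beta) ** 2))
    q_p = float(stats.chi2.sf(q, j - 1))
    if model == "fixed":
        se = se_fixed
        name = "ivw_fixed"
    else:
        se = se_fixed * max(1.0, np.sqrt(q / (j - 1)))
        name = "ivw_random"
    return _estimate(name, beta, se, j, q=q, q_p=q_p,
                     exposure=h.exposure_names[0], outcome=h.outcome_name)


def egger(h: HarmonizedSet) -> tuple[MREstimate, MREstimate]:
    """MR-Egger slope and intercept (the unbalanced-pleiotropy test).

    Weighted regression of beta_outcome on beta_exposure with an intercept,
    weights 1/se_outcome^2, after orienting all exposure betas non-negative.
    Standard errors use the multiplicative random-effects scaling
    sqrt(max(1, Q_egger/(J-2))).
    """
    j = len(h)
    if j < 3:
        raise DataError("egger: at least 3 variants required")
    sgn = np.sign(h.beta_exposure)
    sgn[sgn == 0] = 1.0
    bx = h.beta_exposure * sgn
    by = h.beta_outcome * sgn
    w = 1.0 / h.se_outcome**2
    sw, swx = np.sum(w), np.sum(w * bx)
    swxx, swy, swxy = np.sum(w * bx**2), np.sum(w * by), np.sum(w * bx * by)
    det = sw * swxx - swx**2
    if det <= 0:
        raise EstimationError("egger: degenerate design (constant exposure betas)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid = by - intercept - slope * bx
    q = float(np.sum(w * resid**2))
    phi = max(1.0, q / (j - 2))
    se_slope = np.sqrt(phi * sw / det)
    se_int = np.sqrt(phi * swxx / det)
    q_p = float(stats.chi2.sf(q, j - 2))
    common = dict(exposure=h.exposure_names[0], outcome=h.outcome_name)
    return (
        _estimate("egger_slope", slope, se_slope, j, q=q, q_p=q_p, **common),
        _estimate("egger_intercept", intercept, se_int, j, q=q, q_p=q_p, **common),
    )


@dataclass
class PressoResult:
    """MR-PRESSO global test and outlier removal outcome."""

    global_rss: float
    global_p: float
    outlier_ids: list[str]
    outlier_p: pd.Series
    filtered: HarmonizedSet
    n_sim: int


def _loo_slopes(bx, by, w):
    """Leave-one-out IVW slopes (WLS through origin), vectorized.

    Accepts 1-D arrays or (n_sim, J) matrices; returns the same shape.
    """
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    return (sxy - w * bx * by) / (sxx - w * bx**2)


def mr_presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
) -> PressoResult:
    """MR-PRESSO: simulation-based global pleiotropy test and outlier pruning.

    The observed residual sum of squares of the leave-one-out IVW fit is
    compared with its distribution under ``n_sim`` parametric simulations from
    the fitted model (exposure and outcome betas redrawn from their reported
    standard errors).  Per-variant observed squared residuals against their
    simulated distributions give outlier p-values, Bonferroni-thresholded at
    ``alpha_outlier``; flagged variants are dropped with reason
    ``presso_outlier``.
    """
    if n_sim < 100:
        raise ValueError("mr_presso: n_sim must be at least 100")
    j = len(h)
    if j < 4:
        raise DataError("mr_presso: at least 4 variants required")
    rng = np.random.default_rng(seed)
    bx, sx = h.beta_exposure, h.se_exposure
    by, sy = h.beta_outcome, h.se_outcome
    w = 1.0 / sy**2
    beta_loo = _loo_slopes(bx, by, w)
    resid_obs = w * (by - bx * beta_loo) ** 2
    rss_obs = float(np.sum(resid_obs))
    bx_sim = rng.normal(bx, sx, size=(n_sim, j))
    by_sim = rng.normal(bx * beta_loo, sy, size=(n_sim, j))
    beta_loo_sim = _loo_slopes(bx_sim, by_sim, w)
    resid_sim = w * (by_sim - bx_sim * beta_loo_sim) ** 2
    rss_sim = resid_sim.sum(axis=1)
    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_out = (1 + np.sum(resid_sim >= resid_obs, axis=0)) / (n_sim + 1)
    outlier_p = pd.Series(p_out, index=h.table["variant_id"], name="presso_p")
    outliers = list(outlier_p.index[p_out < alpha_outlier / j])
    filtered = h.drop_variants(outliers, "presso_outlier") if outliers else h
    return PressoResult(
        global_rss=rss_obs,
        global_p=global_p,
        outlier_ids=outliers,
        outlier_p=outlier_p,
        filtered=filtered,
        n_sim=n_sim,
    )


def steiger_filter(h: HarmonizedSet) -> tuple[HarmonizedSet, pd.DataFrame]:
    """Drop variants explaining more outcome than exposure variance.

    Per variant, r^2 = t^2/(t^2 + n - 2) with t = beta/se, on the observation
    scale for both traits (a log-odds approximation when the outcome is
    binary).  Variants with r^2_outcome strictly greater than r^2_exposure are
    removed with reason ``steiger_reverse``.
    """
    t2x = (h.beta_exposure / h.se_exposure) ** 2
    t2y = (h.beta_outcome / h.se_outcome) ** 2
    nx = h.table["n_exposure"].to_numpy(float)
    ny = h.table["n_outcome"].to_numpy(float)
    if np.isnan(nx).any() or np.isnan(ny).any():
        raise DataError("steiger_filter: per-variant sample sizes required")
    r2x = t2x / (t2x + nx - 2)
    r2y = t2y / (t2y + ny - 2)
    detail = pd.DataFrame(
        {
            "variant_id": h.table["variant_id"],
            "r2_exposure": r2x,
            "r2_outcome": r2y,
            "reverse": r2y > r2x,
        }
    )
    drop = detail.loc[detail["reverse"], "variant_id"]
    return h.drop_variants(drop, "steiger_reverse"), detail


def mvmr(h: HarmonizedSet) -> dict[str, MREstimate]:
    """Multivariable MR: joint direct effects of K >= 2 exposures.

    Weighted multiple regression without intercept of beta_outcome on the K
    exposure-beta columns (weights 1/se_outcome^2), with multiplicative
    random-effects scaling.  Each exposure's conditional F statistic follows
    the Sanderson-Windmeijer construction: the weighted residual Q of its beta
    column regressed on the other exposures' columns, divided by J - K + 1;
    estimates with conditional F < 10 carry ``weak_instruments=True``.
    """
    names = list(h.exposure_names)
    k = len(names)
    if k < 2:
        raise DataError("mvmr: at least two exposures required")
    j = len(h)
    if j <= k:
        raise DataError("mvmr: more variants than exposures required")
    b_cols = [f"beta_exposure_{n}" for n in names]
    s_cols = [f"se_exposure_{n}" for n in names]
    bmat_full = h.table[b_cols].to_numpy(float)
    semat_full = h.table[s_cols].to_numpy(float)
    # an exposure with no instrument signal at all cannot be estimated; drop
    # its column so the remaining system degrades gracefully (K=1 -> IVW)
    active = [i for i in range(k) if np.any(bmat_full[:, i] != 0)]
    bmat = bmat_full[:, active]
    semat = semat_full[:, active]
    k_eff = len(active)
    if k_eff == 0:
        raise EstimationError("mvmr: all exposure-beta columns are zero")
    by, sy = h.beta_outcome, h.se_outcome
    w = 1.0 / sy**2
    bw = bmat * np.sqrt(w)[:, None]
    yw = by * np.sqrt(w)
    a = bw.T @ bw
    if np.linalg.matrix_rank(a) < k_eff:
        raise EstimationError("mvmr: rank-deficient exposure-beta matrix")
    coef = np.linalg.solve(a, bw.T @ yw)
    resid = by - bmat @ coef
    q = float(np.sum(w * resid**2))
    q_p = float(stats.chi2.sf(q, j - k_eff))
    phi = max(1.0, q / (j - k_eff))
    cov = np.linalg.inv(a) * phi
    out: dict[str, MREstimate] = {}
    for pos, idx in enumerate(active):
        name = names[idx]
        f_cond = _conditional_f(bmat, semat, pos)
        out[name] = _estimate(
            "mvmr",
            coef[pos],
            np.sqrt(cov[pos, pos]),
            j,
            q=q,
            q_p=q_p,
            exposure=name,
            outcome=h.outcome_name,
            conditional_f=f_cond,
            weak_instruments=f_cond < WEAK_F_THRESHOLD,
        )
    for idx in set(range(k)) - set(active):
        name = names[idx]
        logger.warning("mvmr: exposure %s has an all-zero beta column; not estimable", name)
        out[name] = MREstimate(
            method="mvmr",
            beta=np.nan,
            se=np.nan,
            p=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            n_variants=j,
            exposure=name,
            outcome=h.outcome_name,
            conditional_f=0.0,
            weak_instruments=True,
        )
    return out


def _conditional_f(bmat: np.ndarray, semat: np.ndarray, idx: int) -> float:
    """Conditional instrument strength for exposure ``idx`` given the others.

    Reduces to the mean univariable F = mean((beta/se)^2) when K = 1.
    """
    j, k = bmat.shape
    target = bmat[:, idx]
    se_t = semat[:, idx]
    others = np.delete(bmat, idx, axis=1)
    w = 1.0 / se_t**2
    if others.shape[1] == 0:
        resid = target
    else:
        ow = others * np.sqrt(w)[:, None]
        tw = target * np.sqrt(w)
        gamma, *_ = np.linalg.lstsq(ow, tw, rcond=None)
        resid = target - others @ gamma
    q = float(np.sum(w * resid**2))
    return q / (j - k + 1)


def sensitivity_filter(
    h: HarmonizedSet,
    steiger: bool = True,
    presso: bool = True,
    presso_n_sim: int = 1000,
    seed: int | None = None,
    alpha_outlier: float = 0.05,
    order: tuple[str, ...] = ("steiger", "presso"),
) -> tuple[HarmonizedSet, dict]:
    """Apply Steiger then MR-PRESSO outlier removal (order configurable).

    Returns the pruned harmonized set plus a diagnostics dict (PRESSO global
    p, outlier ids, Steiger detail).  Either filter is skipped gracefully when
    the set is too small for it.
    """
    info: dict = {}
    for step in order:
        if step == "steiger" and steiger:
            h, detail = steiger_filter(h)
            info["steiger_detail"] = detail
        elif step == "presso" and presso:
            if len(h) >= 4:
                res = mr_presso(h, n_sim=presso_n_sim, seed=seed, alpha_outlier=alpha_outlier)
                h = res.filtered
                info["presso_global_p"] = res.global_p
                info["presso_outliers"] = res.outlier_ids
            else:
                logger.info("sensitivity_filter: <4 variants, skipping MR-PRESSO")
    return h, info
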