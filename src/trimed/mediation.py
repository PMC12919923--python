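"""Product-method mediation with Sobel uncertainty, in both frameworks.

The indirect effect of the exposure through a mediator is the product of the
a-path (exposure -> mediator, linear scale) and the b-path (mediator ->
outcome log-risk, adjusted for the exposure).  The Sobel standard error
sqrt(a^2 se_b^2 + b^2 se_a^2) assumes the two paths are estimated
independently — exact for the two-sample MR arm, an approximation for the
cohort arm (which reuses one sample); a Monte-Carlo product-distribution CI
is available as a cross-check.  The proportion mediated is indirect/total on
the log-risk scale, with a first-order delta-method CI; out-of-range values
are reported verbatim with a flag, never truncated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from trimed import cohort as cohort_mod
from trimed import mr as mr_mod
from trimed import sumstats as ss_mod
from trimed.cohort import EffectEstimate
from trimed.errors import DataError, EstimationError
from trimed.mr import MREstimate

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass
class IndirectEffect:
    """Product-method indirect effect with Sobel (and optional MC) uncertainty."""

    beta: float
    se: float
    ci_low: float
    ci_high: float
    mc_ci: tuple[float, float] | None = None

    @property
    def p(self) -> float:
        return float(2 * stats.norm.sf(abs(self.beta) / self.se)) if self.se > 0 else np.nan


@dataclass
class ProportionMediated:
    """indirect/total on the log-risk scale with a delta-method CI."""

    pm: float
    se: float
    ci_low: float
    ci_high: float
    out_of_range: bool


@dataclass
class MediationResult:
    """Total, direct and indirect effects plus proportion mediated, per framework."""

    framework: str  # cohort | mr
    mediator: str
    total: object  # EffectEstimate or MREstimate
    direct: object  # adjusted-coefficient direct effect
    indirect: IndirectEffect
    proportion: ProportionMediated
    direct_minus: float = np.nan  # difference-method direct: total - indirect
    a_path: object = None
    b_path: object = None
    method_notes: str = ""
    suppressed: bool = False


def product_indirect(
    a: EffectEstimate | MREstimate,
    b: EffectEstimate | MREstimate,
    mc_draws: int = 0,
    seed: int | None = None,
) -> IndirectEffect:
    """Indirect effect a*b with the Sobel standard error.

    ``a`` must be on the linear (mediator) scale and ``b`` on a log-risk
    scale; a scale mismatch raises.  With ``mc_draws`` > 0 a Monte-Carlo CI of
    the product of two independent normals is attached as a cross-check.
    """
    a_scale = getattr(a, "scale", "linear")
    b_scale = getattr(b, "scale", "log_odds")
    if a_scale != "linear":
        raise DataError(f"product_indirect: a-path must be linear scale, got {a_scale}")
    if b_scale not in ("log_hazard", "log_odds"):
        raise DataError(f"product_indirect: b-path must be log-risk scale, got {b_scale}")
    beta = a.beta * b.beta
    se = float(np.sqrt(a.beta**2 * b.se**2 + b.beta**2 * a.se**2))
    mc_ci = None
    if mc_draws > 0:
        rng = np.random.default_rng(seed)
        prod = rng.normal(a.beta, a.se, mc_draws) * rng.normal(b.beta, b.se, mc_draws)
        mc_ci = tuple(np.quantile(prod, [0.025, 0.975]))
    return IndirectEffect(
        beta=float(beta),
        se=se,
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        mc_ci=mc_ci,
    )


def proportion_mediated(
    indirect_beta: float,
    indirect_se: float,
    total: EffectEstimate | MREstimate,
) -> ProportionMediated:
    """pm = indirect/total with a first-order delta-method CI.

    The two inputs are treated as independent (they come from different
    models/arms).  Estimates outside [0, 1] are reported verbatim and flagged.
    """
    if total.beta == 0:
        raise EstimationError("proportion_mediated: total effect is zero")
    pm = indirect_beta / total.beta
    var = indirect_se**2 / total.beta**2 + indirect_beta**2 * total.se**2 / total.beta**4
    se = float(np.sqrt(var))
    out_of_range = not (0.0 <= pm <= 1.0)
    if out_of_range:
        logger.info("proportion_mediated: estimate %.3f outside [0, 1]", pm)
    return ProportionMediated(
        pm=float(pm),
        se=se,
        ci_low=float(pm - Z95 * se),
        ci_high=float(pm + Z95 * se),
        out_of_range=out_of_range,
    )


def mediate_cohort(
    cohort: pd.DataFrame,
    mediator: str,
    exposure: str = "bmi",
    covariates=cohort_mod.DEFAULT_COVARIATES,
    mc_draws: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """Cohort-arm two-step mediation.

    a: linear regression of the mediator on per-SD exposure; b: Cox log-hazard
    of the mediator additionally adjusted for the exposure; total: Cox
    log-hazard of the exposure.  The direct effect is reported both as the
    mediator-adjusted exposure coefficient and as total - indirect.
    """
    a = cohort_mod.apath_linear(cohort, mediator, covariates, exposure=exposure)
    b = cohort_mod.cox_risk(cohort, mediator, covariates, extra_adjust=exposure)
    total = cohort_mod.cox_risk(cohort, exposure, covariates)
    direct = cohort_mod.cox_risk(cohort, exposure, covariates, extra_adjust=mediator)
    indirect = product_indirect(a, b, mc_draws=mc_draws, seed=seed)
    pm = proportion_mediated(indirect.beta, indirect.se, total)
    return MediationResult(
        framework="cohort",
        mediator=mediator,
        total=total,
        direct=direct,
        indirect=indirect,
        proportion=pm,
        direct_minus=total.beta - indirect.beta,
        a_path=a,
        b_path=b,
        method_notes=(
            f"a: linear {exposure}->{mediator} adj {','.join(covariates)}; "
            f"b: Cox {mediator} adj {','.join(covariates)}+{exposure}; "
            "Sobel se assumes a,b independent (same-sample approximation)"
        ),
    )


def mediate_mr(
    exposure_ss: pd.DataFrame,
    mediator_ss: pd.DataFrame,
    outcome_ss: pd.DataFrame,
    ld: ss_mod.LDTable | None = None,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
    ivw_model: str = "multiplicative_random",
    mediator_name: str = "mediator",
    exposure_name: str = "exposure",
    suppress_weak: bool = False,
    mc_draws: int = 0,
    seed: int | None = None,
) -> MediationResult:
    """MR-arm two-step mediation from three summary-statistic sets.

    a: univariable IVW exposure -> mediator; b: multivariable MR mediator ->
    outcome adjusted for the exposure (on the union of both instrument sets);
    total: univariable IVW exposure -> outcome.  A conditional F < 10 on the
    mediator marks the b-path weak; with ``suppress_weak`` the mediation
    estimates are reported as NaN ("not calculated") while paths are kept.
    """
    exp_inst = ss_mod.select_instruments(
        exposure_ss, p_threshold, ld, r2_threshold, window_kb, exposure_name
    )
    if exp_inst.empty:
        raise EstimationError("mediate_mr: no instruments for the exposure")
    h_xm = ss_mod.harmonize(exp_inst, mediator_ss, outcome_name=mediator_name)
    a = mr_mod.ivw(h_xm, model=ivw_model)
    h_xy = ss_mod.harmonize(exp_inst, outcome_ss, outcome_name="outcome")
    total = mr_mod.ivw(h_xy, model=ivw_model)

    med_inst = ss_mod.select_instruments(
        mediator_ss, p_threshold, ld, r2_threshold, window_kb, mediator_name
    )
    union = (
        pd.concat([exp_inst.variants, med_inst.variants], ignore_index=True)
        .drop_duplicates("variant_id")
        .reset_index(drop=True)
    )
    union_inst = ss_mod.InstrumentSet(
        exposure_name=f"{exposure_name}+{mediator_name}",
        variants=union,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
    )
    h_mv = ss_mod.harmonize_mvmr(
        {exposure_name: exposure_ss, mediator_name: mediator_ss},
        outcome_ss,
        union_inst,
    )
    mv = mr_mod.mvmr(h_mv)
    b = mv[mediator_name]
    direct = mv[exposure_name]
    notes = [
        f"a: IVW {exposure_name}->{mediator_name} ({len(h_xm)} SNPs); "
        f"b: MVMR {mediator_name}->outcome adj {exposure_name} "
        f"({len(h_mv)} SNPs, conditional F={b.conditional_f:.1f})"
    ]
    suppressed = False
    if b.weak_instruments:
        notes.append("weak instruments: conditional F < 10 on the mediator")
        if suppress_weak:
            suppressed = True
    indirect = product_indirect(a, b, mc_draws=mc_draws, seed=seed)
    pm = proportion_mediated(indirect.beta, indirect.se, total)
    if suppressed:
        indirect = IndirectEffect(np.nan, np.nan, np.nan, np.nan)
        pm = ProportionMediated(np.nan, np.nan, np.nan, np.nan, False)
        notes.append("mediation estimates suppressed (not calculated)")
    return MediationResult(
        framework="mr",
        mediator=mediator_name,
        total=total,
        direct=direct,
        indirect=indirect,
        proportion=pm,
        direct_minus=total.beta - indirect.beta,
        a_path=a,
        b_path=b,
        method_notes="; ".join(notes),
        suppressed=suppressed,
    )
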