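"""Triangulation: gate mediation on concordant evidence from both arms.

A mediator is eligible for mediation analysis only when its association with
the outcome is directionally concordant *and* significant (p < alpha) in both
the cohort arm and the MR arm — the conservative rule that protects the
product-method step from acting on discordant or null risk signals.  This
module also assembles the cross-arm comparison tables (exposure -> mediator
effects per arm, risk effects per arm, pairwise mediator relations) and the
full pipeline orchestration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from trimed import cohort as cohort_mod
from trimed import mediation as med_mod
from trimed import mr as mr_mod
from trimed import sumstats as ss_mod
from trimed.cohort import EffectEstimate
from trimed.errors import DataError, EstimationError
from trimed.mr import MREstimate
from trimed.simulate import SimulatedWorld

logger = logging.getLogger(__name__)


@dataclass
class TriangulationRecord:
    """Cross-arm comparison for one mediator's association with the outcome."""

    mediator: str
    cohort_estimate: EffectEstimate
    mr_estimate: MREstimate
    directionally_concordant: bool
    both_significant: bool
    eligible: bool
    pleiotropy_flag: bool = False


def assess_concordance(
    cohort_est: EffectEstimate,
    mr_est: MREstimate,
    alpha: float = 0.05,
    pleiotropy_p: float | None = None,
    pleiotropy_alpha: float = 0.05,
) -> TriangulationRecord:
    """Apply the eligibility rule to one mediator.

    Both estimates must be on comparable per-SD log-risk scales (log-hazard or
    log-odds; in the rare-disease regime these coincide).  Eligibility is sign
    agreement AND p < alpha in both arms; an Egger-intercept p below
    ``pleiotropy_alpha`` attaches a pleiotropy flag without affecting
    eligibility.
    """
    if cohort_est.scale not in ("log_hazard", "log_odds"):
        raise DataError(f"assess_concordance: cohort estimate on {cohort_est.scale} scale")
    concordant = bool(np.sign(cohort_est.beta) == np.sign(mr_est.beta)) and cohort_est.beta != 0
    significant = bool(cohort_est.p < alpha and mr_est.p < alpha)
    return TriangulationRecord(
        mediator=cohort_est.term,
        cohort_estimate=cohort_est,
        mr_estimate=mr_est,
        directionally_concordant=concordant,
        both_significant=significant,
        eligible=concordant and significant,
        pleiotropy_flag=(pleiotropy_p is not None and pleiotropy_p < pleiotropy_alpha),
    )


def pairwise_relations(
    cohort: pd.DataFrame,
    mediators: list[str],
    sumstats: dict[str, pd.DataFrame],
    ld: ss_mod.LDTable | None = None,
    covariates=cohort_mod.DEFAULT_COVARIATES,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
    ivw_model: str = "multiplicative_random",
    steiger: bool = True,
) -> pd.DataFrame:
    """Ordered-pair mediator-on-mediator effects in both frameworks.

    For every ordered pair (i, j), i != j: the cohort arm regresses mediator j
    on per-SD mediator i (linear, standard adjustment set); the MR arm runs
    univariable IVW of j on i's instruments, Steiger-filtered by default so a
    variant primarily associated with the downstream trait cannot masquerade
    as an instrument for the upstream one.  Rows where no instruments survive
    carry NaN estimates.  Per framework the table has K*(K-1) = 2*C(K,2) rows.
    """
    rows = []
    for m_from, m_to in permutations(mediators, 2):
        est = cohort_mod.apath_linear(cohort, m_to, covariates, exposure=m_from)
        rows.append(
            {
                "framework": "cohort",
                "from": m_from,
                "to": m_to,
                "beta": est.beta,
                "se": est.se,
                "p": est.p,
                "n_variants": np.nan,
            }
        )
        inst = ss_mod.select_instruments(
            sumstats[m_from], p_threshold, ld, r2_threshold, window_kb, m_from
        )
        h = None
        if not inst.empty:
            h = ss_mod.harmonize(inst, sumstats[m_to], outcome_name=m_to)
            if steiger:
                h, _detail = mr_mod.steiger_filter(h)
        if h is None or len(h) == 0:
            beta = se = p = np.nan
            nv = 0
        else:
            mr_est = mr_mod.ivw(h, model=ivw_model)
            beta, se, p, nv = mr_est.beta, mr_est.se, mr_est.p, mr_est.n_variants
        rows.append(
            {
                "framework": "mr",
                "from": m_from,
                "to": m_to,
                "beta": beta,
                "se": se,
                "p": p,
                "n_variants": nv,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ResultBundle:
    """Everything the pipeline computes, ready for the report writers."""

    seed: int
    truth: object
    bmi_mediator_table: pd.DataFrame
    risk_table: pd.DataFrame
    triangulation: list[TriangulationRecord]
    mediation_results: list[med_mod.MediationResult]
    edges: pd.DataFrame
    dropped: pd.DataFrame
    arm_beta_correlation: float
    diagnostics: dict = field(default_factory=dict)


def run_pipeline(config, seed: int | None = None, ld_reference_n: int = 2000) -> ResultBundle:
    """Execute the three-step triangulated mediation analysis end to end.

    (1) exposure -> mediator effects in both arms; (2) mediator -> outcome
    risk in both arms, with Steiger/MR-PRESSO sensitivity filtering and an
    Egger pleiotropy flag on the MR side; (3) product-method mediation for
    mediators passing the concordance gate.  Inputs are drawn from the
    synthetic world described by ``config.simulation``; ``seed`` overrides its
    seed.  LD for clumping is computed from a fresh reference panel of
    ``ld_reference_n`` individuals.
    """
    ana = config.analysis
    sim = config.simulation
    world = SimulatedWorld(sim, seed=seed)
    used_seed = sim.seed if seed is None else seed
    cohort, truth = world.simulate_cohort()
    sumstats, _ids = world.simulate_gwas_arms()
    ld_rng = np.random.default_rng(np.random.SeedSequence([used_seed, 991]))
    ld = ss_mod.LDTable.from_genotypes(
        world.simulate_genotypes(ld_reference_n, ld_rng), world.meta["variant_id"]
    )
    mediators = list(sim.mediator_names)
    clump_kw = dict(
        p_threshold=ana.p_threshold,
        ld=ld,
        r2_threshold=ana.r2_threshold,
        window_kb=ana.window_kb,
    )

    # --- step 1: exposure -> mediator, both arms -------------------------------
    exp_inst = ss_mod.select_instruments(sumstats["exposure"], exposure_name="bmi", **clump_kw)
    if exp_inst.empty:
        raise EstimationError("run_pipeline: no exposure instruments after clumping")
    bmi_rows = []
    for m in mediators:
        coh = cohort_mod.apath_linear(cohort, m, exposure="bmi")
        h = ss_mod.harmonize(exp_inst, sumstats[m], ana.palindromic_eaf_window, outcome_name=m)
        gen = mr_mod.ivw(h, model=ana.ivw_model)
        bmi_rows.append(
            {
                "mediator": m,
                "beta_cohort": coh.beta,
                "se_cohort": coh.se,
                "p_cohort": coh.p,
                "beta_mr": gen.beta,
                "se_mr": gen.se,
                "p_mr": gen.p,
                "n_variants": gen.n_variants,
            }
        )
    bmi_table = pd.DataFrame(bmi_rows)
    if len(bmi_table) >= 2:
        arm_r = float(np.corrcoef(bmi_table["beta_cohort"], bmi_table["beta_mr"])[0, 1]) ** 2
    else:
        arm_r = np.nan

    # --- step 2: risk models, both arms ----------------------------------------
    dropped_frames = []
    risk_rows = []
    records: list[TriangulationRecord] = []
    alpha = ana.alpha / len(mediators) if ana.bonferroni else ana.alpha
    total_cohort = cohort_mod.cox_risk(cohort, "bmi")
    h_bmi_out = ss_mod.harmonize(
        exp_inst, sumstats["outcome"], ana.palindromic_eaf_window, outcome_name="outcome"
    )
    h_bmi_out, _info = mr_mod.sensitivity_filter(
        h_bmi_out,
        steiger=ana.steiger,
        presso=ana.presso,
        presso_n_sim=ana.presso_n_sim,
        seed=used_seed,
        alpha_outlier=ana.presso_alpha_outlier,
    )
    total_mr = mr_mod.ivw(h_bmi_out, model=ana.ivw_model)
    risk_rows.append(_risk_row("bmi", total_cohort, total_mr, np.nan))
    for m in mediators:
        coh = cohort_mod.cox_risk(cohort, m)
        inst = ss_mod.select_instruments(sumstats[m], exposure_name=m, **clump_kw)
        if inst.empty:
            raise EstimationError(f"run_pipeline: no instruments for mediator {m}")
        h = ss_mod.harmonize(
            inst, sumstats["outcome"], ana.palindromic_eaf_window, outcome_name="outcome"
        )
        h, info = mr_mod.sensitivity_filter(
            h,
            steiger=ana.steiger,
            presso=ana.presso,
            presso_n_sim=ana.presso_n_sim,
            seed=used_seed,
            alpha_outlier=ana.presso_alpha_outlier,
        )
        dropped_frames.append(h.dropped.assign(exposure=m))
        gen = mr_mod.ivw(h, model=ana.ivw_model)
        pleio_p = None
        if len(h) >= 3:
            _, intercept = mr_mod.egger(h)
            pleio_p = intercept.p
        rec = assess_concordance(coh, gen, alpha=alpha, pleiotropy_p=pleio_p)
        records.append(rec)
        risk_rows.append(_risk_row(m, coh, gen, pleio_p))
    risk_table = pd.DataFrame(risk_rows)

    # --- step 3: mediation for eligible mediators ------------------------------
    mediation_results = []
    for rec in records:
        if not rec.eligible:
            continue
        mediation_results.append(
            med_mod.mediate_cohort(cohort, rec.mediator, mc_draws=ana.mc_draws, seed=used_seed)
        )
        mediation_results.append(
            med_mod.mediate_mr(
                sumstats["exposure"],
                sumstats[rec.mediator],
                sumstats["outcome"],
                ld=ld,
                p_threshold=ana.p_threshold,
                r2_threshold=ana.r2_threshold,
                window_kb=ana.window_kb,
                ivw_model=ana.ivw_model,
                mediator_name=rec.mediator,
                exposure_name="bmi",
                suppress_weak=ana.suppress_weak,
                mc_draws=ana.mc_draws,
                seed=used_seed,
            )
        )

    edges = (
        pairwise_relations(
            cohort,
            mediators,
            sumstats,
            ld=ld,
            p_threshold=ana.p_threshold,
            r2_threshold=ana.r2_threshold,
            window_kb=ana.window_kb,
            ivw_model=ana.ivw_model,
        )
        if len(mediators) >= 2
        else pd.DataFrame(columns=["framework", "from", "to", "beta", "se", "p", "n_variants"])
    )
    dropped = (
        pd.concat(dropped_frames, ignore_index=True)
        if dropped_frames
        else pd.DataFrame(columns=["variant_id", "reason", "exposure"])
    )
    return ResultBundle(
        seed=used_seed,
        truth=truth,
        bmi_mediator_table=bmi_table,
        risk_table=risk_table,
        triangulation=records,
        mediation_results=mediation_results,
        edges=edges,
        dropped=dropped,
        arm_beta_correlation=arm_r,
        diagnostics={"n_events": int(cohort["event"].sum()), "n_cohort": len(cohort)},
    )


def _risk_row(term, coh: EffectEstimate, gen: MREstimate, pleio_p):
    return {
        "term": term,
        "beta_cohort": coh.beta,
        "se_cohort": coh.se,
        "hr_cohort": float(np.exp(coh.beta)),
        "p_cohort": coh.p,
        "n_events": coh.n_events,
        "beta_mr": gen.beta,
        "se_mr": gen.se,
        "or_mr": gen.odds_ratio,
        "p_mr": gen.p,
        "n_variants": gen.n_variants,
        "egger_intercept_p": np.nan if pleio_p is None else pleio_p,
    }
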