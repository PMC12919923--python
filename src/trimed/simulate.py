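"""Synthetic data with a known exposure -> mediator -> outcome DAG.

The generator emulates the data landscape of an obesity/renal-cancer mediation
study: a BMI-like standardized exposure with a polygenic basis, one or more
mediators causally downstream of the exposure with their own genetic effects,
a shared latent confounder loading on exposure, mediators and outcome, a rare
exponential time-to-event outcome (default ~1.4% cumulative incidence over 12
years of follow-up, i.e. ~1,400 events per 100,000 participants — a
scaled-down rendering of a registry-linked cancer cohort's event count),
lifestyle and demographic covariates, LD-block genotype structure, and two
non-overlapping GWAS arms for two-sample Mendelian randomization.

Structural model (all traits in SD units, closed-form ground truth):

    X   = g_x + c*C + e_x                      (unit variance by construction)
    M_k = a_k*X + b*M_{k-1} + g_k + c*C + e_k  (unit variance by construction)
    h(t|.) = h0 * exp(d*X + sum_k m_k*M_k + c*C + covariate effects)

so the total log-hazard per SD of X is d + sum over directed paths, the
indirect effect is their difference, and the proportion mediated follows in
closed form.

LD is generated at the haplotype level by a Markov allele-copy process: within
a block (constant MAF), each successive allele copies its left neighbour with
probability ``ld_rho`` and is otherwise drawn fresh, giving adjacent genotype
correlation exactly ``ld_rho`` (r^2 = rho^2) and an AR(1) decay rho^k; blocks
are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
import statsmodels.api as sm

from trimed.errors import ConfigError, DataError
from trimed.sumstats import SUMSTAT_COLUMNS

logger = logging.getLogger(__name__)

#: non-palindromic allele pairs assigned to simulated variants, so that
#: harmonization never has to drop a synthetic instrument as ambiguous
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]


def _as_tuple(x) -> tuple[float, ...]:
    if np.isscalar(x):
        return (float(x),)
    return tuple(float(v) for v in x)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world; defaults are the study conditions.

    Effect sizes are per SD: ``beta_xm`` (exposure -> mediator), ``beta_my``
    (mediator -> outcome log-hazard), ``beta_xy_direct`` (direct exposure ->
    outcome log-hazard).  The defaults plant a total log-hazard of
    0.225 + 0.35*0.40 = 0.365 per SD (hazard ratio 1.44).  ``beta_xm`` and
    ``beta_my`` may be sequences to simulate several mediators; ``beta_mm``
    chains mediator k-1 into mediator k (0 = independent mediators).
    """

    seed: int = 0
    n_individuals: int = 100_000
    n_snps_exposure: int = 50
    n_snps_mediator: int = 30
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    ld_rho: float = 0.5
    h2_exposure: float = 0.10
    h2_mediator: float = 0.10
    beta_xm: float | tuple = 0.35
    beta_my: float | tuple = 0.40
    beta_xy_direct: float = 0.225
    beta_mm: float = 0.0
    confounder_strength: float = 0.2
    baseline_hazard: float = 7.3e-4
    followup_years: float = 12.0
    gwas_n_exposure_arm: int = 50_000
    gwas_n_outcome_arm: int = 50_000
    gwas_case_fraction: float = 0.053
    mediator_names: tuple[str, ...] | None = None
    age_log_hr: float = 0.02
    male_log_hr: float = 0.69

    def __post_init__(self) -> None:
        self.beta_xm = _as_tuple(self.beta_xm)
        self.beta_my = _as_tuple(self.beta_my)
        if len(self.beta_xm) != len(self.beta_my):
            raise ConfigError("beta_xm and beta_my must have equal length")
        if self.mediator_names is None:
            if self.n_mediators == 1:
                self.mediator_names = ("mediator",)
            else:
                self.mediator_names = tuple(f"med{k+1}" for k in range(self.n_mediators))
        self.mediator_names = tuple(self.mediator_names)
        if len(self.mediator_names) != self.n_mediators:
            raise ConfigError("mediator_names length mismatch")
        for name, val in [
            ("n_individuals", self.n_individuals),
            ("n_snps_exposure", self.n_snps_exposure),
            ("n_snps_mediator", self.n_snps_mediator),
            ("ld_block_size", self.ld_block_size),
            ("gwas_n_exposure_arm", self.gwas_n_exposure_arm),
            ("gwas_n_outcome_arm", self.gwas_n_outcome_arm),
        ]:
            if int(val) <= 0:
                raise ConfigError(f"{name} must be a positive count")
        lo, hi = self.maf_range
        if not (0.01 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must lie within (0.01, 0.5]")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError("ld_rho must be in [0, 1)")
        for name, h2 in [("h2_exposure", self.h2_exposure), ("h2_mediator", self.h2_mediator)]:
            if not (0.0 < h2 < 1.0):
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.baseline_hazard <= 0 or self.followup_years <= 0:
            raise ConfigError("baseline_hazard and followup_years must be positive")
        if not (0.0 < self.gwas_case_fraction < 1.0):
            raise ConfigError("gwas_case_fraction must be in (0, 1)")
        # variance budgets (noise variance must stay positive)
        self._noise_sd_exposure()
        self._noise_sd_mediators()

    @property
    def n_mediators(self) -> int:
        return len(self.beta_xm)

    def _noise_sd_exposure(self) -> float:
        resid = 1.0 - self.h2_exposure - self.confounder_strength**2
        if resid <= 0:
            raise ConfigError("exposure variance budget exceeds 1 (h2 + confounder^2)")
        return float(np.sqrt(resid))

    def _noise_sd_mediators(self) -> tuple[float, ...]:
        """Noise SDs making each mediator exactly unit variance in expectation."""
        c = self.confounder_strength
        out = []
        cov_prev_x = 0.0  # Cov(M_{k-1}, X)
        cov_prev_c = 0.0  # Cov(M_{k-1}, C)
        for k in range(self.n_mediators):
            a, b = self.beta_xm[k], self.beta_mm if k > 0 else 0.0
            var = (
                a**2
                + b**2
                + c**2
                + self.h2_mediator
                + 2 * a * b * cov_prev_x
                + 2 * a * c * c  # Cov(X, C) = c
                + 2 * b * c * cov_prev_c
            )
            resid = 1.0 - var
            if resid <= 0:
                raise ConfigError(
                    f"mediator {k+1} variance budget exceeds 1 (paths + h2 + confounding)"
                )
            out.append(float(np.sqrt(resid)))
            cov_prev_x = a + b * cov_prev_x + c * c
            cov_prev_c = a * c + b * cov_prev_c + c
        return tuple(out)


@dataclass
class GroundTruth:
    """Closed-form mediation estimands implied by a SimulationConfig."""

    total_log_effect: float
    direct_log_effect: float
    indirect_log_effect: float
    proportion_mediated: float
    per_mediator: dict = field(default_factory=dict)


def compute_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Path-tracing estimands: total = direct + indirect on the log scale."""
    d_x_on_m = []  # total effect of X on M_k
    for k in range(config.n_mediators):
        prev = d_x_on_m[k - 1] if k > 0 else 0.0
        d_x_on_m.append(config.beta_xm[k] + (config.beta_mm if k > 0 else 0.0) * prev)
    indirect = float(sum(m * d for m, d in zip(config.beta_my, d_x_on_m)))
    direct = float(config.beta_xy_direct)
    total = direct + indirect
    # effect of M_k on outcome given X (includes downstream chain paths)
    e_m_on_y = [0.0] * config.n_mediators
    for k in reversed(range(config.n_mediators)):
        downstream = (
            config.beta_mm * e_m_on_y[k + 1] if k + 1 < config.n_mediators else 0.0
        )
        e_m_on_y[k] = config.beta_my[k] + downstream
    per = {
        name: {
            "indirect_log_effect": d_x_on_m[k] * e_m_on_y[k],
            "proportion_mediated": (d_x_on_m[k] * e_m_on_y[k] / total) if total != 0 else np.nan,
        }
        for k, name in enumerate(config.mediator_names)
    }
    return GroundTruth(
        total_log_effect=total,
        direct_log_effect=direct,
        indirect_log_effect=indirect,
        proportion_mediated=indirect / total if total != 0 else np.nan,
        per_mediator=per,
    )


class SimulatedWorld:
    """A fixed genetic architecture from which cohorts and GWAS arms are drawn.

    The variant map, minor-allele frequencies and per-variant effect sizes are
    drawn once at construction (deterministically from the seed), so the two
    GWAS arms and the cohort share one underlying population model while their
    individuals remain disjoint.
    """

    def __init__(self, config: SimulationConfig, seed: int | None = None):
        self.config = config
        root = np.random.SeedSequence(config.seed if seed is None else seed)
        (self._arch_ss, self._cohort_ss, self._exp_arm_ss, self._out_arm_ss,
         self._ncc_ss) = root.spawn(5)
        rng = np.random.default_rng(self._arch_ss)
        cfg = config
        counts = [cfg.n_snps_exposure] + [cfg.n_snps_mediator] * cfg.n_mediators
        traits = ["exposure"] + list(cfg.mediator_names)
        n_total = sum(counts)
        # blocks never straddle trait segments, so exposure and mediator
        # instruments are in linkage equilibrium with each other
        block_of = np.empty(n_total, dtype=int)
        bid = 0
        offset = 0
        for count in counts:
            local = np.arange(count) // cfg.ld_block_size
            block_of[offset : offset + count] = bid + local
            bid += local[-1] + 1
            offset += count
        n_blocks = bid
        block_mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n_blocks)
        self.mafs = block_mafs[block_of]
        self.block_of = block_of
        # variant map: blocks tile chromosomes 1..22 with 20 Mb between blocks
        chrom = 1 + (block_of % 22)
        rank_on_chrom = block_of // 22
        within = np.concatenate(
            [np.arange(np.sum(block_of == b)) for b in range(n_blocks)]
        )
        pos = 1_000_000 + rank_on_chrom * 20_000_000 + within * 100_000
        pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_total)]
        trait_label = np.repeat(traits, counts)
        self.meta = pd.DataFrame(
            {
                "variant_id": [f"rs{i + 1:05d}" for i in range(n_total)],
                "chromosome": chrom.astype(str),
                "base_pair_location": pos.astype(int),
                "effect_allele": [p[0] for p in pairs],
                "other_allele": [p[1] for p in pairs],
                "maf": self.mafs,
                "trait": trait_label,
                "block": block_of,
            }
        )
        # per-variant effects, scaled so each trait's genetic variance is its h2
        self.effects: dict[str, np.ndarray] = {}
        for trait, h2 in zip(traits, [cfg.h2_exposure] + [cfg.h2_mediator] * cfg.n_mediators):
            mask = trait_label == trait
            raw = rng.normal(0.0, 1.0, size=int(mask.sum()))
            gvar = self._genetic_variance(raw, np.flatnonzero(mask))
            eff = np.zeros(n_total)
            eff[mask] = raw * np.sqrt(h2 / gvar)
            self.effects[trait] = eff
        self.truth = compute_ground_truth(cfg)

    def _genetic_variance(self, eff: np.ndarray, idx: np.ndarray) -> float:
        """Analytic variance of G[:, idx] @ eff under the block-AR(1) LD model."""
        cfg = self.config
        total = 0.0
        blocks = self.block_of[idx]
        for b in np.unique(blocks):
            sel = blocks == b
            e = eff[sel]
            p = self.mafs[idx[sel]][0]
            v = 2 * p * (1 - p)
            k = len(e)
            lags = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
            cov = v * cfg.ld_rho**lags
            total += float(e @ cov @ e)
        return total

    # ------------------------------------------------------------------ genotypes

    def simulate_genotypes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Additive 0/1/2 genotypes for ``n`` individuals (HWE, block LD)."""
        if n <= 0:
            raise ConfigError("n must be a positive count")
        cfg = self.config
        if cfg.ld_rho == 0.0 or cfg.ld_block_size == 1:
            # linkage equilibrium: one binomial draw per variant
            return rng.binomial(2, self.mafs, size=(n, len(self.mafs))).astype(np.int8)
        g = np.empty((n, len(self.mafs)), dtype=np.int8)
        for b in np.unique(self.block_of):
            sel = np.flatnonzero(self.block_of == b)
            p = self.mafs[sel[0]]
            hap = np.zeros((n, len(sel), 2), dtype=np.int8)
            for h in range(2):
                hap[:, 0, h] = rng.random(n) < p
                for j in range(1, len(sel)):
                    copy = rng.random(n) < cfg.ld_rho
                    fresh = rng.random(n) < p
                    hap[:, j, h] = np.where(copy, hap[:, j - 1, h], fresh)
            g[:, sel] = hap.sum(axis=2)
        return g

    # ------------------------------------------------------------------ traits

    def _covariates(self, n: int, rng: np.random.Generator, confounder: np.ndarray):
        """Demographic/lifestyle covariates; smoking and alcohol load on C."""
        age = rng.uniform(40.0, 70.0, size=n)
        sex = (rng.random(n) < 0.46).astype(int)  # 1 = male
        center = np.array([f"center_{i}" for i in rng.integers(0, 6, size=n)])
        education = np.array([f"edu_{i}" for i in rng.integers(0, 4, size=n)])

        def _ordinal(latent):
            cat = np.full(n, "never", dtype=object)
            cut1, cut2 = np.quantile(latent, [0.55, 0.80])
            cat[latent > cut1] = "former"
            cat[latent > cut2] = "current"
            return cat

        smoking = _ordinal(0.6 * confounder + 0.8 * rng.normal(size=n))
        alcohol = _ordinal(0.6 * confounder + 0.8 * rng.normal(size=n))
        return pd.DataFrame(
            {
                "age": age,
                "sex": sex,
                "center": center,
                "education": education,
                "smoking": smoking,
                "alcohol": alcohol,
            }
        )

    def _traits(self, genotypes: np.ndarray, rng: np.random.Generator):
        """Latent confounder, exposure and mediators from the structural model."""
        cfg = self.config
        n = genotypes.shape[0]
        gc = genotypes - 2 * self.mafs  # centered dosages
        confounder = rng.normal(size=n)
        noise_x = cfg._noise_sd_exposure()
        x = gc @ self.effects["exposure"] + cfg.confounder_strength * confounder
        x = x + noise_x * rng.normal(size=n)
        noise_m = cfg._noise_sd_mediators()
        mediators = {}
        prev = None
        for k, name in enumerate(cfg.mediator_names):
            m = (
                cfg.beta_xm[k] * x
                + gc @ self.effects[name]
                + cfg.confounder_strength * confounder
                + noise_m[k] * rng.normal(size=n)
            )
            if k > 0 and cfg.beta_mm != 0.0:
                m = m + cfg.beta_mm * prev
            mediators[name] = m
            prev = m
        return confounder, x, mediators

    def _log_hazard(self, x, mediators, confounder, covs: pd.DataFrame) -> np.ndarray:
        cfg = self.config
        lp = cfg.beta_xy_direct * x + cfg.confounder_strength * confounder
        for k, name in enumerate(cfg.mediator_names):
            lp = lp + cfg.beta_my[k] * mediators[name]
        lp = lp + cfg.age_log_hr * (covs["age"].to_numpy() - 55.0)
        lp = lp + cfg.male_log_hr * covs["sex"].to_numpy()
        return lp

    def simulate_cohort(
        self, n: int | None = None, rng: np.random.Generator | None = None
    ) -> tuple[pd.DataFrame, GroundTruth]:
        """Individual-level cohort with exponential survival outcome.

        Event times are exponential with individual rate
        ``baseline_hazard * exp(log-hazard)``, administratively censored at
        ``followup_years``; the constant hazard makes the Cox log-HR equal the
        planted coefficients.
        """
        cfg = self.config
        n = cfg.n_individuals if n is None else n
        rng = np.random.default_rng(self._cohort_ss) if rng is None else rng
        genotypes = self.simulate_genotypes(n, rng)
        confounder, x, mediators = self._traits(genotypes, rng)
        covs = self._covariates(n, rng, confounder)
        lp = self._log_hazard(x, mediators, confounder, covs)
        rate = cfg.baseline_hazard * np.exp(lp)
        t_event = rng.exponential(1.0 / rate)
        event = (t_event <= cfg.followup_years).astype(int)
        time = np.minimum(t_event, cfg.followup_years)
        time = np.maximum(time, 1e-8)
        cohort = pd.DataFrame({"id": [f"cohort_{i:06d}" for i in range(n)]})
        cohort = pd.concat([cohort, covs], axis=1)
        cohort["bmi"] = x
        for name in cfg.mediator_names:
            cohort[name] = mediators[name]
        cohort["followup_time"] = time
        cohort["event"] = event
        return cohort, self.truth

    # ------------------------------------------------------------------ GWAS arms

    def simulate_gwas_arms(self) -> tuple[dict[str, pd.DataFrame], dict[str, np.ndarray]]:
        """Two non-overlapping GWAS arms for two-sample MR.

        Arm A (``gwas_n_exposure_arm`` individuals) yields continuous GWAS for
        the exposure and every mediator; arm B (``gwas_n_outcome_arm``) yields
        a binary-outcome GWAS emulating case-control ascertainment at
        ``gwas_case_fraction``.  All single-variant regressions adjust for age
        and sex.  Returns (summary-statistic frames, per-arm individual ids).
        """
        cfg = self.config
        rng_a = np.random.default_rng(self._exp_arm_ss)
        n_a = cfg.gwas_n_exposure_arm
        geno_a = self.simulate_genotypes(n_a, rng_a)
        conf_a, x_a, med_a = self._traits(geno_a, rng_a)
        covs_a = self._covariates(n_a, rng_a, conf_a)
        adj = covs_a[["age", "sex"]]
        sumstats = {
            "exposure": compute_summary_stats(geno_a, x_a, adj, "continuous", self.meta)
        }
        for name in cfg.mediator_names:
            sumstats[name] = compute_summary_stats(geno_a, med_a[name], adj, "continuous", self.meta)

        rng_b = np.random.default_rng(self._out_arm_ss)
        n_b = cfg.gwas_n_outcome_arm
        geno_b = self.simulate_genotypes(n_b, rng_b)
        conf_b, x_b, med_b = self._traits(geno_b, rng_b)
        covs_b = self._covariates(n_b, rng_b, conf_b)
        lp = self._log_hazard(x_b, med_b, conf_b, covs_b)
        lp = lp - lp.mean()
        y = (rng_b.random(n_b) < expit(logit(cfg.gwas_case_fraction) + lp)).astype(int)
        sumstats["outcome"] = compute_summary_stats(
            geno_b, y, covs_b[["age", "sex"]], "binary", self.meta
        )
        ids = {
            "exposure_arm": np.array([f"exparm_{i:06d}" for i in range(n_a)]),
            "outcome_arm": np.array([f"outarm_{i:06d}" for i in range(n_b)]),
        }
        return sumstats, ids


def simulate_genotypes(
    config: SimulationConfig, n: int | None = None, seed: int | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Convenience wrapper: genotypes plus variant metadata for one cohort."""
    world = SimulatedWorld(config, seed=seed)
    rng = np.random.default_rng(world._cohort_ss)
    g = world.simulate_genotypes(config.n_individuals if n is None else n, rng)
    return g, world.meta


def simulate_traits(
    config: SimulationConfig, seed: int | None = None, n: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Convenience wrapper: a full cohort table plus its ground truth."""
    world = SimulatedWorld(config, seed=seed)
    return world.simulate_cohort(n=n)


def compute_summary_stats(
    genotypes: np.ndarray,
    trait: np.ndarray,
    covariates: pd.DataFrame | None,
    trait_type: str,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant single-variant GWAS with covariate adjustment.

    Continuous traits: OLS of the trait on each dosage column after projecting
    out the covariates (Frisch-Waugh), vectorized across variants.  Binary
    traits: one-step score estimator from the covariate-only logistic null
    model (beta = U/V with U the score and V the efficient information), the
    standard fast approximation for small per-variant effects.  Constant
    genotype columns are flagged and skipped.
    """
    if trait_type not in ("continuous", "binary"):
        raise ValueError(f"unknown trait_type {trait_type!r}")
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.shape[0] != len(y):
        raise DataError("compute_summary_stats: one trait value per individual required")
    n, j = g.shape
    keep = g.std(axis=0) > 0
    if not keep.all():
        logger.warning("compute_summary_stats: skipping %d constant genotype columns",
                       int((~keep).sum()))
    eaf = g.mean(axis=0) / 2.0
    if covariates is not None and covariates.shape[1] > 0:
        xmat = np.column_stack([np.ones(n), covariates.to_numpy(float)])
    else:
        xmat = np.ones((n, 1))
    if trait_type == "continuous":
        q, _ = np.linalg.qr(xmat)
        yr = y - q @ (q.T @ y)
        gr = g - q @ (q.T @ g)
        den = np.sum(gr**2, axis=0)
        den[~keep] = np.nan
        beta = gr.T @ yr / den
        dof = n - xmat.shape[1] - 1
        sse = np.sum(yr**2) - beta**2 * den
        se = np.sqrt(sse / (dof * den))
    else:
        glm = sm.GLM(y, xmat, family=sm.families.Binomial()).fit()
        p_null = glm.fittedvalues
        w = p_null * (1 - p_null)
        xtwx = xmat.T @ (xmat * w[:, None])
        xtwg = xmat.T @ (g * w[:, None])
        coef = np.linalg.solve(xtwx, xtwg)
        g_adj = g - xmat @ coef
        u = g_adj.T @ (y - p_null)
        v = np.sum(w[:, None] * g_adj**2, axis=0)
        v[~keep] = np.nan
        beta = u / v
        se = 1.0 / np.sqrt(v)
    from scipy import stats as _st

    pvals = 2 * _st.norm.sf(np.abs(beta / se))
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    out = meta[
        ["variant_id", "chromosome", "base_pair_location", "effect_allele", "other_allele"]
    ].copy()
    out["effect_allele_frequency"] = eaf
    out["beta"] = beta
    out["standard_error"] = se
    out["p_value"] = pvals
    out["n"] = n
    return out.loc[keep, SUMSTAT_COLUMNS].reset_index(drop=True)


def build_nested_case_control(
    cohort: pd.DataFrame,
    ratio: int = 1,
    tolerances: dict[str, float] | None = None,
    match_exact: tuple[str, ...] = ("sex",),
    seed: int | None = None,
    time_col: str = "followup_time",
    event_col: str = "event",
) -> tuple[pd.DataFrame, int]:
    """Incidence-density matched nested case-control sets within a cohort.

    Each case is matched to ``ratio`` controls sampled without replacement
    from participants still at risk at the case's event time that satisfy the
    exact-match columns and the +/- tolerances (default: same sex, age within
    0.5 years).  Cases with no eligible control are dropped with a warning.
    In the returned table ``event`` is the within-set case indicator and
    ``matched_set`` labels the sets; returns (table, n_unmatched_cases).
    """
    if tolerances is None:
        tolerances = {"age": 0.5}
    cases = cohort[cohort[event_col] == 1]
    if len(cases) == 0:
        raise DataError("build_nested_case_control: cohort contains no events")
    rng = np.random.default_rng(seed)
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    used = np.zeros(len(cohort), dtype=bool)
    pos_of = {idx: i for i, idx in enumerate(cohort.index)}
    rows, n_unmatched = [], 0
    for case_idx in cases.sort_values(time_col).index:
        ci = pos_of[case_idx]
        t = time[ci]
        eligible = (~used) & ((time > t) | ((time == t) & (event == 0)))
        eligible[ci] = False
        for col in match_exact:
            eligible &= (cohort[col] == cohort.at[case_idx, col]).to_numpy()
        for col, tol in tolerances.items():
            eligible &= (
                np.abs(cohort[col].to_numpy(float) - float(cohort.at[case_idx, col])) <= tol
            )
        pool = np.flatnonzero(eligible)
        if len(pool) < ratio:
            n_unmatched += 1
            continue
        chosen = rng.choice(pool, size=ratio, replace=False)
        used[chosen] = True
        used[ci] = True
        set_label = f"set_{case_idx}"
        rows.append((case_idx, set_label, 1))
        rows.extend((cohort.index[c], set_label, 0) for c in chosen)
    if n_unmatched:
        logger.warning(
            "build_nested_case_control: %d cases dropped (no eligible control)", n_unmatched
        )
    if not rows:
        return cohort.iloc[0:0].assign(matched_set=pd.Series(dtype=str)), n_unmatched
    idx, labels, case_flag = zip(*rows)
    out = cohort.loc[list(idx)].copy()
    out["matched_set"] = labels
    out[event_col] = case_flag
    return out.reset_index(drop=True), n_unmatched
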