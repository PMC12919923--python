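"""Synthetic-data generator: genotypes, traits, GWAS arms, matched sets."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trimed.errors import ConfigError, DataError
from trimed.simulate import (
    SimulatedWorld,
    SimulationConfig,
    build_nested_case_control,
    compute_ground_truth,
    compute_summary_stats,
)


def _world(**kw):
    defaults = dict(
        seed=7,
        n_individuals=10_000,
        n_snps_exposure=20,
        n_snps_mediator=10,
        ld_block_size=1,
        ld_rho=0.0,
    )
    defaults.update(kw)
    return SimulatedWorld(SimulationConfig(**defaults))


def _meta(j):
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i}" for i in range(j)],
            "chromosome": "1",
            "base_pair_location": np.arange(j) + 1,
            "effect_allele": "A",
            "other_allele": "G",
        }
    )


class TestGenotypes:
    def test_hwe_proportions_at_half(self):
        """At MAF 0.5 genotype frequencies are ~(0.25, 0.5, 0.25)."""
        w = _world(maf_range=(0.499999, 0.5), n_snps_exposure=5, n_snps_mediator=5)
        g = w.simulate_genotypes(10_000, np.random.default_rng(1))
        freqs = np.stack([(g == k).mean(axis=0) for k in (0, 1, 2)])
        assert np.allclose(freqs[0], 0.25, atol=0.02)
        assert np.allclose(freqs[1], 0.50, atol=0.02)
        assert np.allclose(freqs[2], 0.25, atol=0.02)

    def test_allele_frequencies_within_range(self):
        w = _world()
        g = w.simulate_genotypes(20_000, np.random.default_rng(2))
        eaf = g.mean(axis=0) / 2
        assert np.all(np.abs(eaf - w.mafs) < 4 * np.sqrt(w.mafs * (1 - w.mafs) / (2 * 20_000)))

    def test_ld_zero_gives_independent_columns(self):
        """With ld_rho=0 nearly all pairwise correlations are within 3/sqrt(n)."""
        n = 8000
        w = _world(n_snps_exposure=30, n_snps_mediator=10)
        g = w.simulate_genotypes(n, np.random.default_rng(3)).astype(float)
        corr = np.corrcoef(g, rowvar=False)
        off = np.abs(corr[np.triu_indices_from(corr, k=1)])
        assert np.mean(off < 3 / np.sqrt(n)) > 0.98
        assert off.max() < 6 / np.sqrt(n)

    def test_ld_block_correlation_matches_target(self):
        """Adjacent r^2 within a block ~ rho^2, checked against a brute-force
        pairwise-correlation oracle; across blocks ~0."""
        rho = 0.8
        w = _world(ld_block_size=5, ld_rho=rho, n_snps_exposure=20, n_snps_mediator=5)
        n = 20_000
        g = w.simulate_genotypes(n, np.random.default_rng(4)).astype(float)
        corr = np.corrcoef(g, rowvar=False)  # the oracle: plain sample correlation
        adjacent, cross = [], []
        for i in range(g.shape[1] - 1):
            if w.block_of[i] == w.block_of[i + 1]:
                adjacent.append(corr[i, i + 1])
        for i in range(g.shape[1]):
            for j in range(i + 1, g.shape[1]):
                if w.block_of[i] != w.block_of[j]:
                    cross.append(corr[i, j])
        assert np.allclose(np.asarray(adjacent) ** 2, rho**2, atol=0.05)
        assert np.abs(np.asarray(cross)).max() < 6 / np.sqrt(n)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            SimulationConfig(ld_rho=1.0)
        with pytest.raises(ConfigError):
            SimulationConfig(n_individuals=-5)
        with pytest.raises(ConfigError):
            SimulationConfig(h2_exposure=0.9, confounder_strength=0.5)  # budget > 1


class TestTraits:
    def test_null_model_event_rate_and_truth(self):
        """With every effect zero the event rate is 1 - exp(-h0*T)."""
        cfg = SimulationConfig(
            seed=5,
            n_individuals=40_000,
            n_snps_exposure=5,
            n_snps_mediator=5,
            ld_block_size=1,
            ld_rho=0.0,
            beta_xm=0.0,
            beta_my=0.0,
            beta_xy_direct=0.0,
            confounder_strength=0.0,
            age_log_hr=0.0,
            male_log_hr=0.0,
            baseline_hazard=2e-3,
            followup_years=10.0,
        )
        cohort, truth = SimulatedWorld(cfg).simulate_cohort()
        expected = 1 - np.exp(-2e-3 * 10.0)
        rate = cohort["event"].mean()
        assert abs(rate - expected) < 4 * np.sqrt(expected * (1 - expected) / len(cohort))
        assert truth.total_log_effect == 0.0
        assert truth.indirect_log_effect == 0.0

    def test_ground_truth_arithmetic(self):
        truth = compute_ground_truth(
            SimulationConfig(beta_xm=0.5, beta_my=0.4, beta_xy_direct=0.2)
        )
        assert truth.indirect_log_effect == pytest.approx(0.20)
        assert truth.total_log_effect == pytest.approx(0.40)
        assert truth.proportion_mediated == pytest.approx(0.50)
        assert truth.direct_log_effect == pytest.approx(0.20)

    def test_ground_truth_matches_numeric_integration(self):
        """The closed-form total effect agrees with a Monte-Carlo evaluation of
        the interventional hazard ratio over the simulated DAG within 1%."""
        cfg = SimulationConfig(beta_xm=0.35, beta_my=0.4, beta_xy_direct=0.225,
                               confounder_strength=0.3)
        truth = compute_ground_truth(cfg)
        rng = np.random.default_rng(99)
        n = 400_000
        c = rng.normal(size=n)
        noise_m = cfg._noise_sd_mediators()[0]

        def mean_hazard(x):
            m = cfg.beta_xm[0] * x + cfg.confounder_strength * c + noise_m * rng.normal(size=n)
            return np.mean(np.exp(cfg.beta_my[0] * m + cfg.beta_xy_direct * x
                                  + cfg.confounder_strength * c))

        log_ratio = np.log(mean_hazard(0.5) / mean_hazard(-0.5))
        assert log_ratio == pytest.approx(truth.total_log_effect, rel=0.01)

    def test_traits_have_unit_variance(self, small_cohort):
        cohort, _ = small_cohort
        assert cohort["bmi"].var() == pytest.approx(1.0, abs=0.05)
        assert cohort["mediator"].var() == pytest.approx(1.0, abs=0.05)

    def test_default_event_count_near_target(self):
        """The default world yields ~1,400 events per 100,000 participants."""
        cohort, _ = SimulatedWorld(SimulationConfig(
            seed=12, n_snps_exposure=10, n_snps_mediator=5, ld_block_size=1, ld_rho=0.0
        )).simulate_cohort()
        assert 1200 <= cohort["event"].sum() <= 1650

    def test_seed_determinism(self):
        a, _ = _world(seed=21).simulate_cohort(n=2000)
        b, _ = _world(seed=21).simulate_cohort(n=2000)
        pd.testing.assert_frame_equal(a, b)

    def test_two_sample_arms_disjoint(self, small_world):
        _, ids = small_world.simulate_gwas_arms()
        assert set(ids["exposure_arm"]).isdisjoint(ids["outcome_arm"])


class TestSummaryStats:
    def test_null_trait_pvalues_uniform(self):
        rng = np.random.default_rng(8)
        j, n = 400, 3000
        g = rng.binomial(2, 0.3, size=(n, j))
        y = rng.normal(size=n)
        ss = compute_summary_stats(g, y, None, "continuous", _meta(j))
        frac = (ss["p_value"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / j)

    def test_chi_square_matches_noncentrality(self):
        """One causal variant with r^2=0.01 at n=50,000: chi^2 ~ n*r^2 = 500."""
        rng = np.random.default_rng(9)
        n = 50_000
        g = rng.binomial(2, 0.3, size=(n, 1)).astype(float)
        gv = (g[:, 0] - g[:, 0].mean()) / g[:, 0].std()
        y = 0.1 * gv + np.sqrt(1 - 0.01) * rng.normal(size=n)
        ss = compute_summary_stats(g, y, None, "continuous", _meta(1))
        chi2 = float((ss["beta"] / ss["standard_error"]).iloc[0] ** 2)
        assert 365 < chi2 < 635  # +/- 3 sd of a noncentral chi-square, ncp 500

    def test_allele_recoding_flips_beta(self):
        rng = np.random.default_rng(10)
        n, j = 5000, 3
        g = rng.binomial(2, 0.4, size=(n, j))
        y = 0.2 * g[:, 0] + rng.normal(size=n)
        a = compute_summary_stats(g, y, None, "continuous", _meta(j))
        b = compute_summary_stats(2 - g, y, None, "continuous", _meta(j))
        assert np.allclose(a["beta"], -b["beta"])
        assert np.allclose(a["p_value"], b["p_value"])

    def test_constant_column_skipped(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.4, size=(500, 3))
        g[:, 1] = 2
        ss = compute_summary_stats(g, rng.normal(size=500), None, "continuous", _meta(3))
        assert list(ss["variant_id"]) == ["rs0", "rs2"]

    def test_binary_score_estimator_recovers_log_odds(self):
        """One-step logistic betas track the planted conditional log-odds."""
        rng = np.random.default_rng(12)
        n, j = 60_000, 10
        g = rng.binomial(2, 0.3, size=(n, j)).astype(float)
        alpha = np.zeros(j)
        alpha[0] = 0.15
        lp = -2.5 + g @ alpha
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
        ss = compute_summary_stats(g, y, None, "binary", _meta(j))
        est = ss.loc[ss["variant_id"] == "rs0", "beta"].iloc[0]
        se = ss.loc[ss["variant_id"] == "rs0", "standard_error"].iloc[0]
        assert abs(est - 0.15) < 3 * se


class TestNestedCaseControl:
    def test_matched_pairs_satisfy_constraints(self, small_cohort):
        """Brute-force check: every control matches sex exactly, age within
        tolerance, and was at risk at its case's event time."""
        cohort, _ = small_cohort
        matched, n_unmatched = build_nested_case_control(
            cohort, ratio=1, tolerances={"age": 0.5}, seed=3
        )
        n_cases_total = int(cohort["event"].sum())
        sets = matched.groupby("matched_set")
        assert len(sets) <= n_cases_total
        assert len(sets) + n_unmatched == n_cases_total
        orig = cohort.set_index("id")
        for _, grp in sets:
            case = grp[grp["event"] == 1]
            ctrl = grp[grp["event"] == 0]
            assert len(case) == 1 and len(ctrl) == 1
            case, ctrl = case.iloc[0], ctrl.iloc[0]
            assert case["sex"] == ctrl["sex"]
            assert abs(case["age"] - ctrl["age"]) <= 0.5
            t_case = orig.loc[case["id"], "followup_time"]
            t_ctrl = orig.loc[ctrl["id"], "followup_time"]
            assert (t_ctrl > t_case) or (
                t_ctrl == t_case and orig.loc[ctrl["id"], "event"] == 0
            )
        # controls sampled without replacement (an individual may still appear
        # once as a control and later as a case - incidence-density sampling)
        controls = matched.loc[matched["event"] == 0, "id"]
        assert controls.is_unique
        cases = matched.loc[matched["event"] == 1, "id"]
        assert cases.is_unique

    def test_zero_tolerance_on_continuous_matches_nothing(self, small_cohort):
        cohort, _ = small_cohort
        matched, n_unmatched = build_nested_case_control(
            cohort, ratio=1, tolerances={"age": 0.0}, seed=3
        )
        assert len(matched) == 0
        assert n_unmatched == int(cohort["event"].sum())

    def test_requires_events(self, small_cohort):
        cohort, _ = small_cohort
        with pytest.raises(DataError):
            build_nested_case_control(cohort[cohort["event"] == 0], seed=1)
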