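"""Shared builders and fixtures for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trimed.simulate import SimulationConfig, SimulatedWorld
from trimed.sumstats import HarmonizedSet, SUMSTAT_COLUMNS


def make_harmonized(bx, sx, by, sy, n_exp=50_000, n_out=50_000, ids=None) -> HarmonizedSet:
    """Assemble a HarmonizedSet directly from effect arrays."""
    bx = np.asarray(bx, float)
    j = len(bx)
    table = pd.DataFrame(
        {
            "variant_id": ids if ids is not None else [f"v{i}" for i in range(j)],
            "chromosome": "1",
            "base_pair_location": np.arange(j) * 1_000_000 + 1,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf_exposure": 0.3,
            "beta_exposure": bx,
            "se_exposure": np.asarray(sx, float),
            "p_exposure": 1e-9,
            "n_exposure": n_exp,
            "eaf_outcome": 0.3,
            "beta_outcome": np.asarray(by, float),
            "se_outcome": np.asarray(sy, float),
            "p_outcome": 0.5,
            "n_outcome": n_out,
        }
    )
    return HarmonizedSet(table=table, dropped=pd.DataFrame(columns=["variant_id", "reason"]))


def random_harmonized(rng: np.random.Generator, j: int = 20, slope: float = 0.4) -> HarmonizedSet:
    gamma = rng.uniform(0.05, 0.2, j) * rng.choice([-1, 1], j)
    sx = rng.uniform(0.004, 0.01, j)
    sy = rng.uniform(0.02, 0.06, j)
    bx = rng.normal(gamma, sx)
    by = rng.normal(slope * gamma, sy)
    return make_harmonized(bx, sx, by, sy)


def random_sumstats(rng: np.random.Generator, j: int = 50, n: int = 50_000) -> pd.DataFrame:
    """A synthetic sumstats frame with a mix of significant and null variants."""
    alleles = np.array([("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")], dtype=object)
    pick = rng.integers(0, 4, j)
    beta = rng.normal(0, 0.08, j)
    se = rng.uniform(0.005, 0.02, j)
    from scipy import stats

    z = beta / se
    p = np.clip(2 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    return pd.DataFrame(
        {
            "variant_id": [f"rs{i:04d}" for i in range(j)],
            "chromosome": (1 + rng.integers(0, 4, j)).astype(str),
            "base_pair_location": rng.integers(1, 50_000_000, j),
            "effect_allele": alleles[pick, 0],
            "other_allele": alleles[pick, 1],
            "effect_allele_frequency": rng.uniform(0.05, 0.95, j),
            "beta": beta,
            "standard_error": se,
            "p_value": p,
            "n": n,
        }
    )[SUMSTAT_COLUMNS]


def make_instrument_set(rows) -> "InstrumentSet":
    """Wrap sumstats rows (dicts or a DataFrame) as an InstrumentSet."""
    from trimed.sumstats import InstrumentSet

    return InstrumentSet(
        exposure_name="exp",
        variants=pd.DataFrame(rows),
        p_threshold=5e-8,
        r2_threshold=0.01,
        window_kb=10_000,
    )


def make_mv_harmonized(b1, s1, b2, s2, by, sy, n=50_000) -> HarmonizedSet:
    """Two-exposure harmonized set for multivariable MR tests."""
    h = make_harmonized(b1, s1, by, sy)
    t = h.table.rename(
        columns={"beta_exposure": "beta_exposure_x1", "se_exposure": "se_exposure_x1"}
    )
    t["beta_exposure_x2"] = np.asarray(b2, float)
    t["se_exposure_x2"] = np.asarray(s2, float)
    return HarmonizedSet(
        table=t, dropped=h.dropped, exposure_names=("x1", "x2"), outcome_name="outcome"
    )


def brute_force_clump(ss, ld, p_threshold, r2_threshold, window_kb):
    """Independent clumping oracle: literal greedy pruning with explicit scans."""
    cand = ss[ss["p_value"] <= p_threshold].copy()
    order = cand.sort_values(["p_value", "chromosome", "base_pair_location", "variant_id"])
    kept, removed = [], set()
    for _, row in order.iterrows():
        if row["variant_id"] in removed:
            continue
        kept.append(row["variant_id"])
        for _, other in order.iterrows():
            if other["variant_id"] == row["variant_id"]:
                continue
            if other["chromosome"] != row["chromosome"]:
                continue
            if abs(other["base_pair_location"] - row["base_pair_location"]) >= window_kb * 1000:
                continue
            r2 = ld.r2(row["variant_id"], other["variant_id"], default=1.0) if ld else 1.0
            if r2 > r2_threshold:
                removed.add(other["variant_id"])
    return kept


@pytest.fixture(scope="session")
def small_world():
    """A modest simulated world with enriched event rate, shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_individuals=12_000,
        n_snps_exposure=20,
        n_snps_mediator=10,
        ld_block_size=1,
        ld_rho=0.0,
        confounder_strength=0.0,
        baseline_hazard=2.9e-3,
        gwas_n_exposure_arm=15_000,
        gwas_n_outcome_arm=15_000,
    )
    return SimulatedWorld(cfg)


@pytest.fixture(scope="session")
def small_cohort(small_world):
    cohort, truth = small_world.simulate_cohort()
    return cohort, truth
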