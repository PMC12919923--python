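"""Report writers: deterministic tab-delimited tables, JSON summary, manifest.

Human-facing tables carry floats at 6 significant digits with fixed column
order; summary.json keeps full precision for machine reuse.  The run manifest
(seed, config hash, package version, per-file checksums) suffices to
reproduce a run: identical seed and configuration give byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import trimed
from trimed import config as config_mod
from trimed.triangulate import ResultBundle

FLOAT_FORMAT = "%.6g"


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def mediation_table(bundle: ResultBundle) -> pd.DataFrame:
    """One row per (framework, mediator) mediation result, Tables M/N layout."""
    rows = []
    for res in bundle.mediation_results:
        rows.append(
            {
                "framework": res.framework,
                "mediator": res.mediator,
                "total_beta": res.total.beta,
                "total_se": res.total.se,
                "total_rr": float(np.exp(res.total.beta)),
                "direct_beta": res.direct.beta,
                "direct_se": res.direct.se,
                "direct_minus_indirect": res.direct_minus,
                "indirect_beta": res.indirect.beta,
                "indirect_se": res.indirect.se,
                "indirect_ci_low": res.indirect.ci_low,
                "indirect_ci_high": res.indirect.ci_high,
                "indirect_rr": float(np.exp(res.indirect.beta)),
                "proportion_mediated": res.proportion.pm,
                "pm_ci_low": res.proportion.ci_low,
                "pm_ci_high": res.proportion.ci_high,
                "pm_out_of_range": res.proportion.out_of_range,
                "suppressed": res.suppressed,
                "method_notes": res.method_notes,
            }
        )
    cols = [
        "framework", "mediator", "total_beta", "total_se", "total_rr",
        "direct_beta", "direct_se", "direct_minus_indirect",
        "indirect_beta", "indirect_se", "indirect_ci_low", "indirect_ci_high",
        "indirect_rr", "proportion_mediated", "pm_ci_low", "pm_ci_high",
        "pm_out_of_range", "suppressed", "method_notes",
    ]
    return pd.DataFrame(rows, columns=cols)


def triangulation_table(bundle: ResultBundle) -> pd.DataFrame:
    rows = []
    for rec in bundle.triangulation:
        rows.append(
            {
                "mediator": rec.mediator,
                "beta_cohort": rec.cohort_estimate.beta,
                "p_cohort": rec.cohort_estimate.p,
                "scale_cohort": rec.cohort_estimate.scale,
                "adjustment_cohort": ",".join(rec.cohort_estimate.adjustment),
                "beta_mr": rec.mr_estimate.beta,
                "p_mr": rec.mr_estimate.p,
                "directionally_concordant": rec.directionally_concordant,
                "both_significant": rec.both_significant,
                "eligible": rec.eligible,
                "pleiotropy_flag": rec.pleiotropy_flag,
            }
        )
    cols = [
        "mediator", "beta_cohort", "p_cohort", "scale_cohort", "adjustment_cohort",
        "beta_mr", "p_mr", "directionally_concordant", "both_significant",
        "eligible", "pleiotropy_flag",
    ]
    return pd.DataFrame(rows, columns=cols)


def summary_dict(bundle: ResultBundle) -> dict:
    """Full-precision machine-readable summary of the run."""
    return {
        "seed": bundle.seed,
        "ground_truth": dataclasses.asdict(bundle.truth),
        "arm_beta_correlation_r2": bundle.arm_beta_correlation,
        "n_eligible": int(sum(r.eligible for r in bundle.triangulation)),
        "diagnostics": bundle.diagnostics,
        "risk": bundle.risk_table.to_dict(orient="records"),
        "bmi_mediator": bundle.bmi_mediator_table.to_dict(orient="records"),
        "mediation": mediation_table(bundle).to_dict(orient="records"),
    }


def write_tables(bundle: ResultBundle, out_dir, config=None) -> dict:
    """Write all result tables plus summary.json and manifest.json.

    Returns the manifest dict.  Table files are deterministic given the seed
    and configuration; the manifest's checksum block covers them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "bmi_mediators.tsv": bundle.bmi_mediator_table,
        "risk.tsv": bundle.risk_table,
        "triangulation.tsv": triangulation_table(bundle),
        "mediation.tsv": mediation_table(bundle),
        "edges.tsv": bundle.edges,
        "dropped_variants.tsv": bundle.dropped,
    }
    for name, df in files.items():
        _write_tsv(df, out / name)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary_dict(bundle), fh, indent=2, default=_json_default)
    checksums = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest()
        for name in [*files, "summary.json"]
    }
    config_hash = None
    if config is not None:
        normalized = yaml.safe_dump(config_mod.normalize(config), sort_keys=True)
        config_hash = hashlib.sha256(normalized.encode()).hexdigest()
    manifest = {
        "seed": bundle.seed,
        "config_hash": config_hash,
        "software_version": trimed.__version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "checksums": checksums,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
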