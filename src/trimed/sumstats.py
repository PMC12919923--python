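"""GWAS summary statistics: I/O, instrument selection and allele harmonization.

Collections of per-variant associations are held as pandas DataFrames with the
GWAS-SSF-like schema in :data:`SUMSTAT_COLUMNS`.  Instrument selection follows
the conventional genome-wide pipeline: a p-value screen (default 5e-8) followed
by greedy LD clumping (default r^2 > 0.01 pruned within a 10,000 kb window).
Harmonization aligns exposure and outcome effects onto the exposure's effect
allele, resolving strand flips and dropping ambiguous palindromic variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from trimed.errors import DataError

logger = logging.getLogger(__name__)

#: Column order of the tab-delimited summary-statistics files read and written
#: by this module (one row per variant-trait association).
SUMSTAT_COLUMNS = [
    "variant_id",
    "chromosome",
    "base_pair_location",
    "effect_allele",
    "other_allele",
    "effect_allele_frequency",
    "beta",
    "standard_error",
    "p_value",
    "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class VariantAssociation:
    """A single variant's summary-level association with one trait."""

    variant_id: str
    chromosome: str
    base_pair_location: int
    effect_allele: str
    other_allele: str
    effect_allele_frequency: float
    beta: float
    standard_error: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.standard_error <= 0:
            raise DataError(f"{self.variant_id}: standard_error must be > 0")
        if self.effect_allele == self.other_allele:
            raise DataError(f"{self.variant_id}: alleles must be distinct")
        if not (0 < self.p_value <= 1):
            raise DataError(f"{self.variant_id}: p_value outside (0, 1]")


@dataclass
class InstrumentSet:
    """Genetic instruments for one exposure after screening and clumping."""

    exposure_name: str
    variants: pd.DataFrame
    p_threshold: float
    r2_threshold: float
    window_kb: float

    @property
    def empty(self) -> bool:
        return len(self.variants) == 0

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to the exposure's effect allele.

    ``table`` has one row per retained variant with columns
    ``beta_exposure``/``se_exposure`` (or ``beta_exposure_<name>`` per exposure
    for the multivariable case), ``beta_outcome``, ``se_outcome``, allele
    frequencies and per-arm sample sizes.  ``dropped`` records a reason code
    (missing_in_outcome, palindromic_ambiguous, allele_mismatch,
    presso_outlier, steiger_reverse) per removed variant.
    """

    table: pd.DataFrame
    dropped: pd.DataFrame
    exposure_names: tuple[str, ...] = ("exposure",)
    outcome_name: str = "outcome"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.table["beta_exposure"].to_numpy(float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.table["se_exposure"].to_numpy(float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.table["beta_outcome"].to_numpy(float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.table["se_outcome"].to_numpy(float)

    def drop_variants(self, variant_ids, reason: str) -> "HarmonizedSet":
        """Return a copy with ``variant_ids`` moved to ``dropped`` under ``reason``."""
        ids = set(variant_ids)
        mask = self.table["variant_id"].isin(ids)
        newly = pd.DataFrame(
            {"variant_id": self.table.loc[mask, "variant_id"], "reason": reason}
        )
        return HarmonizedSet(
            table=self.table.loc[~mask].reset_index(drop=True),
            dropped=pd.concat([self.dropped, newly], ignore_index=True),
            exposure_names=self.exposure_names,
            outcome_name=self.outcome_name,
        )


def read_sumstats(path, column_map: dict[str, str] | None = None, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited summary-statistics file into the standard schema.

    ``column_map`` maps file column names onto :data:`SUMSTAT_COLUMNS` entries.
    Malformed rows (non-positive se, p outside (0,1], identical or non-ACGT
    alleles, missing numerics) are dropped, logged and counted in
    ``df.attrs["n_rejected"]``.
    """
    raw = pd.read_csv(path, sep=sep, dtype={"chromosome": str})
    if column_map:
        raw = raw.rename(columns=column_map)
    missing = [c for c in SUMSTAT_COLUMNS if c not in raw.columns]
    if missing:
        raise DataError(f"missing required columns: {missing}")
    df = raw[SUMSTAT_COLUMNS].copy()
    for col in ("effect_allele_frequency", "beta", "standard_error", "p_value"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    df["chromosome"] = df["chromosome"].astype(str)
    clean, rejected = validate_sumstats(df)
    if len(rejected):
        logger.warning(
            "read_sumstats(%s): rejected %d malformed rows (%s)",
            path,
            len(rejected),
            rejected["reason"].value_counts().to_dict(),
        )
    clean.attrs["n_rejected"] = len(rejected)
    clean.attrs["rejected"] = rejected
    return clean


def validate_sumstats(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sumstats frame into valid rows and rejects with reason codes."""
    reasons = pd.Series("", index=df.index, dtype=object)
    numeric = ["effect_allele_frequency", "beta", "standard_error", "p_value", "n"]
    bad_num = df[numeric].isna().any(axis=1)
    reasons[bad_num] = "non_numeric"
    bad_se = (~bad_num) & (df["standard_error"] <= 0)
    reasons[bad_se] = "non_positive_se"
    bad_p = (~bad_num) & ((df["p_value"] <= 0) | (df["p_value"] > 1))
    reasons[bad_p] = "p_out_of_range"
    valid_alleles = df["effect_allele"].isin(_COMPLEMENT) & df["other_allele"].isin(_COMPLEMENT)
    bad_allele = (~valid_alleles) | (df["effect_allele"] == df["other_allele"])
    reasons[bad_allele] = "bad_alleles"
    bad_eaf = (~bad_num) & (
        (df["effect_allele_frequency"] <= 0) | (df["effect_allele_frequency"] >= 1)
    )
    reasons[bad_eaf] = "eaf_out_of_range"
    bad = reasons != ""
    rejected = df[bad].copy()
    rejected["reason"] = reasons[bad]
    clean = df[~bad].reset_index(drop=True)
    clean["base_pair_location"] = clean["base_pair_location"].astype(int)
    clean["n"] = clean["n"].astype(int)
    return clean, rejected.reset_index(drop=True)


def write_sumstats(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a sumstats frame in the standard tab-delimited column order."""
    df[SUMSTAT_COLUMNS].to_csv(path, sep=sep, index=False)


class LDTable:
    """Pairwise LD (r^2) lookup, from a pair list or a genotype matrix.

    Missing pairs return ``default`` (``None`` unless overridden); the clumping
    routine treats a missing pair within the window as r^2 = 1 so that
    possibly-correlated instruments are never retained.
    """

    def __init__(self, pairs: pd.DataFrame | None = None):
        self._r2: dict[frozenset, float] = {}
        if pairs is not None:
            for id_a, id_b, r2 in pairs[["id_a", "id_b", "r2"]].itertuples(index=False):
                self._r2[frozenset((id_a, id_b))] = float(r2)

    @classmethod
    def from_genotypes(cls, genotypes: np.ndarray, variant_ids) -> "LDTable":
        """All-pairs squared Pearson correlation of genotype dosage columns."""
        ld = cls()
        keep = np.std(genotypes, axis=0) > 0
        ids = np.asarray(variant_ids)
        corr = np.corrcoef(np.asarray(genotypes, dtype=float)[:, keep], rowvar=False)
        kept_ids = ids[keep]
        r2 = corr**2
        for i in range(len(kept_ids)):
            for j in range(i + 1, len(kept_ids)):
                ld._r2[frozenset((kept_ids[i], kept_ids[j]))] = float(r2[i, j])
        return ld

    @classmethod
    def read(cls, path, sep: str = "\t") -> "LDTable":
        return cls(pd.read_csv(path, sep=sep))

    def write(self, path, sep: str = "\t") -> None:
        rows = [(sorted(k)[0], sorted(k)[1], v) for k, v in self._r2.items()]
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep=sep, index=False)

    def r2(self, id_a: str, id_b: str, default: float | None = None) -> float | None:
        if id_a == id_b:
            return 1.0
        return self._r2.get(frozenset((id_a, id_b)), default)


def select_instruments(
    sumstats: pd.DataFrame,
    p_threshold: float = 5e-8,
    ld: LDTable | None = None,
    r2_threshold: float = 0.01,
    window_kb: float = 10_000,
    exposure_name: str = "exposure",
) -> InstrumentSet:
    """Screen to genome-wide significance then greedily LD-clump.

    Candidates with p > ``p_threshold`` are excluded.  The remainder are sorted
    by ascending p (ties broken by chromosome, position, variant_id); the best
    remaining variant is accepted and all same-chromosome variants within
    ``window_kb`` with r^2 > ``r2_threshold`` are discarded.  Missing LD for a
    within-window pair is treated as r^2 = 1 (conservative drop).
    """
    cand = sumstats[sumstats["p_value"] <= p_threshold].copy()
    cand = cand.sort_values(
        ["p_value", "chromosome", "base_pair_location", "variant_id"]
    ).reset_index(drop=True)
    kept_rows = []
    alive = np.ones(len(cand), dtype=bool)
    window_bp = window_kb * 1000.0
    chrom = cand["chromosome"].to_numpy()
    pos = cand["base_pair_location"].to_numpy(float)
    vid = cand["variant_id"].to_numpy()
    for i in range(len(cand)):
        if not alive[i]:
            continue
        kept_rows.append(i)
        in_window = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) < window_bp)
        in_window[i] = False
        for j in np.flatnonzero(in_window):
            r2 = 1.0 if ld is None else ld.r2(vid[i], vid[j], default=1.0)
            if r2 > r2_threshold:
                alive[j] = False
    variants = cand.iloc[kept_rows].reset_index(drop=True)
    if len(variants) == 0:
        logger.warning("select_instruments(%s): no variants pass selection", exposure_name)
    return InstrumentSet(
        exposure_name=exposure_name,
        variants=variants,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        window_kb=window_kb,
    )


def _is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT.get(ea) == oa


def _align_one(exp_row, out_row, w: float):
    """Orient one outcome record onto the exposure's effect allele.

    Returns (sign, flip_eaf, reason). ``sign`` multiplies the outcome beta;
    ``reason`` is non-empty when the variant must be dropped.
    """
    ea_x, oa_x = exp_row.effect_allele, exp_row.other_allele
    ea_y, oa_y = out_row.effect_allele, out_row.other_allele
    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return 0.0, False, "allele_mismatch"
        eaf_x = exp_row.effect_allele_frequency
        eaf_y = out_row.effect_allele_frequency
        if abs(eaf_x - 0.5) <= w or abs(eaf_y - 0.5) <= w:
            return 0.0, False, "palindromic_ambiguous"
        # label-based alignment first, then use frequency to resolve strand
        flip = ea_y != ea_x
        eaf_y_aligned = 1.0 - eaf_y if flip else eaf_y
        if (eaf_x - 0.5) * (eaf_y_aligned - 0.5) < 0:
            flip = not flip
        return (-1.0 if flip else 1.0), flip, ""
    if {ea_y, oa_y} == {ea_x, oa_x}:
        if ea_y == ea_x:
            return 1.0, False, ""
        return -1.0, True, ""
    comp = {_COMPLEMENT[ea_y], _COMPLEMENT[oa_y]}
    if comp == {ea_x, oa_x}:
        if _COMPLEMENT[ea_y] == ea_x:
            return 1.0, False, ""
        return -1.0, True, ""
    return 0.0, False, "allele_mismatch"


def harmonize(
    instruments: InstrumentSet,
    outcome: pd.DataFrame,
    palindromic_eaf_window: float = 0.08,
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Align outcome effects to the exposure instruments' effect alleles.

    Matching is by ``variant_id``.  Swapped alleles flip the outcome beta sign
    and complement the outcome frequency; strand flips are resolved through
    allele complements, and palindromic (A/T, C/G) variants are retained only
    when both frequencies fall outside ``0.5 +/- palindromic_eaf_window``.
    """
    exp = instruments.variants
    if exp["variant_id"].duplicated().any():
        raise DataError("duplicate variant identifiers in exposure instruments")
    if outcome["variant_id"].duplicated().any():
        raise DataError("duplicate variant identifiers in outcome summary statistics")
    out_idx = outcome.set_index("variant_id")
    rows, dropped = [], []
    for exp_row in exp.itertuples(index=False):
        vid = exp_row.variant_id
        if vid not in out_idx.index:
            dropped.append((vid, "missing_in_outcome"))
            continue
        out_row = out_idx.loc[vid]
        sign, flip_eaf, reason = _align_one(exp_row, out_row, palindromic_eaf_window)
        if reason:
            dropped.append((vid, reason))
            continue
        eaf_y = out_row.effect_allele_frequency
        rows.append(
            {
                "variant_id": vid,
                "chromosome": exp_row.chromosome,
                "base_pair_location": exp_row.base_pair_location,
                "effect_allele": exp_row.effect_allele,
                "other_allele": exp_row.other_allele,
                "eaf_exposure": exp_row.effect_allele_frequency,
                "beta_exposure": exp_row.beta,
                "se_exposure": exp_row.standard_error,
                "p_exposure": exp_row.p_value,
                "n_exposure": exp_row.n,
                "eaf_outcome": 1.0 - eaf_y if flip_eaf else eaf_y,
                "beta_outcome": sign * out_row.beta,
                "se_outcome": out_row.standard_error,
                "p_outcome": out_row.p_value,
                "n_outcome": out_row.n,
            }
        )
    table = pd.DataFrame(rows)
    return HarmonizedSet(
        table=table,
        dropped=pd.DataFrame(dropped, columns=["variant_id", "reason"]),
        exposure_names=(instruments.exposure_name,),
        outcome_name=outcome_name,
    )


def harmonize_mvmr(
    exposures: dict[str, pd.DataFrame],
    outcome: pd.DataFrame,
    instruments: InstrumentSet,
    palindromic_eaf_window: float = 0.08,
    outcome_name: str = "outcome",
) -> HarmonizedSet:
    """Harmonize several exposures and one outcome onto shared instruments.

    ``instruments`` is the (already clumped) union instrument set; a variant is
    retained only if present and alignable in every exposure and the outcome.
    Columns are ``beta_exposure_<name>``/``se_exposure_<name>`` per exposure.
    """
    base = harmonize(instruments, outcome, palindromic_eaf_window, outcome_name)
    table = base.table
    dropped = base.dropped
    for name, ss in exposures.items():
        aligned = harmonize(
            InstrumentSet(
                exposure_name=instruments.exposure_name,
                variants=instruments.variants[
                    instruments.variants["variant_id"].isin(table["variant_id"])
                ].reset_index(drop=True),
                p_threshold=instruments.p_threshold,
                r2_threshold=instruments.r2_threshold,
                window_kb=instruments.window_kb,
            ),
            ss,
            palindromic_eaf_window,
            outcome_name=name,
        )
        sub = aligned.table[["variant_id", "beta_outcome", "se_outcome", "n_outcome"]].rename(
            columns={
                "beta_outcome": f"beta_exposure_{name}",
                "se_outcome": f"se_exposure_{name}",
                "n_outcome": f"n_exposure_{name}",
            }
        )
        miss = aligned.dropped.copy()
        miss["reason"] = miss["reason"].str.replace("missing_in_outcome", f"missing_in_{name}")
        dropped = pd.concat([dropped, miss], ignore_index=True)
        table = table.merge(sub, on="variant_id", how="inner")
    return HarmonizedSet(
        table=table.reset_index(drop=True),
        dropped=dropped,
        exposure_names=tuple(exposures),
        outcome_name=outcome_name,
    )


def instrument_strength(h: HarmonizedSet) -> tuple[pd.Series, float]:
    """Per-variant univariable F statistics, F_j = (beta_j / se_j)^2, and mean F."""
    if len(h) == 0:
        raise DataError("instrument_strength: empty harmonized set")
    f = (h.beta_exposure / h.se_exposure) ** 2
    per_variant = pd.Series(f, index=h.table["variant_id"], name="F")
    return per_variant, float(np.mean(f))
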