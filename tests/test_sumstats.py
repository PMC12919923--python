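"""Summary-statistics I/O, instrument selection, harmonization, strength."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from trimed.errors import DataError
from trimed.sumstats import (
    LDTable,
    harmonize,
    instrument_strength,
    read_sumstats,
    select_instruments,
    write_sumstats,
)
from conftest import brute_force_clump, make_harmonized, make_instrument_set, random_sumstats


def _ss_row(vid, chrom, pos, ea, oa, eaf, beta, se, p, n=50_000):
    return dict(
        variant_id=vid,
        chromosome=str(chrom),
        base_pair_location=pos,
        effect_allele=ea,
        other_allele=oa,
        effect_allele_frequency=eaf,
        beta=beta,
        standard_error=se,
        p_value=p,
        n=n,
    )


class TestIO:
    def test_write_read_roundtrip_normalizes_case(self, tmp_path):
        """Lower-case alleles are upper-cased and survive a write-read cycle."""
        df = pd.DataFrame(
            [
                _ss_row("rs1", 1, 100, "a", "g", 0.3, 0.1, 0.02, 1e-9),
                _ss_row("rs2", 2, 200, "C", "t", 0.4, -0.05, 0.01, 1e-4),
                _ss_row("rs3", 3, 300, "T", "A", 0.2, 0.0, 0.01, 1.0),
            ]
        )
        p1 = tmp_path / "a.tsv"
        df.to_csv(p1, sep="\t", index=False)
        loaded = read_sumstats(p1)
        assert len(loaded) == 3
        assert list(loaded["effect_allele"]) == ["A", "C", "T"]
        p2 = tmp_path / "b.tsv"
        write_sumstats(loaded, p2)
        again = read_sumstats(p2)
        pd.testing.assert_frame_equal(loaded, again)

    def test_malformed_rows_rejected_with_reason(self, tmp_path):
        df = pd.DataFrame(
            [
                _ss_row("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9),
                _ss_row("rs_bad_se", 1, 200, "A", "G", 0.3, 0.1, 0.0, 1e-9),
                _ss_row("rs_bad_allele", 1, 300, "A", "A", 0.3, 0.1, 0.02, 1e-9),
                _ss_row("rs_bad_p", 1, 400, "A", "G", 0.3, 0.1, 0.02, 1.5),
            ]
        )
        p = tmp_path / "m.tsv"
        df.to_csv(p, sep="\t", index=False)
        loaded = read_sumstats(p)
        assert list(loaded["variant_id"]) == ["rs1"]
        assert loaded.attrs["n_rejected"] == 3
        reasons = set(loaded.attrs["rejected"]["reason"])
        assert reasons == {"non_positive_se", "bad_alleles", "p_out_of_range"}

    def test_missing_column_raises(self, tmp_path):
        p = tmp_path / "x.tsv"
        pd.DataFrame({"variant_id": ["rs1"]}).to_csv(p, sep="\t", index=False)
        with pytest.raises(DataError, match="missing required columns"):
            read_sumstats(p)


class TestClumping:
    def test_subthreshold_variant_excluded(self):
        """p = 6e-8 fails the genome-wide screen at 5e-8."""
        ss = pd.DataFrame([_ss_row("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, 6e-8)])
        inst = select_instruments(ss, p_threshold=5e-8)
        assert inst.empty

    def test_correlated_neighbour_pruned(self):
        """Of two correlated nearby variants the smaller p-value survives."""
        ss = pd.DataFrame(
            [
                _ss_row("rs_best", 1, 10_000, "A", "G", 0.3, 0.1, 0.01, 1e-10),
                _ss_row("rs_other", 1, 15_000, "A", "G", 0.3, 0.1, 0.012, 1e-9),
            ]
        )
        ld = LDTable(pd.DataFrame({"id_a": ["rs_best"], "id_b": ["rs_other"], "r2": [0.5]}))
        inst = select_instruments(ss, ld=ld, r2_threshold=0.01, window_kb=10_000)
        assert list(inst.variants["variant_id"]) == ["rs_best"]

    def test_low_ld_pair_both_kept(self):
        ss = pd.DataFrame(
            [
                _ss_row("rs_a", 1, 10_000, "A", "G", 0.3, 0.1, 0.01, 1e-10),
                _ss_row("rs_b", 1, 15_000, "A", "G", 0.3, 0.1, 0.012, 1e-9),
            ]
        )
        ld = LDTable(pd.DataFrame({"id_a": ["rs_a"], "id_b": ["rs_b"], "r2": [0.005]}))
        inst = select_instruments(ss, ld=ld)
        assert len(inst) == 2

    def test_missing_ld_treated_as_correlated(self):
        """A within-window pair with unknown LD is conservatively pruned."""
        ss = pd.DataFrame(
            [
                _ss_row("rs_a", 1, 10_000, "A", "G", 0.3, 0.1, 0.01, 1e-10),
                _ss_row("rs_b", 1, 15_000, "A", "G", 0.3, 0.1, 0.012, 1e-9),
            ]
        )
        inst = select_instruments(ss, ld=LDTable())
        assert list(inst.variants["variant_id"]) == ["rs_a"]

    def test_out_of_window_pair_kept_despite_missing_ld(self):
        ss = pd.DataFrame(
            [
                _ss_row("rs_a", 1, 1_000_000, "A", "G", 0.3, 0.1, 0.01, 1e-10),
                _ss_row("rs_b", 1, 30_000_000, "A", "G", 0.3, 0.1, 0.012, 1e-9),
            ]
        )
        inst = select_instruments(ss, ld=LDTable(), window_kb=10_000)
        assert len(inst) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ss = random_sumstats(rng, j=50)
        ss["base_pair_location"] = rng.integers(1, 40_000_000, len(ss))
        ids = list(ss["variant_id"])
        pairs = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if rng.random() < 0.6:
                    pairs.append((ids[i], ids[j], rng.random()))
        ld = LDTable(pd.DataFrame(pairs, columns=["id_a", "id_b", "r2"]))
        inst = select_instruments(ss, p_threshold=1e-3, ld=ld, r2_threshold=0.1, window_kb=5000)
        oracle = brute_force_clump(ss, ld, 1e-3, 0.1, 5000)
        assert list(inst.variants["variant_id"]) == oracle

    def test_row_order_invariance(self):
        rng = np.random.default_rng(17)
        ss = random_sumstats(rng, j=40)
        ld = LDTable()
        a = select_instruments(ss, p_threshold=1e-2, ld=ld)
        b = select_instruments(ss.sample(frac=1, random_state=1), p_threshold=1e-2, ld=ld)
        assert list(a.variants["variant_id"]) == list(b.variants["variant_id"])


_inst = make_instrument_set


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta(self):
        inst = _inst([_ss_row("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        outcome = pd.DataFrame([_ss_row("rs1", 1, 100, "G", "A", 0.7, 0.05, 0.01, 1e-3)])
        h = harmonize(inst, outcome)
        assert h.beta_outcome[0] == pytest.approx(-0.05)
        assert h.table["eaf_outcome"].iloc[0] == pytest.approx(0.3)

    def test_strand_flip_resolved_by_complement(self):
        inst = _inst([_ss_row("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)])
        outcome = pd.DataFrame([_ss_row("rs1", 1, 100, "T", "C", 0.3, 0.05, 0.01, 1e-3)])
        h = harmonize(inst, outcome)
        assert h.beta_outcome[0] == pytest.approx(0.05)

    def test_palindromic_ambiguous_dropped(self):
        inst = _inst([_ss_row("rs1", 1, 100, "A", "T", 0.5, 0.1, 0.02, 1e-9)])
        outcome = pd.DataFrame([_ss_row("rs1", 1, 100, "A", "T", 0.3, 0.05, 0.01, 1e-3)])
        h = harmonize(inst, outcome)
        assert len(h) == 0
        assert list(h.dropped["reason"]) == ["palindromic_ambiguous"]

    def test_palindromic_frequency_resolves_strand(self):
        """Opposite-side frequencies on a palindromic variant imply a flip."""
        inst = _inst([_ss_row("rs1", 1, 100, "A", "T", 0.2, 0.1, 0.02, 1e-9)])
        outcome = pd.DataFrame([_ss_row("rs1", 1, 100, "A", "T", 0.8, 0.05, 0.01, 1e-3)])
        h = harmonize(inst, outcome)
        assert h.beta_outcome[0] == pytest.approx(-0.05)
        assert h.table["eaf_outcome"].iloc[0] == pytest.approx(0.2)

    def test_missing_and_mismatched_reason_codes(self):
        inst = _inst(
            [
                _ss_row("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9),
                _ss_row("rs2", 1, 200, "A", "G", 0.3, 0.1, 0.02, 1e-9),
            ]
        )
        outcome = pd.DataFrame([_ss_row("rs2", 1, 200, "A", "C", 0.3, 0.05, 0.01, 1e-3)])
        h = harmonize(inst, outcome)
        assert len(h) == 0
        assert dict(zip(h.dropped["variant_id"], h.dropped["reason"])) == {
            "rs1": "missing_in_outcome",
            "rs2": "allele_mismatch",
        }

    def test_duplicate_ids_rejected(self):
        rows = [_ss_row("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.02, 1e-9)] * 2
        with pytest.raises(DataError, match="duplicate"):
            harmonize(_inst(rows), pd.DataFrame(rows[:1]))

    def test_harmonization_idempotent(self):
        """Re-harmonizing the already-aligned outcome changes nothing."""
        rng = np.random.default_rng(5)
        ss = random_sumstats(rng, j=30)
        inst = _inst(list(ss.to_dict(orient="records")))
        outcome = random_sumstats(rng, j=30)
        outcome["variant_id"] = ss["variant_id"]
        outcome["effect_allele"] = ss["other_allele"]
        outcome["other_allele"] = ss["effect_allele"]
        h1 = harmonize(inst, outcome)
        realigned = h1.table.rename(
            columns={
                "eaf_outcome": "effect_allele_frequency",
                "beta_outcome": "beta",
                "se_outcome": "standard_error",
                "p_outcome": "p_value",
                "n_outcome": "n",
            }
        )[[c for c in ss.columns]]
        h2 = harmonize(
            _inst(list(h1.table.rename(columns={
                "eaf_exposure": "effect_allele_frequency",
                "beta_exposure": "beta",
                "se_exposure": "standard_error",
                "p_exposure": "p_value",
                "n_exposure": "n",
            })[[c for c in ss.columns]].to_dict(orient="records"))),
            realigned,
        )
        assert np.allclose(h1.beta_outcome, h2.beta_outcome)
        assert np.allclose(h1.table["eaf_outcome"], h2.table["eaf_outcome"])

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_wald_ratio_invariant_under_recoding(self, seed):
        """Arbitrary allele recodings of exposure and outcome records leave
        every retained variant's Wald ratio unchanged."""
        rng = np.random.default_rng(seed)
        ss = random_sumstats(rng, j=12)
        outcome = random_sumstats(rng, j=12)
        outcome["variant_id"] = ss["variant_id"]
        outcome["effect_allele"] = ss["effect_allele"]
        outcome["other_allele"] = ss["other_allele"]
        base = harmonize(_inst(list(ss.to_dict(orient="records"))), outcome)
        ss2, out2 = ss.copy(), outcome.copy()
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for df in (ss2, out2):
            for i in df.index:
                if rng.random() < 0.5:  # swap effect/other
                    ea, oa = df.at[i, "effect_allele"], df.at[i, "other_allele"]
                    df.at[i, "effect_allele"], df.at[i, "other_allele"] = oa, ea
                    df.at[i, "beta"] = -df.at[i, "beta"]
                    df.at[i, "effect_allele_frequency"] = 1 - df.at[i, "effect_allele_frequency"]
                if rng.random() < 0.5:  # strand relabel
                    df.at[i, "effect_allele"] = comp[df.at[i, "effect_allele"]]
                    df.at[i, "other_allele"] = comp[df.at[i, "other_allele"]]
        recoded = harmonize(_inst(list(ss2.to_dict(orient="records"))), out2)
        r1 = (base.beta_outcome / base.beta_exposure)
        r2 = (recoded.beta_outcome / recoded.beta_exposure)
        m1 = pd.Series(r1, index=base.table["variant_id"]).sort_index()
        m2 = pd.Series(r2, index=recoded.table["variant_id"]).sort_index()
        assert m1.index.equals(m2.index)
        assert np.allclose(m1.to_numpy(), m2.to_numpy(), atol=1e-12)


class TestInstrumentStrength:
    def test_f_statistic_arithmetic(self):
        h = make_harmonized([0.1], [0.02], [0.05], [0.01])
        per, mean_f = instrument_strength(h)
        assert per.iloc[0] == pytest.approx(25.0)
        assert mean_f == pytest.approx(25.0)

    def test_boundary_significance_f(self):
        """Variants at exactly p = 5e-8 have F = z^2 ~ 29.7."""
        z = stats.norm.isf(2.5e-8)
        h = make_harmonized([0.1] * 3, [0.1 / z] * 3, [0.0] * 3, [0.01] * 3)
        _, mean_f = instrument_strength(h)
        assert mean_f == pytest.approx(z**2, rel=1e-10)
        assert mean_f == pytest.approx(29.7, abs=0.1)

    def test_f_invariant_under_allele_flip(self):
        h1 = make_harmonized([0.1, -0.2], [0.02, 0.05], [0.0, 0.0], [0.01, 0.01])
        h2 = make_harmonized([-0.1, 0.2], [0.02, 0.05], [0.0, 0.0], [0.01, 0.01])
        assert instrument_strength(h1)[1] == instrument_strength(h2)[1]
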