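"""Summary-statistic I/O, harmonisation, MAF filtering, p/FDR utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qtltriad import (
    VariantAssociation,
    bh_fdr,
    filter_by_maf,
    harmonize_pair,
    log_wald_p,
    read_sumstats,
    wald_p,
    write_sumstats,
)
from qtltriad.sumstats import Dataset

from conftest import ma_line


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

class TestReadSumstats:
    def test_well_formed_file_reads_all_rows(self, write_ma):
        path = write_ma(
            [
                ma_line("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.05, wald_p(0.1, 0.05), 1000),
                ma_line("rs2", 1, 200, "C", "T", 0.2, -0.2, 0.1, wald_p(-0.2, 0.1), 1000),
                ma_line("rs3", 2, 300, "G", "A", 0.4, 0.0, 0.2, 1.0, 1000),
            ]
        )
        ds = read_sumstats(path)
        assert len(ds) == 3
        assert len(ds.qc_log) == 0

    def test_unparsable_se_row_is_dropped_and_logged(self, write_ma):
        path = write_ma(
            [
                ma_line("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.05, wald_p(0.1, 0.05), 1000),
                ma_line("rs2", 1, 200, "C", "T", 0.2, -0.2, "NA", 0.5, 1000),
            ]
        )
        ds = read_sumstats(path)
        assert len(ds) == 1
        assert (ds.qc_log["action"] == "dropped_invalid").sum() == 1
        assert ds.qc_log.iloc[0]["variant_id"] == "rs2"

    def test_dialect_remapping_round_trips(self, write_ma, tmp_path):
        """Swapped allele column names resolved via dialect give the same
        dataset as the canonical header (write-then-read oracle)."""
        rows = [
            ma_line("rs1", 1, 100, "A", "G", 0.3, 0.1, 0.05, wald_p(0.1, 0.05), 1000),
            ma_line("rs2", 1, 200, "C", "T", 0.2, -0.2, 0.1, wald_p(-0.2, 0.1), 1000),
        ]
        canonical = read_sumstats(write_ma(rows))
        odd_header = "SNP\tCHR\tPOS\tEFFECT\tOTHER\tfreq\tb\tse\tp\tN\n"
        dialect = {"SNP": "snp", "CHR": "chrom", "POS": "pos", "EFFECT": "a1",
                   "OTHER": "a2", "freq": "eaf", "b": "beta", "se": "se",
                   "p": "p", "N": "n"}
        remapped = read_sumstats(write_ma(rows, header=odd_header, name="odd.tsv"),
                                 dialect=dialect)
        pd.testing.assert_frame_equal(canonical.df, remapped.df)
        # and the writer reproduces a readable file
        out = tmp_path / "roundtrip.tsv"
        write_sumstats(canonical, out)
        again = read_sumstats(out)
        pd.testing.assert_frame_equal(
            canonical.df[["snp", "beta", "se", "p"]],
            again.df[["snp", "beta", "se", "p"]],
        )

    def test_missing_required_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tA1\tb\tse\tp\nrs1\tA\t0.1\t0.05\t0.04\n")
        with pytest.raises(ValueError, match="a2"):
            read_sumstats(path)

    def test_empty_file_is_a_hard_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(ValueError):
            read_sumstats(path)

    def test_discordant_p_is_recomputed_and_reported_value_kept(self, write_ma):
        # printed P far from 2*Phi(-|b/se|): row keeps recomputed p
        path = write_ma(
            [ma_line("rs1", 1, 100, "A", "G", 0.3, 1.9982, 0.2789, "1.00E-190", 1000)]
        )
        ds = read_sumstats(path)
        row = ds.df.iloc[0]
        assert row["p"] == pytest.approx(float(wald_p(1.9982, 0.2789)), rel=1e-12)
        assert row["p_reported"] == pytest.approx(1.00e-190)
        assert (ds.qc_log["action"] == "p_recomputed").sum() == 1


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

def _rec(a1, a2, beta=0.3, eaf=0.3, vid="rs1"):
    return VariantAssociation(vid, "1", 100, a1, a2, eaf, beta, 0.1, 0.01, 1000)


class TestHarmonizePair:
    def test_identical_alleles_unchanged(self):
        out, flag = harmonize_pair(_rec("A", "G", 0.2), _rec("A", "G", 0.3))
        assert flag == "same"
        assert out.beta == 0.3

    def test_swapped_alleles_flip_sign_and_eaf(self):
        out, flag = harmonize_pair(_rec("A", "G", 0.2), _rec("G", "A", 0.3, eaf=0.7))
        assert flag == "flip"
        assert out.beta == -0.3
        assert out.eaf == pytest.approx(0.3)

    def test_strand_complement_resolves(self):
        out, flag = harmonize_pair(_rec("A", "G", 0.2), _rec("T", "C", 0.3))
        assert flag == "strand"
        assert out.beta == 0.3
        assert (out.effect_allele, out.other_allele) == ("A", "G")

    def test_strand_complement_plus_swap_flips(self):
        out, flag = harmonize_pair(_rec("A", "G", 0.2), _rec("C", "T", 0.3, eaf=0.7))
        assert flag == "strand"
        assert out.beta == -0.3
        assert out.eaf == pytest.approx(0.3)

    def test_palindromic_near_half_frequency_dropped(self):
        _, flag = harmonize_pair(_rec("A", "T", eaf=0.49), _rec("A", "T", eaf=0.49))
        assert flag == "drop_palindromic"

    def test_palindromic_missing_eaf_dropped(self):
        _, flag = harmonize_pair(_rec("C", "G", eaf=None), _rec("C", "G", eaf=0.2))
        assert flag == "drop_palindromic"

    def test_palindromic_clear_frequency_kept(self):
        out, flag = harmonize_pair(_rec("A", "T", eaf=0.1), _rec("A", "T", eaf=0.12))
        assert flag == "same"
        assert out.beta == 0.3

    def test_irreconcilable_alleles_dropped(self):
        _, flag = harmonize_pair(_rec("A", "G"), _rec("A", "C"))
        assert flag == "drop_mismatch"

    def test_mismatched_variant_ids_rejected(self):
        with pytest.raises(ValueError):
            harmonize_pair(_rec("A", "G"), _rec("A", "G", vid="rs2"))

    @given(
        beta=st.floats(-2, 2, allow_nan=False),
        eaf=st.floats(0.01, 0.99),
        swap=st.booleans(),
    )
    def test_involution(self, beta, eaf, swap):
        """Harmonising the harmonised record back is the identity."""
        exp = _rec("A", "G", 0.2, eaf=0.5)
        out = _rec("G" if swap else "A", "A" if swap else "G", beta, eaf=eaf)
        harm, flag = harmonize_pair(exp, out)
        assert flag in ("same", "flip")
        again, _ = harmonize_pair(exp, harm)
        assert again.beta == pytest.approx(harm.beta)
        back, _ = harmonize_pair(out, harm)  # re-orient to the original
        assert back.beta == pytest.approx(out.beta)
        if out.eaf is not None:
            assert back.eaf == pytest.approx(out.eaf)


# ---------------------------------------------------------------------------
# MAF filter
# ---------------------------------------------------------------------------

def _dataset(eafs):
    df = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(len(eafs))],
            "chrom": "1",
            "pos": np.arange(len(eafs)) + 1,
            "a1": "A",
            "a2": "G",
            "eaf": eafs,
            "beta": 0.1,
            "se": 0.05,
            "p": 0.05,
            "n": 1000.0,
        }
    )
    return Dataset("t", "disease", df)


class TestMafFilter:
    @pytest.mark.parametrize(
        "eaf,kept",
        [(0.004, False), (0.996, False), (0.30, True), (0.005, True), (np.nan, True)],
    )
    def test_folding_rule(self, eaf, kept):
        ds = filter_by_maf(_dataset([eaf]), 0.005)
        assert (len(ds) == 1) is kept

    def test_missing_eaf_flagged(self):
        ds = filter_by_maf(_dataset([np.nan, 0.2]), 0.005)
        assert (ds.qc_log["action"] == "maf_unknown").sum() == 1

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_subset_and_idempotent(self, eafs):
        ds = _dataset(eafs)
        once = filter_by_maf(ds, 0.01)
        assert set(once.df["snp"]) <= set(ds.df["snp"])
        twice = filter_by_maf(once, 0.01)
        assert list(twice.df["snp"]) == list(once.df["snp"])


# ---------------------------------------------------------------------------
# Wald p
# ---------------------------------------------------------------------------

class TestWaldP:
    # internally consistent rows of the published meta-analysis locus table
    @pytest.mark.parametrize(
        "beta,se,p_printed",
        [
            (3.9869, 0.4730, 3.49e-17),
            (1.7219, 0.2992, 8.73e-09),
            (-1.2655, 0.2237, 1.56e-08),
            (-2.1264, 0.25666, 1.19e-16),
            (-1.5318, 0.1393, 4.02e-28),
            (1.8497, 0.2241, 1.56e-16),
        ],
    )
    def test_published_locus_table_rows(self, beta, se, p_printed):
        assert wald_p(beta, se) == pytest.approx(p_printed, rel=0.05)

    def test_zero_beta_gives_one(self):
        assert wald_p(0.0, 0.123) == 1.0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wald_p(0.1, 0.0)

    @given(st.floats(0.01, 30), st.floats(0.01, 30))
    def test_strictly_decreasing_in_z(self, z1, z2):
        lo, hi = sorted([z1, z2])
        if hi - lo > 1e-9:
            assert wald_p(hi, 1.0) < wald_p(lo, 1.0)

    @pytest.mark.parametrize("z", [10.0, 20.0, 37.0, 45.0, 60.0])
    def test_log_tail_matches_asymptotic_series(self, z):
        """log p + z^2/2 stays finite and matches the Mills-ratio
        asymptotic expansion of the normal tail."""
        lp = float(log_wald_p(z, 1.0))
        assert np.isfinite(lp + z * z / 2.0)
        series = 1 - z**-2 + 3 * z**-4 - 15 * z**-6 + 105 * z**-8
        lp_series = (
            np.log(2) - 0.5 * np.log(2 * np.pi) - z * z / 2 - np.log(z) + np.log(series)
        )
        assert lp == pytest.approx(lp_series, abs=1e-6)


# ---------------------------------------------------------------------------
# BH FDR
# ---------------------------------------------------------------------------

def bh_bruteforce(p):
    """O(m^2) literal implementation of the step-up definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    rank = np.empty(m, int)
    rank[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        vals = [m * p[j] / rank[j] for j in range(m) if rank[j] >= rank[i]]
        q[i] = min(min(vals), 1.0)
    return q


class TestBhFdr:
    def test_hand_worked_triple(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_is_its_own_q(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.1], [0.1, 1.5], [np.nan]):
            with pytest.raises(ValueError):
                bh_fdr(bad)
        with pytest.raises(ValueError):
            bh_fdr([])

    def test_matches_bruteforce_and_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(50):
            p = rng.uniform(1e-6, 1, size=10)
            q = bh_fdr(p)
            np.testing.assert_allclose(q, bh_bruteforce(p), rtol=0, atol=0)
            np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1],
                                       rtol=1e-12)
            assert np.all(q >= p - 1e-12)
            order = np.argsort(p, kind="mergesort")
            assert np.all(np.diff(q[order]) >= -1e-15)
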