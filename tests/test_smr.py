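"""SMR test, HEIDI heterogeneity test, quadratic-form tail, LD matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from qtltriad import (
    Instrument,
    LdMatrix,
    SmrAnalysis,
    heidi_test,
    liu_sf,
    simulate_locus,
    smr_test,
)
from qtltriad.simulate import GENE_ID
from qtltriad.smr import quadform_sf


def _inst(z_exp, z_out, se_exp=0.1, se_out=0.1):
    return Instrument("rs0", beta_exp=z_exp * se_exp, se_exp=se_exp, p_exp=1e-9,
                      beta_out=z_out * se_out, se_out=se_out)


class TestSmrTest:
    def test_hand_worked_statistic(self):
        est = smr_test(_inst(10.0, 5.0))
        assert est.t_smr == pytest.approx(20.0)
        # chi-square(1) survival oracle
        assert est.p_smr == pytest.approx(stats.chi2.sf(20.0, 1), rel=1e-12)
        assert est.p_smr == pytest.approx(7.74e-6, rel=1e-2)

    def test_null_outcome_gives_p_one(self):
        est = smr_test(_inst(10.0, 0.0))
        assert est.t_smr == 0.0
        assert est.p_smr == 1.0

    def test_ratio_estimate(self):
        inst = Instrument("rs0", beta_exp=0.5, se_exp=0.05, p_exp=1e-9,
                          beta_out=0.1, se_out=0.02)
        assert smr_test(inst).b_smr == pytest.approx(0.2)

    def test_degenerate_instrument_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            smr_test(Instrument("rs0", 0.0, 0.1, 1e-9, 0.1, 0.1))

    @given(st.floats(0.5, 30), st.floats(0.5, 30))
    def test_statistic_symmetric_and_bounded(self, z1, z2):
        t12 = smr_test(_inst(z1, z2)).t_smr
        t21 = smr_test(_inst(z2, z1)).t_smr
        assert t12 == pytest.approx(t21, rel=1e-9)
        assert t12 <= min(z1**2, z2**2) + 1e-9


class TestLdMatrix:
    def test_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            LdMatrix(["a", "b"], np.array([[2.0, 0.5], [0.5, 1.0]]))
        with pytest.raises(ValueError, match="PSD"):
            LdMatrix(
                ["a", "b", "c"],
                np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]]),
            )
        with pytest.raises(ValueError, match="rho"):
            LdMatrix.ar1(["a", "b"], 1.0)

    def test_ar1_structure_and_tsv_round_trip(self, tmp_path):
        ld = LdMatrix.ar1([f"rs{i}" for i in range(5)], 0.6)
        assert ld.r[0, 3] == pytest.approx(0.6**3)
        assert ld.r2("rs0", "rs1") == pytest.approx(0.36)
        path = tmp_path / "ld.tsv"
        ld.to_tsv(path)
        again = LdMatrix.from_tsv(path)
        assert again.variant_ids == ld.variant_ids
        np.testing.assert_allclose(again.r, ld.r, atol=1e-7)


class TestQuadformTail:
    def test_single_unit_weight_is_chi2_1(self):
        for t in (0.5, 2.0, 5.0):
            assert quadform_sf(t, np.array([1.0])) == pytest.approx(
                stats.chi2.sf(t, 1), abs=1e-3
            )

    def test_iid_weights_reduce_to_chi2_k(self):
        lam = np.ones(4)
        for t in (1.0, 4.0, 10.0):
            assert quadform_sf(t, lam) == pytest.approx(stats.chi2.sf(t, 4), abs=1e-6)
            # the moment-matched fallback is close too
            assert liu_sf(t, lam) == pytest.approx(stats.chi2.sf(t, 4), abs=5e-3)

    def test_zero_statistic_gives_one(self):
        assert quadform_sf(0.0, np.array([0.5, 0.5])) == 1.0
        assert liu_sf(0.0, np.array([0.5, 0.5])) == 1.0

    def test_monte_carlo_agreement_random_panels(self, rng):
        """Imhof inversion tracks a 50k-draw MC oracle on random small
        correlation spectra (the heavier 200k-draw check runs in the
        acceptance suite)."""
        for _ in range(8):
            m = int(rng.integers(3, 7))
            a = rng.standard_normal((m, m))
            c = a @ a.T
            d = np.sqrt(np.diag(c))
            c = c / np.outer(d, d)
            lam = np.linalg.eigvalsh(c)
            chol = np.linalg.cholesky(c + 1e-12 * np.eye(m))
            t = float(np.sum((chol @ rng.standard_normal(m)) ** 2))
            p = quadform_sf(t, lam)
            draws = chol @ rng.standard_normal((m, 50_000))
            p_mc = np.mean(np.sum(draws**2, axis=0) >= t)
            assert p == pytest.approx(p_mc, abs=0.02)


def _heidi_frames(be, se_e, bo, se_o, ids=None):
    ids = ids or [f"rs{i}" for i in range(len(be))]
    exp = pd.DataFrame({"snp": ids, "beta": be, "se": se_e,
                        "p": [float(x) for x in
                              2 * stats.norm.sf(np.abs(np.array(be) / np.array(se_e)))]})
    out = pd.DataFrame({"snp": ids, "beta": bo, "se": se_o, "p": 0.5})
    return exp, out


class TestHeidi:
    def test_homogeneous_ratios_give_p_one(self):
        """Noise-free single-causal data: every SNP carries the same
        ratio, so the deviations vanish and p = 1."""
        m = 6
        ld = LdMatrix.ar1([f"rs{i}" for i in range(m)], 0.8)
        be = 0.5 * ld.r[:, 0]
        bo = 0.2 * be  # identical b_i = 0.2 everywhere
        exp, out = _heidi_frames(be, [0.01] * m, bo, [0.01] * m)
        res = heidi_test(exp, out, ld, top="rs0")
        assert res.flag == "ok"
        assert res.p_heidi == pytest.approx(1.0, abs=1e-9)

    def test_too_few_eligible_snps_untestable(self):
        m = 3  # top + 2 others < min_snps
        ld = LdMatrix.ar1([f"rs{i}" for i in range(m)], 0.5)
        be = 0.5 * ld.r[:, 0]
        exp, out = _heidi_frames(be, [0.01] * m, 0.2 * be, [0.01] * m)
        res = heidi_test(exp, out, ld, top="rs0", min_snps=3)
        assert res.p_heidi is None
        assert res.flag == "heidi_untestable"
        assert res.n_snps == 2

    def test_invariant_to_non_top_snp_order(self):
        loc = simulate_locus("linkage", 40, seed=42)
        merged = loc.eqtl.df.merge(loc.gwas.df, on="snp", suffixes=("_e", "_g"))
        exp = merged.rename(columns={"beta_e": "beta", "se_e": "se", "p_e": "p"})[
            ["snp", "beta", "se", "p"]]
        out = merged.rename(columns={"beta_g": "beta", "se_g": "se", "p_g": "p"})[
            ["snp", "beta", "se", "p"]]
        top = exp.loc[exp["p"].idxmin(), "snp"]
        base = heidi_test(exp, out, loc.ld, top=top)
        perm = np.random.default_rng(0).permutation(len(exp))
        shuffled = heidi_test(exp.iloc[perm], out.iloc[perm], loc.ld, top=top)
        assert base.p_heidi == pytest.approx(shuffled.p_heidi, rel=1e-9)
        assert base.n_snps == shuffled.n_snps

    def test_mediated_rejection_rate_near_nominal(self):
        rejections = tested = 0
        for i in range(60):
            loc = simulate_locus("mediated", 60, seed=20_000 + i)
            res = SmrAnalysis(loc.eqtl, loc.gwas, loc.ld, loc.annotation).fit([GENE_ID])
            if len(res.table) and res.table.iloc[0]["heidi_flag"] == "ok":
                tested += 1
                rejections += int(res.table.iloc[0]["p_heidi"] <= 0.05)
        assert tested >= 50
        assert rejections / tested <= 0.10

    def test_linkage_rejected_often(self):
        rejections = tested = 0
        for i in range(40):
            loc = simulate_locus("linkage", 60, seed=30_000 + i)
            res = SmrAnalysis(loc.eqtl, loc.gwas, loc.ld, loc.annotation).fit([GENE_ID])
            if len(res.table) and res.table.iloc[0]["heidi_flag"] == "ok":
                tested += 1
                rejections += int(res.table.iloc[0]["p_heidi"] <= 0.05)
        assert tested >= 30
        assert rejections / tested >= 0.5


class TestSmrAnalysisModel:
    def test_no_ld_flags_heidi_untestable(self, mediated_locus):
        res = SmrAnalysis(
            mediated_locus.eqtl, mediated_locus.gwas, None,
            mediated_locus.annotation,
        ).fit([GENE_ID])
        assert (res.table["heidi_flag"] == "heidi_untestable").all()

    def test_weak_top_snp_skipped(self):
        loc = simulate_locus("null", 30, seed=5)
        res = SmrAnalysis(loc.eqtl, loc.gwas, loc.ld, loc.annotation).fit([GENE_ID])
        assert res.table.empty
        assert (res.skipped["reason"] == "no_significant_top").any()

    def test_smr_null_pvalues_roughly_uniform(self):
        """Light calibration check (full 2000-rep KS in acceptance)."""
        ps = []
        for i in range(200):
            loc = simulate_locus("mediated", 30, c=0.0, seed=40_000 + i)
            res = SmrAnalysis(loc.eqtl, loc.gwas, loc.ld, loc.annotation).fit([GENE_ID])
            if len(res.table):
                ps.append(res.table.iloc[0]["p_smr"])
        assert len(ps) >= 150
        assert stats.kstest(ps, "uniform").pvalue > 0.001
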