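"""Case-case reconstruction: delta conversion, genetic distance, calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardiocc.casecase import casecase_stats, fst_causal, to_delta_scale
from cardiocc.models import CrossTraitModel, DiseaseModel
from cardiocc.simulate import default_config, simulate_paired_sumstats

from conftest import make_table


def make_pair_from_deltas(delta_a, delta_b, var_a, var_b, da, db):
    """Build harmonized log-odds tables whose delta-scale conversion gives the
    requested delta estimates and variances (eaf = 0.5 throughout)."""
    gvar = 2 * 0.5 * 0.5
    beta_a = np.asarray(delta_a) / (np.sqrt(gvar) * (1 - da.prevalence))
    se_a = np.sqrt(np.asarray(var_a) / gvar) / (1 - da.prevalence)
    beta_b = np.asarray(delta_b) / (np.sqrt(gvar) * (1 - db.prevalence))
    se_b = np.sqrt(np.asarray(var_b) / gvar) / (1 - db.prevalence)
    a = make_table("a", beta=beta_a, se=se_a, n_case=[da.n_case] * len(beta_a),
                   n_control=[da.n_control] * len(beta_a))
    b = make_table("b", beta=beta_b, se=se_b, n_case=[db.n_case] * len(beta_b),
                   n_control=[db.n_control] * len(beta_b))
    return a, b


class TestDeltaScale:
    def test_zero_beta_gives_zero_delta(self, toy_diseases):
        da, _ = toy_diseases
        t = make_table("t", beta=[0.0, 0.0], se=[0.1, 0.2], eaf=[0.1, 0.9])
        delta, var, _ = to_delta_scale(t, da)
        np.testing.assert_array_equal(delta, 0.0)
        assert (var > 0).all()

    def test_allele_flip_negates_delta_keeps_variance(self, toy_diseases):
        da, _ = toy_diseases
        t = make_table("t", beta=[0.3], se=[0.1], eaf=[0.2])
        t_flip = make_table("t", beta=[-0.3], se=[0.1], eaf=[0.8])
        d1, v1, _ = to_delta_scale(t, da)
        d2, v2, _ = to_delta_scale(t_flip, da)
        assert d2[0] == pytest.approx(-d1[0])
        assert v2[0] == pytest.approx(v1[0])

    def test_boundary_eaf_skipped(self, toy_diseases):
        da, _ = toy_diseases
        t = make_table("t", beta=[0.3, 0.3], se=[0.1, 0.1], eaf=[0.0, 0.4])
        delta, _, meta = to_delta_scale(t, da)
        assert np.isnan(delta[0]) and np.isfinite(delta[1])
        assert meta["n_skipped_boundary_eaf"] == 1

    def test_matches_direct_case_frequency_difference_oracle(self):
        # individual-level oracle: simulate a cohort, run the actual 0/1
        # regression-free frequency contrast, and compare with the delta
        # conversion of log-odds statistics computed from the same cohort
        rng = np.random.default_rng(42)
        n = 120_000
        k = 0.1
        disease = DiseaseModel("A", k, 0.5, 1000, 1000)
        m = 30
        eaf = rng.uniform(0.2, 0.8, m)
        beta_l = rng.normal(0, 0.06, m)
        g = rng.binomial(2, eaf, size=(n, m)).astype(float)
        gs = (g - 2 * eaf) / np.sqrt(2 * eaf * (1 - eaf))
        lia = gs @ beta_l + rng.standard_normal(n) * np.sqrt(1 - (beta_l**2).sum())
        case = lia > stats.norm.isf(k)

        # direct standardized case-vs-population frequency difference
        direct = gs[case].mean(axis=0)

        # log-odds effects per allele from a 2x2-style contrast (logit of
        # per-allele frequencies in cases vs controls), the sumstats route
        p_case = g[case].mean(axis=0) / 2
        p_ctrl = g[~case].mean(axis=0) / 2
        beta_lo = np.log(p_case / (1 - p_case)) - np.log(p_ctrl / (1 - p_ctrl))
        se_lo = np.sqrt(
            1 / (2 * case.sum() * p_case * (1 - p_case))
            + 1 / (2 * (~case).sum() * p_ctrl * (1 - p_ctrl))
        )
        t = make_table("t", beta=beta_lo, se=se_lo, eaf=eaf)
        delta, var, _ = to_delta_scale(t, disease)
        resid = (delta - direct) / np.sqrt(var)
        # agreement within sampling noise across variants
        assert np.abs(resid).mean() < 2.0
        assert np.corrcoef(delta, direct)[0, 1] > 0.97


class TestFstCausal:
    def test_identical_diseases_rg_one_is_zero(self):
        d = DiseaseModel("X", 0.01, 0.2, 1000, 1000)
        assert fst_causal(d, d, CrossTraitModel(rg=1.0, m_causal=500)) == pytest.approx(0.0)

    def test_monotone_dilution_in_m_causal(self, toy_diseases):
        da, db = toy_diseases
        vals = [
            fst_causal(da, db, CrossTraitModel(rg=-0.56, m_causal=m))
            for m in (100, 1_000, 10_000, 100_000)
        ]
        assert all(v1 > v2 > 0 for v1, v2 in zip(vals, vals[1:]))
        assert vals[-1] < 1e-4

    def test_forward_simulation_oracle_at_study_parameters(self, toy_diseases):
        # draw causal liability effects at the study parameterization and
        # realize case-group frequency differences in simulated individuals
        da, db = toy_diseases
        x = CrossTraitModel(rg=-0.56, m_causal=1223)
        expected = fst_causal(da, db, x)

        rng = np.random.default_rng(7)
        m = 1223
        sa = np.sqrt(da.h2_liability / m)
        sb = np.sqrt(db.h2_liability / m)
        u = rng.standard_normal(m)
        bl_a = sa * u
        bl_b = sb * (x.rg * u + np.sqrt(1 - x.rg**2) * rng.standard_normal(m))

        # realized standardized case-group frequency difference per variant:
        # E[g_std | case] = beta_l * phi(tau)/K  (checked by forward sampling
        # of liabilities conditional on genotype at a subsample of variants)
        n = 2_000_000
        idx = rng.choice(m, 40, replace=False)
        eaf = np.full(m, 0.4)
        realized = np.empty(len(idx))
        for j, v in enumerate(idx):
            g = rng.binomial(2, eaf[v], n)
            gs = (g - 2 * eaf[v]) / np.sqrt(2 * eaf[v] * (1 - eaf[v]))
            lia_a = bl_a[v] * gs + rng.standard_normal(n) * np.sqrt(1 - bl_a[v] ** 2)
            lia_b = bl_b[v] * gs + rng.standard_normal(n) * np.sqrt(1 - bl_b[v] ** 2)
            da_mean = gs[lia_a > da.tau].mean()
            db_mean = gs[lia_b > db.tau].mean()
            realized[j] = (da_mean - db_mean) ** 2
        mc_mean = realized.mean()
        mc_se = realized.std(ddof=1) / np.sqrt(len(idx))
        # the Monte-Carlo mean over sampled variants estimates fst_causal
        assert expected == pytest.approx(mc_mean, abs=2 * mc_se)


class TestCaseCaseStats:
    def test_equal_deltas_give_zero_ordinary_z(self, toy_diseases):
        da, db = toy_diseases
        a, b = make_pair_from_deltas([0.01], [0.01], [1e-5], [1e-5], da, db)
        res = casecase_stats(a, b, da, db, CrossTraitModel(rg=-0.56, m_causal=1223))
        assert res.df["z_ols"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_opposing_deltas_boost_sqrt2(self, toy_diseases):
        # delta_a = +d, delta_b = -d, equal variances, zero overlap:
        # z_cc = 2d/sqrt(2v) = sqrt(2) * single-trait z
        da, db = toy_diseases
        d, v = 0.004, 1e-6
        a, b = make_pair_from_deltas([d], [-d], [v], [v], da, db)
        res = casecase_stats(a, b, da, db, CrossTraitModel(rg=-0.56, m_causal=1223,
                                                           error_covariance=0.0))
        single_z = d / np.sqrt(v)
        assert res.df["z_ols"].iloc[0] == pytest.approx(np.sqrt(2) * single_z, rel=1e-9)

    def test_swap_symmetry(self, toy_diseases):
        da, db = toy_diseases
        rng = np.random.default_rng(0)
        deltas = rng.normal(0, 0.004, 50)
        a, b = make_pair_from_deltas(deltas, -deltas / 2, np.full(50, 1e-6),
                                     np.full(50, 2e-6), da, db)
        x = CrossTraitModel(rg=-0.56, m_causal=1223, error_covariance=0.01)
        res_ab = casecase_stats(a, b, da, db, x)
        res_ba = casecase_stats(b, a, db, da, x)
        np.testing.assert_allclose(res_ba.df["delta_ols"], -res_ab.df["delta_ols"])
        np.testing.assert_allclose(res_ba.df["p_ols"], res_ab.df["p_ols"])
        np.testing.assert_allclose(res_ba.df["delta_exact"], -res_ab.df["delta_exact"])
        np.testing.assert_allclose(res_ba.df["p_exact"], res_ab.df["p_exact"])

    @staticmethod
    def _null_rejections(alpha, m=40_000, seed=5):
        cfg = default_config(
            m_variants=m, m_causal=400,
            disease_a=DiseaseModel("A", 0.004, 0.0, 9_365, 100_000),
            disease_b=DiseaseModel("B", 0.002, 0.0, 5_900, 68_359),
            rg=0.0, shared_controls=0, ld_block_size=1, within_block_corr=0.0,
            seed=seed,
        )
        a, b, _ = simulate_paired_sumstats(cfg)
        da, db = cfg.disease_a, cfg.disease_b
        res = casecase_stats(a, b, da, db,
                             CrossTraitModel(rg=0.0, m_causal=400, error_covariance=0.0))
        return (
            float((res.df["p_ols"] < alpha).mean()),
            float((res.df["p_exact"] < alpha).mean()),
            len(res.df),
        )

    @pytest.mark.parametrize("alpha", [0.05, 1e-3])
    def test_global_null_type_i_error_both_paths(self, alpha):
        r_ols, r_exact, m = self._null_rejections(alpha)
        se = np.sqrt(alpha * (1 - alpha) / m)
        assert abs(r_ols - alpha) < 3 * se + 1e-9
        assert abs(r_exact - alpha) < 3 * se + 1e-9

    def test_stress_variants_inflate_ordinary_but_not_exact(self, toy_diseases):
        # variants with EQUAL liability-scale effects in both disorders at
        # large n: the ordinary path's type-I error inflates, the exact-weight
        # path stays calibrated (<= 1.5x nominal)
        da0, db0 = toy_diseases
        da = DiseaseModel("A", da0.prevalence, da0.h2_liability, 60_000, 1_000_000)
        db = DiseaseModel("B", db0.prevalence, db0.h2_liability, 50_000, 900_000)
        rng = np.random.default_rng(11)
        n_rep = 4_000
        beta_shared = 0.05  # strong shared liability effect
        x = CrossTraitModel(rg=-0.56, m_causal=1223, error_covariance=0.0)

        true_da = beta_shared * da.case_scale
        true_db = beta_shared * db.case_scale
        var_a = np.full(n_rep, 4.0 / da.n_eff)
        var_b = np.full(n_rep, 4.0 / db.n_eff)
        delta_a = true_da + rng.standard_normal(n_rep) * np.sqrt(var_a)
        delta_b = true_db + rng.standard_normal(n_rep) * np.sqrt(var_b)
        a, b = make_pair_from_deltas(delta_a, delta_b, var_a, var_b, da, db)
        res = casecase_stats(a, b, da, db, x)

        alpha = 0.05
        rate_ols = (res.df["p_ols"] < alpha).mean()
        rate_exact = (res.df["p_exact"] < alpha).mean()
        assert rate_ols > 2 * alpha  # ordinary path visibly inflated
        assert rate_exact <= 1.5 * alpha

    def test_power_ordering_on_mirrored_effect_variants(self):
        # exactly opposite effects in a balanced design: every causal variant
        # gains the sqrt(2) boost, so the case-case scan dominates the better
        # single-trait scan in median |z|
        d = DiseaseModel("A", 0.004, 0.16, 9_000, 200_000)
        e = DiseaseModel("B", 0.004, 0.16, 9_000, 200_000)
        cfg = default_config(m_variants=20_000, m_causal=300, rg=-1.0,
                             disease_a=d, disease_b=e, shared_controls=0, seed=19)
        a, b, truth = simulate_paired_sumstats(cfg)
        res = casecase_stats(a, b, d, e,
                             CrossTraitModel(rg=-1.0, m_causal=300,
                                             error_covariance=0.0))
        causal = truth.causal_index
        z_cc = np.abs(res.df["z_exact"].to_numpy()[causal])
        z_single = np.maximum(
            np.abs(a.df["z"].to_numpy()[causal]), np.abs(b.df["z"].to_numpy()[causal])
        )
        assert np.median(z_cc) > np.median(z_single)

    def test_discovery_yield_boost_on_opposing_variants(self):
        # at rg = -0.6 under the study conditions, the case-case scan finds
        # opposing-effect causal variants that neither input scan reaches at
        # genome-wide significance -- the novelty yield the design exists for
        cfg = default_config(m_variants=20_000, m_causal=300, rg=-0.6, seed=19)
        a, b, truth = simulate_paired_sumstats(cfg)
        da, db = cfg.disease_a, cfg.disease_b
        res = casecase_stats(a, b, da, db,
                             CrossTraitModel(rg=-0.6, m_causal=300,
                                             error_covariance=truth.overlap_corr))
        causal = truth.causal_index
        opposing = np.sign(truth.delta_a) != np.sign(truth.delta_b)
        idx = causal[opposing]
        cc_sig = res.df["p_exact"].to_numpy()[idx] < 5e-8
        single_sig = (a.df["p"].to_numpy()[idx] < 5e-8) | (
            b.df["p"].to_numpy()[idx] < 5e-8
        )
        novel = cc_sig & ~single_sig
        assert novel.sum() >= 5

    def test_stress_flag_marks_discordant_conclusions(self, toy_diseases):
        da, db = toy_diseases
        # a strong shared-liability variant: ordinary significant, exact not
        beta = 0.4
        var = 1e-8
        a, b = make_pair_from_deltas(
            [beta * da.case_scale], [beta * db.case_scale], [var], [var], da, db
        )
        res = casecase_stats(a, b, da, db, CrossTraitModel(rg=-0.56, m_causal=1223))
        assert res.df["flag_stress"].iloc[0]
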