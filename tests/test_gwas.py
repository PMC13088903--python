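"""Factor GWAS: SNP expansion, per-SNP estimates, Q_SNP, N_eff, clumping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gsemkit import (
    GenomicCovariance,
    GsemModel,
    TruthModel,
    build_ld_panel,
    clump,
    common_factor_model,
    effective_n,
    expand_with_snp,
    simulate_sumstats,
    simulate_truth_effects,
    snp_factor_gwas,
)
from gsemkit.gwas import SNP_NAME, _PerSnpFitter
from gsemkit.utils import InputError, vech_index


def exact_gcov(S, names, v_scale=1e-4):
    d = len(names) * (len(names) + 1) // 2
    return GenomicCovariance(list(names), S, np.eye(len(names)), np.eye(d) * v_scale,
                             M=20000, n_blocks=200)


class TestExpandWithSnp:
    def setup_method(self):
        lam = np.sqrt([0.5, 0.4, 0.3])
        S = np.outer(lam, lam)
        np.fill_diagonal(S, [0.5, 0.4, 0.3])
        self.g = exact_gcov(S, ["a", "b", "c"])

    def test_null_snp_column(self):
        out = expand_with_snp(self.g, np.zeros(3), np.full(3, 0.01), snp_var=0.5)
        assert np.allclose(out.S[3, :3], 0.0)
        assert out.S[3, 3] == 0.5

    def test_frq_half_gives_variance_half(self):
        frq = 0.5
        assert 2 * frq * (1 - frq) == pytest.approx(0.5)

    def test_snp_variance_moment_marked_fixed(self):
        out = expand_with_snp(self.g, np.zeros(3), np.full(3, 0.01), snp_var=0.5)
        pos = vech_index(3, 3, 4)
        assert out.V[pos, pos] == 0.0

    def test_measurement_block_embedded_consistently(self):
        out = expand_with_snp(self.g, np.full(3, 0.02), np.full(3, 0.01), snp_var=0.4)
        assert out.V[vech_index(1, 0, 4), vech_index(1, 0, 4)] == pytest.approx(
            self.g.V[vech_index(1, 0, 3), vech_index(1, 0, 3)]
        )
        # SNP-trait sampling variance = (se * snp_var)^2
        p = vech_index(3, 0, 4)
        assert out.V[p, p] == pytest.approx((0.01 * 0.4) ** 2)

    def test_single_indicator_passthrough(self):
        """k=1: the factor-GWAS estimate equals the input standardized beta."""
        g1 = exact_gcov(np.array([[0.4]]), ["a"], v_scale=1.0)
        from gsemkit.sem import SemModel

        meas = GsemModel(g1, "F =~ 0.6324555320336759*a\nF ~~ 1*F\na ~~ 0*a").fit()
        f = _PerSnpFitter(meas, ["F"])
        b_std = np.array([0.012])
        res_c, _ = f.fit_snp(b_std, np.array([0.005]), fit_independent=False)
        b = res_c.params[f"F~{SNP_NAME}"]
        # path-traced effect on the trait equals the input effect
        assert b * 0.6324555320336759 == pytest.approx(0.012, rel=1e-6)


@pytest.fixture(scope="module")
def common_pathway_setup(eur_like_meas):
    return eur_like_meas


@pytest.fixture(scope="module")
def eur_like_meas():
    """Exact single-factor measurement model for per-SNP tests."""
    lam = np.sqrt([0.5, 0.4, 0.3, 0.35])
    S = np.outer(lam, lam)
    np.fill_diagonal(S, [0.5, 0.4, 0.3, 0.35])
    g = exact_gcov(S, ["a", "b", "c", "d"], v_scale=4e-4)
    meas = GsemModel(g, common_factor_model({"F": ["a", "b", "c", "d"]})).fit()
    return meas, lam


class TestPerSnpEstimates:
    def test_factor_z_pools_power_with_equal_loadings(self):
        """Equal loadings, no residuals: factor z beats each trait z, -> sqrt(k)."""
        k = 4
        lam_val = 0.999
        S = np.full((k, k), lam_val**2)
        np.fill_diagonal(S, 1.0)
        g = exact_gcov(S, list("abcd"), v_scale=1e-6)
        meas = GsemModel(g, common_factor_model({"F": list("abcd")})).fit()
        f = _PerSnpFitter(meas, ["F"])
        se = 0.005
        beta = np.full(k, 0.01)
        res_c, _ = f.fit_snp(beta, np.full(k, se), fit_independent=False)
        z_factor = res_c.params[f"F~{SNP_NAME}"] / res_c.bse[f"F~{SNP_NAME}"]
        z_trait = beta[0] / se
        assert z_factor > z_trait
        assert z_factor / z_trait == pytest.approx(np.sqrt(k), rel=0.02)

    def test_null_snp_z_standard_normal(self, eur_like_meas):
        meas, lam = eur_like_meas
        f = _PerSnpFitter(meas, ["F"])
        rng = np.random.default_rng(0)
        n = 20000.0
        zs = []
        for _ in range(500):
            beta = rng.standard_normal(4) / np.sqrt(n)
            res_c, _ = f.fit_snp(beta, np.full(4, 1 / np.sqrt(n)), fit_independent=False)
            zs.append(res_c.params[f"F~{SNP_NAME}"] / res_c.bse[f"F~{SNP_NAME}"])
        ks = stats.kstest(zs, "norm")
        assert ks.pvalue > 0.01

    def test_qsnp_df_rule(self, eur_like_meas):
        meas, _ = eur_like_meas
        f = _PerSnpFitter(meas, ["F"])
        assert f.q_df == 3  # 4 indicators - 1

    def test_single_indicator_effect_detected_at_scale(self, eur_like_meas):
        """A SNP hitting one indicator only is flagged far below 5e-8."""
        meas, _ = eur_like_meas
        f = _PerSnpFitter(meas, ["F"])
        n = 100_000.0
        beta = np.array([15.0 / np.sqrt(n), 0.0, 0.0, 0.0])
        res_c, res_i = f.fit_snp(beta, np.full(4, 1 / np.sqrt(n)))
        q = res_c.chi2 - res_i.chi2
        assert stats.chi2.sf(q, f.q_df) < 5e-8

    def test_trait_order_invariance(self, small_panel):
        names = ["a", "b", "c", "d"]
        lam = np.sqrt([0.5, 0.4, 0.3, 0.35])
        S = np.outer(lam, lam)
        np.fill_diagonal(S, [0.5, 0.4, 0.3, 0.35])
        g = exact_gcov(S, names, v_scale=4e-4)
        meas = GsemModel(g, common_factor_model({"F": names})).fit()
        truth = TruthModel(names, np.ones((4, 1)), np.eye(1),
                           h2=[0.5, 0.4, 0.3, 0.35], n=[2e4] * 4, polygenicity=0.5)
        fx = simulate_truth_effects(truth, small_panel, seed=5, common_pathway_only=True)
        tables = simulate_sumstats(fx, small_panel, truth, seed=6)
        sub = [type(t)(t.trait_name, t.df.head(200).copy()) for t in tables]
        r1 = snp_factor_gwas(meas, sub, small_panel)
        r2 = snp_factor_gwas(meas, [sub[2], sub[0], sub[3], sub[1]], small_panel)
        pd.testing.assert_frame_equal(r1, r2)

    def test_het_removed_is_exact_threshold_set(self, eur_like_meas, small_panel):
        meas, _ = eur_like_meas
        names = ["a", "b", "c", "d"]
        truth = TruthModel(names, np.ones((4, 1)), np.eye(1),
                           h2=[0.5, 0.4, 0.3, 0.35], n=[2e4] * 4, polygenicity=0.5)
        fx = simulate_truth_effects(truth, small_panel, seed=7)
        tables = simulate_sumstats(fx, small_panel, truth, seed=8)
        sub = [type(t)(t.trait_name, t.df.head(300).copy()) for t in tables]
        thresh = 0.05  # deliberately loose so the flag actually fires
        rows = snp_factor_gwas(meas, sub, small_panel, qsnp_threshold=thresh)
        flagged = rows["HET_REMOVED"].to_numpy()
        expected = rows["QP"].to_numpy() < thresh
        assert np.array_equal(flagged, np.where(np.isnan(rows["QP"]), False, expected))
        assert flagged.any()


class TestEffectiveN:
    def make_rows(self, n, n_snps=300, seed=0):
        rng = np.random.default_rng(seed)
        frq = rng.uniform(0.05, 0.5, n_snps)
        se = 1.0 / np.sqrt(2 * frq * (1 - frq) * n)
        return pd.DataFrame({"FRQ": frq, "SE": se, "BETA": 0.0})

    def test_constructed_se_returns_n_exactly(self):
        rows = self.make_rows(10_000.0)
        assert effective_n(rows) == pytest.approx(10_000.0, rel=1e-12)

    def test_doubling_se_quarters_n(self):
        rows = self.make_rows(10_000.0)
        rows2 = rows.assign(SE=rows["SE"] * 2)
        assert effective_n(rows2) == pytest.approx(2_500.0, rel=1e-12)

    def test_only_in_window_snps_contribute(self):
        rows = self.make_rows(10_000.0)
        out_window = rows.copy()
        # corrupt every out-of-window SNP: the estimate must not move
        maf = np.minimum(out_window["FRQ"], 1 - out_window["FRQ"])
        outside = (maf < 0.1) | (maf > 0.4)
        assert outside.any()
        out_window.loc[outside, "SE"] *= 100
        assert effective_n(out_window) == pytest.approx(effective_n(rows), rel=1e-12)

    def test_empty_window_rejected(self):
        rows = self.make_rows(10_000.0)
        with pytest.raises(InputError):
            effective_n(rows, maf_window=(0.001, 0.002))


def brute_force_clump(rows, panel, p1, r2, window_kb):
    """Independent oracle: direct greedy enumeration, no shared code."""
    df = rows.sort_values(["P", "SNP"], kind="mergesort")
    df = df[df["P"] <= p1]
    assigned = set()
    leads = []
    for _, row in df.iterrows():
        if row["SNP"] in assigned:
            continue
        assigned.add(row["SNP"])
        leads.append(row["SNP"])
        for _, other in rows.iterrows():
            if other["SNP"] in assigned:
                continue
            if other["CHR"] != row["CHR"]:
                continue
            if abs(other["POS"] - row["POS"]) > window_kb * 1000:
                continue
            if panel.ld_r2(row["SNP"], other["SNP"]) >= r2:
                assigned.add(other["SNP"])
    return leads


class TestClump:
    def make_rows(self, panel, pvals):
        pf = panel.snp_frame()
        return pd.DataFrame(
            {"SNP": pf["SNP"], "CHR": pf["CHR"], "POS": pf["POS"], "P": pvals}
        )

    def test_two_linked_gws_snps_one_lead(self):
        panel = build_ld_panel(n_blocks=1, snps_per_block=2, rho=0.9487, seed=0)
        rows = self.make_rows(panel, [1e-9, 1e-10])
        res = clump(rows, panel, r2=0.1)
        assert res.n_leads == 1
        assert res.leads["SNP"].iloc[0] == panel.blocks[0].snp_ids[1]

    def test_two_unlinked_gws_snps_two_leads(self):
        panel = build_ld_panel(n_blocks=2, snps_per_block=1, rho=0.0, seed=0)
        rows = self.make_rows(panel, [1e-9, 1e-10])
        res = clump(rows, panel)
        assert res.n_leads == 2

    def test_every_lead_is_minimum_p_of_its_clump(self):
        panel = build_ld_panel(n_blocks=5, snps_per_block=8, rho=0.8, seed=3)
        rng = np.random.default_rng(4)
        rows = self.make_rows(panel, 10 ** (-rng.uniform(2, 12, panel.n_snps)))
        res = clump(rows, panel, p1=1e-5, r2=0.2)
        pmap = dict(zip(rows["SNP"], rows["P"]))
        for lead, members in res.members.items():
            for m in members:
                assert pmap[lead] <= pmap[m]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        panel = build_ld_panel(
            n_blocks=4, snps_per_block=5, rho=float(rng.uniform(0.2, 0.9)), seed=seed
        )
        rows = self.make_rows(panel, 10 ** (-rng.uniform(4, 12, panel.n_snps)))
        res = clump(rows, panel, p1=5e-8, r2=0.1)
        oracle = brute_force_clump(rows, panel, 5e-8, 0.1, 250.0)
        assert list(res.leads["SNP"]) == oracle
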