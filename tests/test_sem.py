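"""DWLS SEM engine: fit indices, recovery, EFA, nested comparison."""

import numpy as np
import pytest

from gsemkit import (
    GenomicCovariance,
    GsemModel,
    SemModel,
    build_second_order,
    common_factor_model,
    compare_nested,
    efa,
    fit_cfa,
    smooth_covariance,
    suggest_n_factors,
)
from gsemkit.sem import independence_model, saturated_model
from gsemkit.utils import ConfigurationError, vech
from tests.conftest import EUR_FACTORS, EUR_LOADINGS, EUR_PSI, EUR_TRAITS


def exact_gcov(S, names=None, v_scale=1e-4, m=20000):
    names = names or [f"t{i}" for i in range(S.shape[0])]
    d = S.shape[0] * (S.shape[0] + 1) // 2
    return GenomicCovariance(names, S, np.eye(S.shape[0]), np.eye(d) * v_scale, M=m, n_blocks=200)


def eur_correlation():
    S = EUR_LOADINGS @ EUR_PSI @ EUR_LOADINGS.T
    np.fill_diagonal(S, 1.0)
    return S


class TestSmoothCovariance:
    def test_psd_input_unchanged(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        out, changed = smooth_covariance(S)
        assert not changed
        assert np.array_equal(out, S)

    def test_indefinite_matrix_clipped(self):
        S = np.array([[1.0, 1.2], [1.2, 1.0]])
        assert np.linalg.eigvalsh(S).min() == pytest.approx(-0.2)
        out, changed = smooth_covariance(S, eps=1e-6)
        assert changed
        assert np.linalg.eigvalsh(out).min() >= 1e-6 - 1e-12

    def test_clipping_bound_on_frobenius_change(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((5, 5))
        S = (a + a.T) / 2
        w = np.linalg.eigvalsh(S)
        out, _ = smooth_covariance(S, eps=0.0)
        worst = abs(min(w.min(), 0.0))
        assert np.linalg.norm(out - S) <= worst * np.sqrt(5) + 1e-12


class TestModelSpecification:
    def test_text_parsing_fixed_and_labeled(self):
        m = SemModel.from_text("F =~ a + 0.7*b + lab*c\nF ~~ 1*F\na ~~ a")
        loads = [r for r in m.rows if r.op == "=~"]
        assert loads[0].free and loads[0].value is None
        assert not loads[1].free and loads[1].value == 0.7
        assert loads[2].free and loads[2].label == "lab"
        assert m.latents == ["F"]

    def test_bad_line_rejected(self):
        with pytest.raises(ConfigurationError):
            SemModel.from_text("F == a")

    def test_equality_labels_share_one_parameter(self):
        S = np.array([[1.0, 0.49], [0.49, 1.0]])
        g = exact_gcov(S, ["a", "b"])
        model = GsemModel(g, "F =~ l*a + l*b\nF ~~ 1*F")
        assert model.n_free == 3  # shared loading + two residuals
        res = model.fit()
        assert res.params["l"] == pytest.approx(0.7, abs=1e-6)


class TestFitIndices:
    def test_eur_model_df_and_aic_arithmetic(self):
        """Eight indicators, three correlated factors: 36 moments - 19 free = 17 df."""
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        model = GsemModel(g, common_factor_model(EUR_FACTORS))
        assert model.n_free == 19
        res = model.fit()
        assert res.df == 17
        assert res.aic - res.chi2 == pytest.approx(2 * 19)

    def test_saturated_model_fits_perfectly(self):
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        res = fit_cfa(g, saturated_model(EUR_TRAITS))
        assert res.df == 0
        assert res.chi2 == pytest.approx(0.0, abs=1e-8)
        assert res.cfi == 1.0
        assert res.srmr == pytest.approx(0.0, abs=1e-8)

    def test_noise_free_parameter_recovery(self):
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        res = fit_cfa(g, common_factor_model(EUR_FACTORS))
        assert res.chi2 == pytest.approx(0.0, abs=1e-6)
        lam_err = []
        for f, (inds, col) in zip(EUR_FACTORS, [(EUR_TRAITS[:4], 0), (EUR_TRAITS[4:6], 1), (EUR_TRAITS[6:8], 2)]):
            for ind in inds:
                i = EUR_TRAITS.index(ind)
                lam_err.append(abs(res.standardized_loading(f, ind) - EUR_LOADINGS[i, col]))
        assert max(lam_err) < 1e-4
        assert res.factor_correlation("F1", "F2") == pytest.approx(0.4, abs=1e-4)

    def test_fit_invariant_under_indicator_reordering(self):
        S = eur_correlation()
        perm = [3, 6, 0, 7, 4, 1, 5, 2]
        names_p = [EUR_TRAITS[i] for i in perm]
        g1 = exact_gcov(S, EUR_TRAITS, v_scale=2.0)
        g2 = exact_gcov(S[np.ix_(perm, perm)], names_p, v_scale=2.0)
        r1 = fit_cfa(g1, common_factor_model(EUR_FACTORS))
        factors_p = {f: [i for i in names_p if i in inds] for f, inds in EUR_FACTORS.items()}
        r2 = fit_cfa(g2, common_factor_model(factors_p))
        assert r2.chi2 == pytest.approx(r1.chi2, abs=1e-8)
        assert r2.srmr == pytest.approx(r1.srmr, abs=1e-10)
        assert r2.standardized_loading("F1", "OUD") == pytest.approx(
            r1.standardized_loading("F1", "OUD"), abs=1e-8
        )

    def test_dwls_with_scalar_v_matches_brute_force_grid(self):
        """Unweighted least squares on a 1-factor 3-indicator toy vs grid search."""
        S = np.array([[1.0, 0.35, 0.3], [0.35, 1.0, 0.42], [0.3, 0.42, 1.0]])
        g = exact_gcov(S, ["a", "b", "c"], v_scale=7.3)  # V = c*I: reduces to ULS
        res = fit_cfa(g, common_factor_model({"F": ["a", "b", "c"]}))
        s_obs = vech(S)

        from itertools import product

        def uls(theta):
            la, lb, lc, ua, ub, uc = theta
            lam = np.array([la, lb, lc])
            sig = np.outer(lam, lam) + np.diag([ua, ub, uc])
            return ((vech(sig) - s_obs) ** 2).sum()

        grid = np.linspace(0.3, 0.9, 25)
        best = min(
            (uls((a, b, c, 1 - a * a, 1 - b * b, 1 - c * c)), (a, b, c))
            for a, b, c in product(grid, grid, grid)
        )
        # analytic optimum (exact structure) dominates any grid point
        assert res.objective * 7.3 <= best[0] + 1e-9
        assert res.params["F=~a"] == pytest.approx(0.5, abs=1e-6)

    def test_heywood_case_flagged_not_fatal(self):
        S = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.05], [0.2, 0.05, 1.0]])
        g = exact_gcov(S, ["a", "b", "c"])
        res = fit_cfa(g, common_factor_model({"F": ["a", "b", "c"]}))
        assert res.converged
        assert res.heywood


class TestSecondOrder:
    def make_factor_gcov(self):
        return exact_gcov(EUR_PSI.copy(), ["SUDF", "PSY", "MOOD"])

    def test_two_indicator_loading_product_equals_correlation(self):
        g = exact_gcov(np.array([[1.0, 0.38], [0.38, 1.0]]), ["SUDF", "PSY"])
        fo = SemModel.from_text("SO =~ SUDF + PSY\nSO ~~ 1*SO")
        for f in ["SUDF", "PSY"]:
            fo.add(f, "~~", f, free=False, constraint="unit_total")
        res = GsemModel(g, fo).fit()
        prod = res.params["SO=~SUDF"] * res.params["SO=~PSY"]
        assert prod == pytest.approx(0.38, abs=1e-6)

    def test_residual_is_one_minus_squared_loading(self):
        g = exact_gcov(np.array([[1.0, 0.38], [0.38, 1.0]]), ["SUDF", "PSY"])
        fo = SemModel.from_text("SO =~ l*SUDF + l*PSY\nSO ~~ 1*SO")
        for f in ["SUDF", "PSY"]:
            fo.add(f, "~~", f, free=True, value=0.5)
        res = GsemModel(g, fo).fit()
        lam_std = res.standardized_loading("SO", "SUDF")
        assert res.residual_variance("SUDF") == pytest.approx(1 - lam_std**2, abs=1e-6)

    def test_pairwise_second_order_df_matches_printed_bookkeeping(self):
        """Two second-order latents sharing the SUD factor: 6 moments - 4 free = 2 df."""
        fo = SemModel()
        for f in ["SUDF", "PSY", "MOOD"]:
            fo.add(f, "=~", f + "_dummy")
        so = SemModel.from_text("SO1 =~ SUDF + PSY\nSO2 =~ SUDF + MOOD\nSO1 ~~ 1*SO1\nSO2 ~~ 1*SO2\nSO1 ~~ 0*SO2")
        for f in ["SUDF", "PSY", "MOOD"]:
            so.add(f, "~~", f, free=False, constraint="unit_total")
        g = self.make_factor_gcov()
        model = GsemModel(g, so)
        assert model.n_free == 4
        res = model.fit()
        assert res.df == 2
        assert res.aic - res.chi2 == pytest.approx(8.0)
        assert res.non_identified  # individual loadings only identified up to scale

    def test_build_second_order_replaces_factor_correlations(self):
        first = common_factor_model(EUR_FACTORS)
        so = build_second_order(first, {"SO1": ["F1", "F2"], "SO2": ["F1", "F3"]})
        ops = {(r.lhs, r.op, r.rhs) for r in so.rows}
        assert ("F1", "~~", "F2") not in ops
        assert ("SO1", "=~", "F1") in ops
        assert ("SO1", "~~", "SO2") in ops  # fixed orthogonal
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        res = GsemModel(g, so).fit()
        assert res.converged

    def test_underidentified_spec_rejected(self):
        first = common_factor_model(EUR_FACTORS)
        with pytest.raises(ConfigurationError):
            build_second_order(first, {"SO1": ["F1"]})


class TestCompareNested:
    def test_identical_models_give_zero_difference(self):
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        r = fit_cfa(g, common_factor_model(EUR_FACTORS))
        with pytest.raises(ConfigurationError):
            compare_nested(r, r)

    def test_restriction_violated_detected(self):
        S = eur_correlation()
        g = exact_gcov(S, EUR_TRAITS, v_scale=1e-5)
        full = fit_cfa(g, common_factor_model(EUR_FACTORS))
        restricted = fit_cfa(g, common_factor_model(EUR_FACTORS, correlated=False))
        cmp = compare_nested(restricted, full)
        assert cmp["df_diff"] == 3
        assert cmp["p"] < 1e-6

    FULL_SPEC = """
    F1 =~ AUD + CanUD + TUD + OUD
    F2 =~ SCZ + BD
    F3 =~ MDD + ANX
    F1 ~~ 1*F1
    F2 ~~ 1*F2
    F3 ~~ 1*F3
    F1 ~~ F2
    F1 ~~ F3
    F2 ~~ F3
    """

    def test_null_restriction_calibrated(self):
        """p uniform when the restriction (equal factor correlations) holds.

        The restriction must leave the model locally identified: restricting
        the three factor correlations to a single shared value keeps every
        loading identified, whereas forcing them to zero would leave the
        two-indicator factors' loadings determined only up to their product.
        """
        from scipy import stats

        from gsemkit.utils import unvech

        rng = np.random.default_rng(7)
        psi = np.full((3, 3), 0.4)
        np.fill_diagonal(psi, 1.0)
        S0 = EUR_LOADINGS @ psi @ EUR_LOADINGS.T
        np.fill_diagonal(S0, 1.0)
        v = 4e-4
        restr = (
            self.FULL_SPEC.replace("F1 ~~ F2", "F1 ~~ p*F2")
            .replace("F1 ~~ F3", "F1 ~~ p*F3")
            .replace("F2 ~~ F3", "F2 ~~ p*F3")
        )
        ps = []
        for rep in range(200):
            srep = vech(S0) + rng.standard_normal(36) * np.sqrt(v)
            g = exact_gcov(unvech(srep, 8), EUR_TRAITS, v_scale=v)
            full = fit_cfa(g, self.FULL_SPEC, restarts=0)
            restricted = fit_cfa(g, restr, restarts=0)
            ps.append(compare_nested(restricted, full)["p"])
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestEfa:
    def test_identity_correlation_no_common_variance(self):
        g = exact_gcov(np.eye(6))
        res = efa(g, 2)
        assert np.allclose(res.eigenvalues, 1.0, atol=1e-9)
        assert not res.salient.any().any()

    def test_noise_free_loading_recovery_up_to_permutation(self):
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        res = efa(g, 3)
        L = res.loadings.to_numpy()
        # match each true column to its best estimated column
        errs = []
        for col in range(3):
            truth_col = EUR_LOADINGS[:, col]
            best = min(np.abs(L[:, j] - truth_col).max() for j in range(3))
            errs.append(best)
        assert max(errs) < 0.05

    def test_factor_correlations_recovered_by_promax(self):
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        res = efa(g, 3)
        vals = np.sort(np.abs(res.factor_corr[np.triu_indices(3, 1)]))
        assert np.allclose(vals, np.sort([0.3, 0.4, 0.45]), atol=0.06)

    def test_kaiser_rule_selects_three_factors(self):
        assert suggest_n_factors(eur_correlation()) == 3

    def test_proportion_variance_bounded(self):
        g = exact_gcov(eur_correlation(), EUR_TRAITS)
        res = efa(g, 3)
        assert res.prop_var.sum() <= 1.0 + 1e-9

    def test_invalid_factor_count_rejected(self):
        with pytest.raises(ConfigurationError):
            efa(exact_gcov(np.eye(4)), 4)


def test_efa_matches_r_factanal_oracle():
    """Cross-check ML uniquenesses against R's factanal on one matrix.

    Three indicators per factor with distinct loadings make the ML solution
    unique (two-indicator factors would leave a solution ridge on which the
    two programs could legitimately land at different points).
    """
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    lam = np.zeros((9, 3))
    lam[:3, 0] = [0.8, 0.7, 0.6]
    lam[3:6, 1] = [0.85, 0.75, 0.65]
    lam[6:9, 2] = [0.7, 0.6, 0.5]
    psi = np.array([[1, 0.4, 0.45], [0.4, 1, 0.3], [0.45, 0.3, 1]])
    S = lam @ psi @ lam.T
    np.fill_diagonal(S, 1.0)
    rows = ";".join(",".join(f"{v:.10f}" for v in row) for row in S)
    script = (
        f'm <- do.call(rbind, lapply(strsplit(strsplit("{rows}", ";")[[1]], ","), as.numeric));'
        "f <- factanal(covmat = m, factors = 3, rotation = 'none');"
        "cat(f$uniquenesses, sep=',')"
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
    if out.returncode != 0:
        pytest.skip(f"factanal failed: {out.stderr[:200]}")
    r_uniq = np.array([float(x) for x in out.stdout.strip().split(",")])
    res = efa(exact_gcov(S), 3)
    assert np.allclose(res.uniquenesses, r_uniq, atol=5e-3)
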