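import numpy as np
import pandas as pd
import pytest
from scipy import stats

from schurdle import (
    DesignSpec,
    apply_threshold,
    FitSettings,
    bh_adjust,
    build_design,
    call_de,
    combine_tests,
    component_tests,
    de_test,
    deviance_decomposition,
    estimate_logfc,
    fit_all,
    shrink_fit,
    simulate,
    SimScenario,
)


def _bh_oracle(p):
    """Direct step-up definition: p*m/rank, cumulative min from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


class TestCombineTests:
    def test_chi2_sum_worked_example(self):
        chisq, df, p = combine_tests([3.0], [1], [5.0], [1])
        assert chisq[0] == 8.0 and df[0] == 2
        assert p[0] == pytest.approx(np.exp(-4.0), abs=1e-12)

    def test_zero_statistics_give_p_one(self):
        _, _, p = combine_tests([0.0], [1], [0.0], [1])
        assert p[0] == 1.0

    def test_df_zero_flagged_as_p_one(self):
        _, _, p = combine_tests([0.0], [0], [0.0], [0])
        assert p[0] == 1.0

    def test_symmetric_in_components(self):
        rng = np.random.default_rng(0)
        a, b = rng.chisquare(1, 50), rng.chisquare(1, 50)
        _, _, p1 = combine_tests(a, np.ones(50), b, np.ones(50))
        _, _, p2 = combine_tests(b, np.ones(50), a, np.ones(50))
        np.testing.assert_allclose(p1, p2)

    def test_sum_of_two_chi1_draws_is_chi2_2(self):
        rng = np.random.default_rng(1)
        draws = rng.chisquare(1, 10**5) + rng.chisquare(1, 10**5)
        d = stats.kstest(draws, stats.chi2(2).cdf).statistic
        assert d < 0.01

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            combine_tests([-1.0], [1], [0.0], [1])


class TestBhAdjust:
    def test_worked_vector(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04] * 4
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestCallDe:
    @pytest.mark.parametrize(
        "p_adj,logfc,expected",
        [(0.005, 1.0, True), (0.005, 0.30, False), (0.02, 2.0, False)],
    )
    def test_joint_fdr_and_foldchange_gate(self, p_adj, logfc, expected):
        df = pd.DataFrame({"p_adj": [p_adj], "logfc": [logfc]})
        assert call_de(df)["is_de"].iloc[0] == expected

    def test_thresholds_configurable(self):
        df = pd.DataFrame({"p_adj": [0.02], "logfc": [2.0]})
        assert call_de(df, fdr_cut=0.05)["is_de"].iloc[0]


@pytest.fixture(scope="module")
def fits():
    assay, cov, truth = simulate(
        SimScenario(n_cells=150, n_genes=60, cont_effect=1.0, disc_effect=1.0,
                    frac_affected=0.4, seed=21)
    )
    spec = DesignSpec(cov, ["treatment"], include_cdr=True)
    full = fit_all(assay, build_design(spec, assay))
    shrink_fit(full)
    red = fit_all(assay, build_design(spec.drop_term("treatment"), assay))
    return full, red


class TestComponentTests:
    def test_lrt_statistics_nonnegative_with_counted_df(self, fits):
        full, red = fits
        out = component_tests(full, red, "lrt")
        assert (out["chisq_d"] >= 0).all() and (out["chisq_c"] >= 0).all()
        assert (out["df_d"] == 1).all() and (out["df_c"] == 1).all()

    def test_wald_matches_explicit_quadratic_form(self, fits):
        full, red = fits
        out = component_tests(full, red, "wald", term="treatment")
        from schurdle.data_model import term_columns

        j = term_columns(full.design, "treatment")[0]
        for g in [0, 5, 11]:
            b = full.beta_d[g, j]
            v = full.cov_d[g, j, j]
            assert out["chisq_d"][g] == pytest.approx(b * b / v, rel=1e-9)

    def test_wald_zero_coefficient_gives_zero(self):
        from schurdle.testing import _wald_quadform

        beta = np.zeros((1, 2))
        cov = np.stack([np.eye(2)])
        assert _wald_quadform(beta, cov, [1])[0] == 0.0

    def test_wald_two_df_term_matches_inversion(self):
        from schurdle.testing import _wald_quadform

        rng = np.random.default_rng(3)
        beta = rng.standard_normal((1, 4))
        A = rng.standard_normal((4, 4))
        cov = np.stack([A @ A.T + 4 * np.eye(4)])
        cols = [1, 3]
        b = beta[0, cols]
        V = cov[0][np.ix_(cols, cols)]
        oracle = b @ np.linalg.inv(V) @ b
        assert _wald_quadform(beta, cov, cols)[0] == pytest.approx(oracle, rel=1e-10)

    def test_non_nested_designs_rejected(self, fits):
        full, _ = fits
        with pytest.raises(ValueError, match="nested"):
            component_tests(full, full, "lrt")

    def test_null_lrt_components_are_approximately_chi1(self):
        # Monte-Carlo null: many independent no-effect genes, one shared
        # split; enough cells and moderate detection rates for the binomial
        # LRT's discreteness to wash out
        assay, cov, _ = simulate(
            SimScenario(
                n_cells=500, n_genes=2000, cell_size_sd=0.0,
                baseline_logit_sd=0.75, seed=31,
            )
        )
        spec = DesignSpec(cov, ["treatment"])
        full = fit_all(assay, build_design(spec, assay))
        shrink_fit(full)
        red = fit_all(assay, build_design(spec.drop_term("treatment"), assay))
        out = component_tests(full, red, "lrt")
        for comp in ("chisq_d", "chisq_c"):
            d = stats.kstest(out[comp], stats.chi2(1).cdf).statistic
            assert d < 0.05, comp


class TestEstimateLogfc:
    def test_no_effect_gives_zero(self, null_sim):
        assay, cov, _ = null_sim
        spec = DesignSpec(cov, ["treatment"])
        fit = fit_all(assay, build_design(spec, assay))
        fit.beta_d[:, 1] = 0.0
        fit.beta_c[:, 1] = 0.0
        fc = estimate_logfc(fit, "treatment")
        np.testing.assert_allclose(fc["logfc"], 0.0, atol=1e-12)

    def test_pure_continuous_effect_at_full_detection(self):
        fit = _toy_fit(beta_d=[[30.0, 0.0]], beta_c=[[2.0, 0.7]])
        fc = estimate_logfc(fit, "treatment")
        assert fc["logfc"][0] == pytest.approx(0.7, abs=1e-8)
        assert fc["logfc_disc"][0] == pytest.approx(0.0, abs=1e-8)

    def test_components_sum_to_total_and_match_prediction_oracle(self, small_sim):
        assay, cov, _ = small_sim
        spec = DesignSpec(cov, ["treatment"], include_cdr=True)
        fit = fit_all(assay, build_design(spec, assay))
        fc = estimate_logfc(fit, "treatment")
        np.testing.assert_allclose(
            fc["logfc"], fc["logfc_disc"] + fc["logfc_cont"], atol=1e-10
        )
        # oracle: predict E[Y] = expit(x b_d) * (x b_c) at the two profiles
        X = fit.design.to_numpy()
        xbar = X.mean(axis=0)
        j = list(fit.design.columns).index("treatment[stim]")
        for g in [0, 13]:
            pred = []
            for val in (1.0, 0.0):
                x = xbar.copy()
                x[j] = val
                p = 1 / (1 + np.exp(-x @ fit.beta_d[g]))
                pred.append(p * (x @ fit.beta_c[g]))
            assert fc["logfc"][g] == pytest.approx(pred[0] - pred[1], rel=1e-9)

    def test_missing_term_rejected(self, small_sim):
        assay, cov, _ = small_sim
        fit = fit_all(assay, build_design(DesignSpec(cov, ["treatment"]), assay))
        with pytest.raises(ValueError):
            estimate_logfc(fit, "batch")


def _toy_fit(beta_d, beta_c):
    """Minimal HurdleFit stub with a 2-column design (intercept + treatment)."""
    from schurdle.hurdle import HurdleFit, FitSettings

    n = 10
    X = pd.DataFrame(
        {"(Intercept)": np.ones(n), "treatment": (np.arange(n) >= 5).astype(float)}
    )
    X.attrs["term_map"] = {"treatment": ["treatment"]}
    G = len(beta_d)
    p = 2
    return HurdleFit(
        gene_ids=[f"g{i}" for i in range(G)],
        design=X,
        settings=FitSettings(),
        beta_d=np.array(beta_d, float),
        cov_d=np.stack([np.eye(p)] * G),
        loglik_d=np.zeros(G),
        converged_d=np.ones(G, bool),
        degenerate_d=np.zeros(G, bool),
        beta_c=np.array(beta_c, float),
        cov_c=np.stack([np.eye(p)] * G),
        sigma2=np.ones(G),
        ssr=np.ones(G),
        df_resid_c=np.full(G, 5),
        n_expressed=np.full(G, 8),
        loglik_c=np.zeros(G),
        rank_c=np.full(G, p),
    )


class TestDevianceDecomposition:
    def test_orthogonal_covariate_attributes_nothing(self):
        rng = np.random.default_rng(6)
        assay, cov, _ = simulate(
            SimScenario(n_cells=500, n_genes=40, cell_size_sd=0.0, seed=13)
        )
        cov = cov.copy()
        cov["noise"] = rng.standard_normal(len(cov))
        spec = DesignSpec(cov, ["treatment", "noise"])
        out = deviance_decomposition(assay, spec, "noise")
        assert out["frac_comb"].mean() < 0.01

    def test_fully_determined_binary_pattern_saturates_discrete(self):
        n = 40
        rng = np.random.default_rng(0)
        x = (np.arange(n) >= n // 2).astype(float)
        vals = np.where(x[:, None] > 0, 5.0 + 0.01 * np.arange(n)[:, None], 0.0)
        extra = 3.0 + 0.5 * np.abs(rng.standard_normal((n, 2)))
        assay = apply_threshold(np.hstack([vals, extra]), 0.0)
        cov = pd.DataFrame({"grp": np.where(x > 0, "b", "a")})
        out = deviance_decomposition(assay, DesignSpec(cov, ["grp"]), "grp")
        assert out["frac_d"][0] > 0.9

    def test_matches_manual_refit_sequence(self):
        assay, cov, _ = simulate(
            SimScenario(n_cells=100, n_genes=10, cont_effect=0.8, frac_affected=0.5, seed=3)
        )
        spec = DesignSpec(cov, ["treatment"], include_cdr=True)
        out = deviance_decomposition(assay, spec, "treatment")
        # manual: three fits, component deviances on the full fit's variance scale
        full = fit_all(assay, build_design(spec, assay))
        shrink_fit(full)
        drop = fit_all(assay, build_design(spec.drop_term("treatment"), assay))
        null = fit_all(assay, build_design(DesignSpec(cov, []), assay))
        s2 = full.sigma2_shrunk
        for g in range(10):
            dd = -2 * drop.loglik_d[g] + 2 * full.loglik_d[g]
            dc = (drop.ssr[g] - full.ssr[g]) / s2[g]
            num = max(dd, 0) + max(dc, 0)
            den = -2 * null.loglik_d[g] + null.ssr[g] / s2[g]
            assert out["frac_comb"][g] == pytest.approx(num / den, rel=1e-8)


class TestDeTest:
    def test_null_split_calibration_no_de_calls(self, null_sim):
        from schurdle import null_split

        assay, cov, _ = null_sim
        spec = DesignSpec(null_split(assay, cov, seed=5), ["treatment"], include_cdr=True)
        res, _ = de_test(assay, spec, "treatment")
        frac = (res["p"] < 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / len(res))
        assert res["is_de"].sum() == 0
        assert abs(frac - 0.05) < 3 * se + 0.02

    def test_monotone_adjustment_and_bounds(self, small_sim):
        assay, cov, _ = small_sim
        res, _ = de_test(assay, DesignSpec(cov, ["treatment"], include_cdr=True), "treatment")
        assert ((res["p_adj"] >= res["p"] - 1e-12) & (res["p_adj"] <= 1.0)).all()
        ordered = res.sort_values("p")
        assert (np.diff(ordered["p_adj"]) >= -1e-12).all()
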