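"""GLS fitting, alpha profiling, ANOVA tables, phylANOVA and Holm post hoc."""

import numpy as np
import pandas as pd
import pytest
from scipy import linalg, stats

from phylotherm import (
    PGLS,
    anova,
    covariance,
    fit_ou_alpha,
    gls_fit,
    holm_adjust,
    patristic_distances,
    phyl_anova,
    posthoc_holm,
)
from phylotherm.errors import DesignError, UnidentifiableError, ValidationError
from phylotherm.pgls import build_design
from phylotherm.simulate import SimulationConfig, simulate_trait, simulate_tree

from conftest import random_yule_tree


def ou_trait(tree, alpha, sigma2, rng):
    return simulate_trait(tree, "OU", sigma2=sigma2, alpha=alpha, rng=rng).to_numpy()


class TestGlsFit:
    def test_identity_reproduces_ols(self, rng):
        n = 12
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        res = gls_fit(y, X, np.eye(n))
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(res.params.to_numpy(), beta_ols, rtol=1e-12)

    def test_scaled_identity_same_beta_shifted_loglik(self, rng):
        n = 10
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = rng.normal(size=n)
        r1 = gls_fit(y, X, np.eye(n))
        h = 2.5
        r2 = gls_fit(y, X, h * np.eye(n))
        np.testing.assert_allclose(r1.params, r2.params, rtol=1e-10)

    def test_matches_whitening_oracle(self, rng):
        """beta equals a direct solve of the whitened normal equations."""
        tree = random_yule_tree(12, 31)
        C = covariance(tree, "BM").C
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = simulate_trait(tree, "BM", sigma2=1.0, rng=rng).to_numpy()
        res = gls_fit(y, X, C)
        L = np.linalg.cholesky(C)
        Xw = np.linalg.solve(L, X)
        yw = np.linalg.solve(L, y)
        beta = np.linalg.solve(Xw.T @ Xw, Xw.T @ yw)
        np.testing.assert_allclose(res.params.to_numpy(), beta, rtol=1e-10)

    def test_matches_statsmodels_gls(self, rng):
        import statsmodels.api as sm

        tree = random_yule_tree(12, 13)
        C = covariance(tree, "BM").C
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        y = rng.normal(size=12)
        res = gls_fit(y, X, C)
        ref = sm.GLS(y, X, sigma=C).fit()
        np.testing.assert_allclose(res.params.to_numpy(), ref.params, rtol=1e-8)

    def test_rank_deficiency_names_aliased(self, rng):
        n = 10
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(DesignError, match="x[12]"):
            gls_fit(rng.normal(size=n), X, np.eye(n), names=["Intercept", "x1", "x2"])

    def test_perfect_fit_degenerate(self, rng):
        n = 8
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        with pytest.raises(UnidentifiableError):
            gls_fit(x, X, np.eye(n))


class TestFitOuAlpha:
    def test_alpha_recovery_median(self):
        """Profile ML recovers alpha = 2 on 64-tip trees (seeded replicates)."""
        tree = random_yule_tree(64, 202)
        X = np.ones((64, 1))
        rng = np.random.default_rng(777)
        alphas = [
            fit_ou_alpha(ou_trait(tree, 2.0, 1.0, rng), X, tree).alpha
            for _ in range(60)
        ]
        assert 1.5 <= np.median(alphas) <= 2.7

    def test_iid_data_indistinguishable_from_identity(self):
        """No phylogenetic structure: the fit either lands on the C -> I
        boundary or its likelihood advantage over the identity limit is
        below the 1-df chi-square criterion."""
        tree = simulate_tree(SimulationConfig(n_species=16, tree_model="balanced"))
        X = np.ones((16, 1))
        rng = np.random.default_rng(8)
        hits = 0
        reps = 25
        for _ in range(reps):
            res = fit_ou_alpha(rng.normal(size=16), X, tree)
            if res.alpha_at_boundary or 2 * res.alpha_gap_to_identity < 3.841:
                hits += 1
        assert hits >= 0.8 * reps

    def test_profile_maximum_beats_grid(self):
        tree = random_yule_tree(16, 5)
        rng = np.random.default_rng(5)
        y = ou_trait(tree, 1.0, 1.0, rng)
        res = fit_ou_alpha(y, np.ones((16, 1)), tree)
        assert res.llf >= res.alpha_profile["loglik"].max() - 1e-9

    def test_degenerate_response_raises(self):
        tree = random_yule_tree(8, 2)
        X = np.column_stack([np.ones(8), np.arange(8.0)])
        with pytest.raises(UnidentifiableError):
            fit_ou_alpha(X[:, 1], X, tree)


class TestAnova:
    def test_identity_matches_classical_oneway(self, trait_table, surrogate_tree):
        """With identity correlation the province F is the textbook one-way F."""
        model = PGLS.from_dataframe(
            trait_table, response="MHT", factors=["province"], tree=surrogate_tree
        )
        tab = model.fit("identity").anova("sequential")
        groups = [g["MHT"].to_numpy() for _, g in trait_table.groupby("province")]
        f_ref, _ = stats.f_oneway(*groups)
        assert tab["province"]["F"] == pytest.approx(f_ref, rel=1e-10)

    def test_orthogonal_design_sequential_equals_marginal(self, rng):
        n = 16
        f = np.repeat(["a", "b"], 8)
        x = np.tile([-1.0, 1.0], 8)  # orthogonal to the factor and intercept
        df = pd.DataFrame({
            "species": [f"s{i}" for i in range(n)],
            "g": f, "x": x, "y": rng.normal(size=n),
        })
        design = build_design(df, factors=["g"], covariates=["x"])
        model = PGLS(df["y"].to_numpy(), design, df["species"], response_name="y")
        fit = model.fit("identity")
        seq = fit.anova("sequential").to_frame()
        marg = fit.anova("marginal").to_frame()
        np.testing.assert_allclose(seq["F"], marg["F"], rtol=1e-10)

    def test_sequential_matches_nested_rss_oracle(self, rng):
        """Term F values agree with explicit nested whitened-RSS comparisons."""
        tree = random_yule_tree(12, 77)
        C = covariance(tree, "BM").C
        df = pd.DataFrame({
            "species": tree.tips,
            "g": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "x": rng.normal(size=12),
            "y": rng.normal(size=12),
        })
        design = build_design(df, factors=["g"], covariates=["x"])
        model = PGLS(df["y"].to_numpy(), design, df["species"], tree=tree)
        struct = covariance(tree, "BM")
        tab = model.fit(struct).anova("sequential").to_frame()

        L = np.linalg.cholesky(C)

        def rss(cols):
            Xw = np.linalg.solve(L, cols)
            yw = np.linalg.solve(L, df["y"].to_numpy())
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            r = yw - Xw @ beta
            return r @ r

        X = design.X
        r0 = rss(X[:, :1])
        r1 = rss(X[:, :3])  # + g (2 dummies)
        r2 = rss(X)  # + x
        mse = r2 / (12 - 4)
        assert tab.loc["g", "F"] == pytest.approx(((r0 - r1) / 2) / mse, rel=1e-9)
        assert tab.loc["x", "F"] == pytest.approx((r1 - r2) / mse, rel=1e-9)

    def test_sequential_ss_conservation(self, rng):
        """Sequential SS plus residual RSS reconstruct the whitened total SS."""
        tree = random_yule_tree(12, 7)
        df = pd.DataFrame({
            "species": tree.tips,
            "g": ["a"] * 6 + ["b"] * 6,
            "x": rng.normal(size=12),
            "y": rng.normal(size=12),
        })
        design = build_design(df, factors=["g"], covariates=["x"])
        model = PGLS(df["y"].to_numpy(), design, df["species"], tree=tree)
        struct = covariance(tree, "BM")
        tab = model.fit(struct).anova("sequential").to_frame()
        C = struct.C
        L = np.linalg.cholesky(C)
        yw = np.linalg.solve(L, df["y"].to_numpy())
        ones_w = np.linalg.solve(L, np.ones(12))
        mu = (ones_w @ yw) / (ones_w @ ones_w)
        total = np.sum((yw - mu * ones_w) ** 2)
        assert tab["SS"].sum() + tab.attrs["rss_resid"] == pytest.approx(total, rel=1e-9)


class TestPhylAnova:
    def test_f_is_classical_and_tree_free(self, trait_table, surrogate_tree):
        res = phyl_anova(
            trait_table["MHT"].to_numpy(), trait_table["province"], surrogate_tree,
            n_sim=99, seed=0, species=trait_table["species"].tolist(),
        )
        groups = [g["MHT"].to_numpy() for _, g in trait_table.groupby("province")]
        f_ref, _ = stats.f_oneway(*groups)
        assert res.frame["F"].iloc[0] == pytest.approx(f_ref, rel=1e-12)

    def test_star_tree_p_matches_analytic(self):
        """On a star tree the BM null is iid, so p_simulated ~ p_analytic."""
        cfg = SimulationConfig(n_species=12, tree_model="star")
        tree = simulate_tree(cfg)
        rng = np.random.default_rng(10)
        y = rng.normal(size=12) + np.repeat([0.0, 1.0, 0.0], 4)
        res = phyl_anova(y, np.repeat(["a", "b", "c"], 4), tree, n_sim=4999, seed=3)
        assert res.frame["p_simulated"].iloc[0] == pytest.approx(
            res.frame["p_analytic"].iloc[0], abs=0.02
        )

    def test_power_on_strong_shift(self):
        """A +10 SD shift in one group is always detected on a shallow tree."""
        cfg = SimulationConfig(n_species=12, tree_model="star")
        tree = simulate_tree(cfg)
        groups = np.repeat(["a", "b", "c"], 4)
        rng = np.random.default_rng(99)
        for _ in range(100):
            y = rng.normal(size=12)
            y[groups == "c"] += 10.0
            res = phyl_anova(y, groups, tree, n_sim=999, seed=rng)
            assert res.frame["p_simulated"].iloc[0] <= 0.01

    def test_zero_variance_trait_rejected(self, surrogate_tree):
        with pytest.raises(UnidentifiableError):
            phyl_anova(np.ones(12), ["a"] * 6 + ["b"] * 6, surrogate_tree, n_sim=99)


class TestPosthoc:
    def test_holm_worked_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.20]), [0.03, 0.08, 0.20]
        )

    def test_holm_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=7)
        _, ref, *_ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), ref, rtol=1e-12)

    def test_holm_monotone_and_bounded(self, rng):
        p = rng.uniform(size=6)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_two_group_case_equals_raw_p(self):
        tree = random_yule_tree(8, 12)
        rng = np.random.default_rng(4)
        y = rng.normal(size=8)
        res = posthoc_holm(y, ["a"] * 4 + ["b"] * 4, tree, n_sim=199, seed=1)
        frame = res.to_frame()
        assert len(frame) == 1
        assert frame["p_holm"].iloc[0] == frame["p_sim"].iloc[0]

    def test_p_holm_at_least_p_sim(self, trait_table, surrogate_tree):
        res = posthoc_holm(
            trait_table["LL50"].to_numpy(), trait_table["province"], surrogate_tree,
            n_sim=199, seed=2, covariate=trait_table["MHT"].to_numpy(),
            species=trait_table["species"].tolist(),
        )
        frame = res.to_frame()
        assert np.all(frame["p_holm"] >= frame["p_sim"] - 1e-15)
        assert len(frame) == 3

    def test_familywise_error_under_null(self):
        """Equal true means: the Holm family rejects rarely."""
        tree = random_yule_tree(12, 91)
        groups = np.repeat(["a", "b", "c"], 4)
        rng = np.random.default_rng(123)
        clean = 0
        reps = 300
        for _ in range(reps):
            y = simulate_trait(tree, "BM", sigma2=1.0, rng=rng).to_numpy()
            res = posthoc_holm(y, groups, tree, n_sim=199, seed=rng)
            if res.to_frame()["p_holm"].min() > 0.05:
                clean += 1
        assert clean >= 0.93 * reps

    def test_ancova_adjusted_contrast(self, trait_table, surrogate_tree):
        """With a covariate the estimates are adjusted-mean differences."""
        res = posthoc_holm(
            trait_table["UL50"].to_numpy(), trait_table["province"], surrogate_tree,
            n_sim=99, seed=0, covariate=trait_table["MHT"].to_numpy(),
            species=trait_table["species"].tolist(),
        )
        frame = res.to_frame().set_index("pair")
        # parallel-slopes ANCOVA oracle via statsmodels OLS
        import statsmodels.formula.api as smf

        df = trait_table.rename(columns={"UL50": "y"})
        fit = smf.ols("y ~ C(province) + MHT", data=df).fit()
        adj = {
            lev: fit.params.get(f"C(province)[T.{lev}]", 0.0)
            for lev in ["Argentinian", "Brazilian", "Magellanic"]
        }
        expect = adj["Argentinian"] - adj["Brazilian"]
        assert frame.loc["Argentinian - Brazilian", "estimate"] == pytest.approx(
            expect, rel=1e-8
        )


class TestPglsModel:
    def test_fit_ou_reports_profile(self, trait_table, surrogate_tree):
        model = PGLS.from_dataframe(
            trait_table, response="UL50", factors=["province"], covariates=["MHT"],
            tree=surrogate_tree,
        )
        res = model.fit_ou()
        assert res.alpha > 0
        assert res.alpha_profile is not None and len(res.alpha_profile) == 61
        assert "alpha" in res.summary()

    def test_species_tree_mismatch_rejected(self, trait_table, surrogate_tree):
        bad = trait_table.copy()
        bad.loc[0, "species"] = "Nonexistent_species"
        with pytest.raises(ValidationError, match="Nonexistent_species"):
            PGLS.from_dataframe(
                bad, response="UL50", factors=["province"], tree=surrogate_tree
            )
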