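"""Griffing Method 1 estimation and ANOVA against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from diallelkit import (
    CrossMeanTable,
    DiallelError,
    PlotData,
    combining_ability_anova,
    combining_ability_df,
    effect_standard_errors,
    entry_means,
    griffing_effects,
    rcbd_anova,
)
from conftest import random_means


def _means_from(x, trait="y"):
    p = x.shape[0]
    return CrossMeanTable(trait=trait, parents=tuple(f"P{i+1}" for i in range(p)), x=np.asarray(x, float))


class TestGriffingEffects:
    def test_constant_table(self):
        eff = griffing_effects(_means_from(np.full((5, 5), 3.25)))
        assert eff.mu == pytest.approx(3.25)
        assert np.allclose(eff.g, 0) and np.allclose(eff.s, 0) and np.allclose(eff.rec, 0)

    def test_purely_additive_table(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 2.0, 6)
        a -= a.mean()
        x = 10.0 + a[:, None] + a[None, :]
        eff = griffing_effects(_means_from(x))
        assert eff.mu == pytest.approx(10.0)
        assert np.allclose(eff.g, a, atol=1e-12)
        assert np.allclose(eff.s, 0, atol=1e-12)
        assert np.allclose(eff.rec, 0, atol=1e-12)

    def test_antisymmetric_perturbation_moves_only_reciprocal(self):
        base = random_means(p=5, seed=7)
        rng = np.random.default_rng(8)
        d = rng.normal(0, 1.0, (5, 5))
        d = d - d.T  # antisymmetric
        before = griffing_effects(base)
        after = griffing_effects(_means_from(base.x + d))
        assert np.allclose(after.g, before.g, atol=1e-10)
        assert np.allclose(after.s, before.s, atol=1e-10)
        assert np.allclose(after.rec - before.rec, d, atol=1e-10)

    def test_zero_sum_and_symmetry_invariants(self):
        eff = griffing_effects(random_means(p=6, seed=2))
        assert eff.g.sum() == pytest.approx(0, abs=1e-9)
        assert np.allclose(eff.s, eff.s.T)
        assert np.allclose(eff.rec, -eff.rec.T)
        assert np.allclose(np.diag(eff.rec), 0)
        # row sums of s vanish for Method 1
        assert np.allclose(eff.s.sum(axis=1), 0, atol=1e-9)

    def test_reconstruction_every_cell(self):
        tab = random_means(p=7, seed=5)
        eff = griffing_effects(tab)
        recon = eff.mu + eff.g[:, None] + eff.g[None, :] + eff.s + eff.rec
        assert np.allclose(recon, tab.x, atol=1e-10)

    def test_least_squares_projection_oracle(self):
        """Closed-form g equals the LS projection onto the additive subspace."""
        tab = random_means(p=4, seed=13)
        p = 4
        cols = [np.ones(p * p)]
        for k in range(p - 1):  # sum-zero parameterization g_k - g_p
            u = np.zeros(p)
            u[k], u[-1] = 1.0, -1.0
            cols.append((u[:, None] + u[None, :]).ravel())
        A = np.column_stack(cols)
        coef, *_ = np.linalg.lstsq(A, tab.x.ravel(), rcond=None)
        g_free = coef[1:]
        g_ls = np.append(g_free, -g_free.sum())
        eff = griffing_effects(tab)
        assert np.allclose(eff.g, g_ls, atol=1e-9)
        assert eff.mu == pytest.approx(coef[0], abs=1e-9)


class TestRcbdAnova:
    def test_df_for_eight_parents_three_reps(self, sim_data):
        tab = rcbd_anova(sim_data, "GY").table.set_index("source")
        assert tab.loc["Replications", "df"] == 2
        assert tab.loc["Treatments", "df"] == 63
        assert tab.loc["Residual", "df"] == 126

    def test_zero_variance_data(self):
        rows = [
            {"female": f, "male": m, "rep": k, "y": 4.0}
            for f in "ABC"
            for m in "ABC"
            for k in (1, 2)
        ]
        tab = rcbd_anova(PlotData.from_dataframe(pd.DataFrame(rows)), "y").table
        assert np.allclose(tab["SS"], 0)

    def test_single_rep_is_an_error(self):
        rows = [{"female": f, "male": m, "rep": 1, "y": 1.0} for f in "ABC" for m in "ABC"]
        data = PlotData.from_dataframe(pd.DataFrame(rows))
        with pytest.raises(DiallelError):
            rcbd_anova(data, "y")

    def test_ss_additivity_brute_force(self, sim_data):
        tab = rcbd_anova(sim_data, "GY").table.set_index("source")
        y = sim_data.df["GY"].to_numpy()
        ss_total = ((y - y.mean()) ** 2).sum()
        assert tab.loc["Total", "SS"] == pytest.approx(ss_total, rel=1e-12)
        parts = tab.loc[["Replications", "Treatments", "Residual"], "SS"].sum()
        assert parts == pytest.approx(ss_total, rel=1e-12)

    def test_statsmodels_oracle(self, sim_data):
        """Independent two-way fixed-effects fit reproduces SS and F."""
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        df = sim_data.df.copy()
        df["entry"] = df["female"] + ":" + df["male"]
        fit = ols("GY ~ C(rep) + C(entry)", data=df).fit()
        aov = sm.stats.anova_lm(fit, typ=1)
        tab = rcbd_anova(sim_data, "GY").table.set_index("source")
        assert tab.loc["Replications", "SS"] == pytest.approx(aov.loc["C(rep)", "sum_sq"])
        assert tab.loc["Treatments", "SS"] == pytest.approx(aov.loc["C(entry)", "sum_sq"])
        assert tab.loc["Residual", "SS"] == pytest.approx(aov.loc["Residual", "sum_sq"])
        assert tab.loc["Treatments", "F"] == pytest.approx(aov.loc["C(entry)", "F"])


class TestCombiningAbilityAnova:
    def test_df_partition_eight_parents(self, sim_means):
        anova = combining_ability_anova(sim_means, ms_residual=47.0, r=3)
        tab = anova.table.set_index("source")
        assert tab.loc["Treatments", "df"] == 63
        for src, df in (("GCA", 7), ("SCA", 28), ("Reciprocal", 28), ("Maternal", 7), ("Non-Maternal", 21)):
            assert tab.loc[src, "df"] == df
        dfs = combining_ability_df(8)
        assert dfs["GCA"] + dfs["SCA"] + dfs["Reciprocal"] == 63
        assert dfs["Maternal"] + dfs["Non-Maternal"] == dfs["Reciprocal"]

    def test_symmetric_table_kills_reciprocal(self):
        tab = random_means(p=5, seed=21)
        x = (tab.x + tab.x.T) / 2
        anova = combining_ability_anova(_means_from(x), ms_residual=1.0, r=2).table.set_index("source")
        for src in ("Reciprocal", "Maternal", "Non-Maternal"):
            assert anova.loc[src, "SS"] == pytest.approx(0, abs=1e-18)
            assert anova.loc[src, "p"] == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_ss_additivity_random_instances(self, seed):
        """GCA+SCA+Reciprocal SS equal the brute-force spread of the 16 means."""
        tab = random_means(p=4, seed=seed)
        anova = combining_ability_anova(tab, ms_residual=2.0, r=3).table.set_index("source")
        brute = ((tab.x - tab.x.mean()) ** 2).sum()
        assert anova.loc["Treatments", "SS"] == pytest.approx(brute, rel=1e-12)
        parts = anova.loc[["GCA", "SCA", "Reciprocal"], "SS"].sum()
        assert parts == pytest.approx(brute, rel=1e-12)
        rec = anova.loc[["Maternal", "Non-Maternal"], "SS"].sum()
        assert rec == pytest.approx(anova.loc["Reciprocal", "SS"], rel=1e-12)

    def test_plot_basis_scales_ss_by_r(self, sim_means):
        mean_tab = combining_ability_anova(sim_means, 47.0, 3, basis="mean").table
        plot_tab = combining_ability_anova(sim_means, 47.0, 3, basis="plot").table
        assert np.allclose(plot_tab["SS"], mean_tab["SS"] * 3)
        assert np.allclose(
            plot_tab["F"].dropna(), mean_tab["F"].dropna()
        )  # F is basis-invariant

    def test_nonpositive_residual_rejected(self, sim_means):
        with pytest.raises(DiallelError):
            combining_ability_anova(sim_means, ms_residual=0.0, r=3)


class TestStandardErrors:
    def test_zero_error_variance(self):
        se = effect_standard_errors(0.0, 3, 8)
        assert all(v == 0 for v in se.values())

    def test_scaling_law(self):
        se1 = effect_standard_errors(10.0, 3, 8)
        se2 = effect_standard_errors(20.0, 3, 8)
        for k in se1:
            assert se2[k] == pytest.approx(se1[k] * np.sqrt(2))

    def test_monte_carlo_oracle(self):
        """SEs match empirical sds over 10,000 error-only diallel mean tables."""
        p, r, sigma2 = 4, 3, 4.0
        rng = np.random.default_rng(99)
        n = 10_000
        x = rng.normal(0.0, np.sqrt(sigma2 / r), (n, p, p))  # entry means, no effects
        row = x.sum(axis=2)
        col = x.sum(axis=1)
        tot = x.sum(axis=(1, 2))
        g0 = (row[:, 0] + col[:, 0]) / (2 * p) - tot / p**2
        m0 = (row[:, 0] - col[:, 0]) / (2 * p)
        rec01 = (x[:, 0, 1] - x[:, 1, 0]) / 2
        marg = row + col
        s01 = (x[:, 0, 1] + x[:, 1, 0]) / 2 - (marg[:, 0] + marg[:, 1]) / (2 * p) + tot / p**2
        gf0 = row[:, 0] / p - tot / p**2
        se = effect_standard_errors(sigma2, r, p)
        for sample, key in ((g0, "g"), (m0, "m"), (rec01, "rec"), (s01, "s"), (gf0, "g_fm")):
            assert sample.std() == pytest.approx(se[key], rel=0.03)

    def test_significance_stars(self, sim_means):
        eff = griffing_effects(sim_means, ms_residual=47.44, r=3)
        z = np.abs(eff.g) / eff.se["g"]
        assert ((z > 2.576) == (eff.sig["g"] == "**")).all()
        assert ((z > 1.96) == (np.isin(eff.sig["g"], ["*", "**"]))).all()
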