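"""Nested ANOVA, Tukey HSD, correlations/slopes, ANCOVA, MANOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import adipoflim as af
from adipoflim.exceptions import ValidationError


def balanced_table(rng, a=2, b=2, m=3, n=2, effects=None):
    """Balanced temperature × depot × mouse(temperature) table."""
    effects = effects or {}
    rows = []
    for ti, t in enumerate([f"T{i}" for i in range(a)]):
        for mi in range(m):
            mouse = f"{t}-m{mi}"
            mouse_eff = rng.normal(0, effects.get("mouse_sd", 0.0))
            for di, d in enumerate([f"D{i}" for i in range(b)]):
                mu = (effects.get("temp", 0.0) * ti
                      + effects.get("depot", 0.0) * di)
                for _ in range(n):
                    rows.append(dict(
                        temperature=t, depot=d, mouse=mouse,
                        y=mu + mouse_eff + rng.normal(0, effects.get("sd", 1.0)),
                    ))
    return pd.DataFrame(rows)


class TestNestedMixedAnova:
    def test_matches_hand_computed_ems_on_toy_table(self):
        rng = np.random.default_rng(1)
        df = balanced_table(rng)
        res = af.nested_mixed_anova(df, "y")
        assert res.balanced

        # independent oracle: explicit sums of squares by loops
        a, b, m, n = 2, 2, 3, 2
        grand = df.y.mean()
        ss_t = sum(
            b * m * n * (df[df.temperature == t].y.mean() - grand) ** 2
            for t in df.temperature.unique()
        )
        ss_m = 0.0
        for t in df.temperature.unique():
            sub = df[df.temperature == t]
            for mouse in sub.mouse.unique():
                ss_m += b * n * (sub[sub.mouse == mouse].y.mean()
                                 - sub.y.mean()) ** 2
        ms_t = ss_t / (a - 1)
        ms_m = ss_m / (a * (m - 1))
        assert res.f("temperature") == pytest.approx(ms_t / ms_m, rel=1e-10)

    def test_perfect_depot_separation_gives_tiny_p(self):
        rng = np.random.default_rng(2)
        df = balanced_table(rng, effects={"depot": 5.0, "sd": 1e-6})
        res = af.nested_mixed_anova(df, "y")
        assert res.p("depot") < 1e-10

    def test_single_mouse_per_cell_signaled(self):
        rng = np.random.default_rng(3)
        df = balanced_table(rng, m=1)
        with pytest.raises(ValidationError, match="untestable"):
            af.nested_mixed_anova(df, "y")

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(4)
        df = balanced_table(rng, m=30, n=8,
                            effects={"mouse_sd": 2.0, "sd": 1.0})
        res = af.nested_mixed_anova(df, "y")
        assert res.variance_components["mouse"] == pytest.approx(4.0, rel=0.5)
        assert res.variance_components["residual"] == pytest.approx(1.0, rel=0.2)

    def test_unbalanced_design_runs_with_flag(self):
        rng = np.random.default_rng(5)
        df = balanced_table(rng).iloc[:-3]
        res = af.nested_mixed_anova(df, "y")
        assert not res.balanced
        assert np.isfinite(res.f("depot"))


class TestTukeyHsd:
    def test_two_groups_equal_pooled_t_test(self):
        rng = np.random.default_rng(6)
        g1, g2 = rng.normal(0, 1, 12), rng.normal(0.7, 1, 12)
        ms = (g1.var(ddof=1) * 11 + g2.var(ddof=1) * 11) / 22
        tk = af.tukey_hsd({"A": g1.mean(), "B": g2.mean()}, ms, 22, 12)
        t_p = sps.ttest_ind(g1, g2).pvalue
        assert tk.p_adj.iloc[0] == pytest.approx(t_p, rel=1e-6)

    def test_identical_means_give_p_one(self):
        tk = af.tukey_hsd({"A": 1.0, "B": 1.0, "C": 1.0}, 1.0, 20, 5)
        assert np.allclose(tk.p_adj, 1.0)

    def test_three_groups_match_scipy_tukey_on_raw_data(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(mu, 1, 10) for mu in (0.0, 0.5, 1.5)]
        means = {f"g{i}": g.mean() for i, g in enumerate(groups)}
        ms = np.mean([g.var(ddof=1) for g in groups])
        ours = af.tukey_hsd(means, ms, 27, 10)
        ref = sps.tukey_hsd(*groups)
        for row in ours.itertuples():
            i, j = int(row.group1[1]), int(row.group2[1])
            assert row.p_adj == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_adjusted_p_not_smaller_than_pairwise_t(self):
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(0.3 * i, 1, 8) for i in range(4)}
        ms = np.mean([g.var(ddof=1) for g in groups.values()])
        df_err = 4 * 7
        tk = af.tukey_hsd({k: v.mean() for k, v in groups.items()}, ms,
                          df_err, 8)
        for row in tk.itertuples():
            t_stat = abs(row.diff) / np.sqrt(ms * 2 / 8)
            p_t = 2 * sps.t.sf(t_stat, df_err)
            assert row.p_adj >= p_t - 1e-12

    def test_invalid_df_rejected(self):
        with pytest.raises(ValidationError):
            af.tukey_hsd({"A": 0, "B": 1}, 1.0, 0, 5)


class TestPearsonAndSlope:
    def test_perfect_negative_correlation(self):
        x = np.arange(10.0)
        r, p = af.pearson(x, -x)
        assert r == pytest.approx(-1.0)
        assert p < 1e-10

    def test_null_pairs_uniform_p(self):
        rng = np.random.default_rng(9)
        ps = [af.pearson(rng.normal(size=30), rng.normal(size=30))[1]
              for _ in range(200)]
        # KS against uniform
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_signaled(self):
        with pytest.raises(ValidationError):
            af.pearson(np.ones(10), np.arange(10.0))

    def test_exact_line_recovered(self):
        x = np.linspace(0, 1, 20)
        slope, intercept, se = af.ols_slope(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_permutation_destroys_slope(self):
        rng = np.random.default_rng(10)
        df = af.generate_bivariate_summaries(
            slope=-1.5, intercept=1.2, x_mean=0.7, x_sd=0.05, n=265,
            target_correlation=-0.89, seed=11,
        )
        slope, _, se = af.ols_slope(df.x, df.y)
        assert abs(slope - (-1.5)) < 2 * se
        y_perm = rng.permutation(df.y.to_numpy())
        slope_p, _, se_p = af.ols_slope(df.x, y_perm)
        assert abs(slope_p) < 3 * se_p


class TestAncova:
    def test_zero_noise_distinct_slopes(self):
        x = np.linspace(0, 1, 20)
        df = pd.DataFrame({
            "g": ["a"] * 20 + ["b"] * 20,
            "x": np.concatenate([x, x]),
            "y": np.concatenate([2 * x, -1 * x + 0.5]),
        })
        res = af.ancova_slopes(df, "g", "x", "y")
        assert res.p_interaction < 1e-10
        slopes = dict(zip(res.slopes.group, res.slopes.slope))
        assert slopes["a"] == pytest.approx(2.0)
        assert slopes["b"] == pytest.approx(-1.0)

    def test_null_interaction_p_roughly_uniform(self):
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(100):
            x = rng.normal(0, 1, 60)
            y = 1.0 + 0.5 * x + rng.normal(0, 0.3, 60)
            df = pd.DataFrame({"g": ["a"] * 30 + ["b"] * 30, "x": x, "y": y})
            ps.append(af.ancova_slopes(df, "g", "x", "y").p_interaction)
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_small_groups_excluded_with_warning(self):
        df = pd.DataFrame({
            "g": ["a"] * 10 + ["b"] * 10 + ["c"] * 2,
            "x": np.r_[np.linspace(0, 1, 10), np.linspace(0, 1, 10), [0, 1]],
            "y": np.r_[np.linspace(0, 2, 10), np.linspace(0, 1, 10), [0, 1]],
        })
        with pytest.warns(UserWarning, match="excluding group 'c'"):
            res = af.ancova_slopes(df, "g", "x", "y")
        assert set(res.slopes.group) == {"a", "b"}


class TestManova:
    def _table(self, rng, sep=0.0, n=30):
        rows = []
        for gi, g in enumerate(["A", "B", "C"]):
            mu = np.array([0.3, 0.6, 0.9]) + sep * gi
            for _ in range(n):
                v = mu + rng.normal(0, 0.05, 3)
                rows.append(dict(depot=g, redox=v[0], nadh_llif=v[1],
                                 lipid_llif=v[2]))
        return pd.DataFrame(rows)

    def test_single_response_equals_oneway_anova(self):
        rng = np.random.default_rng(13)
        df = self._table(rng, sep=0.05)
        res = af.manova(df, "depot", responses=("redox",))
        f_ref = sps.f_oneway(*[sub.redox for _, sub in df.groupby("depot")])
        assert res.f_approx == pytest.approx(f_ref.statistic, abs=1e-8)
        assert res.p == pytest.approx(f_ref.pvalue, abs=1e-8)

    def test_identical_group_means_lambda_near_one(self):
        rng = np.random.default_rng(14)
        df = self._table(rng, sep=0.0, n=200)
        res = af.manova(df, "depot")
        assert res.wilks_lambda > 0.95

    def test_separated_clouds_reject_strongly(self):
        rng = np.random.default_rng(15)
        df = self._table(rng, sep=0.15)
        res = af.manova(df, "depot")
        assert res.wilks_lambda < 0.5
        assert res.p < 1e-3

    def test_matches_statsmodels_wilks(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(16)
        df = self._table(rng, sep=0.05)
        res = af.manova(df, "depot")
        sm = MANOVA.from_formula("redox + nadh_llif + lipid_llif ~ depot",
                                 data=df)
        tbl = sm.mv_test().results["depot"]["stat"]
        assert res.wilks_lambda == pytest.approx(
            float(tbl.loc["Wilks' lambda", "Value"]), abs=1e-10
        )

    def test_small_groups_rejected(self):
        df = self._table(np.random.default_rng(17), n=3)
        with pytest.raises(ValidationError):
            af.manova(df, "depot")


class TestHeterogeneity:
    def test_constant_cell_has_zero_sd(self):
        df = pd.DataFrame({
            "depot": ["BAT"] * 5 + ["WAT"] * 5,
            "temperature": ["RT"] * 10,
            "redox": [0.4] * 5 + [0.2] * 5,
            "nadh_llif": np.r_[np.full(5, 0.5), np.linspace(0.7, 0.8, 5)],
            "lipid_llif": [0.9] * 10,
        })
        sd_tab, _ = af.heterogeneity(df)
        bat = sd_tab[sd_tab.depot == "BAT"].iloc[0]
        assert bat["sd_redox"] == 0.0

    def test_doubled_within_cell_sd_recovered(self):
        rng = np.random.default_rng(18)
        rows = []
        for depot, sd in (("BAT", 0.02), ("scWAT", 0.04)):
            for _ in range(300):
                rows.append(dict(depot=depot, temperature="RT",
                                 redox=rng.normal(0.3, sd),
                                 nadh_llif=rng.normal(0.7, 0.02),
                                 lipid_llif=rng.normal(0.9, 0.01)))
        sd_tab, _ = af.heterogeneity(pd.DataFrame(rows))
        ratio = (sd_tab.set_index("depot").loc["scWAT", "sd_redox"]
                 / sd_tab.set_index("depot").loc["BAT", "sd_redox"])
        assert ratio == pytest.approx(2.0, rel=0.15)

    def test_ellipse_coverage_near_95_percent(self):
        rng = np.random.default_rng(19)
        n = 4000
        x = rng.normal(0.7, 0.05, n)
        y = 1.0 - 0.8 * x + rng.normal(0, 0.02, n)
        ell = af.confidence_ellipse(x, y, 0.95)
        cov = np.array([[ell["cov_xx"], ell["cov_xy"]],
                        [ell["cov_xy"], ell["cov_yy"]]])
        inv = np.linalg.inv(cov)
        d = np.stack([x - ell["mean_x"], y - ell["mean_y"]])
        maha = np.einsum("in,ij,jn->n", d, inv, d)
        coverage = (maha <= sps.chi2.ppf(0.95, 2)).mean()
        assert coverage == pytest.approx(0.95, abs=0.02)

    def test_small_cells_skipped_with_warning(self):
        df = pd.DataFrame({
            "depot": ["BAT"] * 2, "temperature": ["RT"] * 2,
            "redox": [0.1, 0.2], "nadh_llif": [0.5, 0.6],
            "lipid_llif": [0.9, 0.8],
        })
        with pytest.warns(UserWarning, match="skipping cell"):
            sd_tab, _ = af.heterogeneity(df)
        assert sd_tab.empty
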