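"""Relative growth, GLM, repeated-measures ANOVA and the mixed model."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from coralchron import growth_stats as gs
from coralchron import study


def _growth_table(values: dict, years=range(1998, 2017)) -> pd.DataFrame:
    rows = []
    for core, series in values.items():
        for y, v in zip(years, np.broadcast_to(series, len(list(years)))):
            rows.append({"core_id": core, "location_id": core[:3], "year": y,
                         "extension_cm": float(v)})
    return pd.DataFrame(rows)


class TestRelativeExtension:
    def test_constant_core_is_zero_everywhere(self):
        rel, excluded = gs.relative_extension(_growth_table({"a": 1.2}))
        assert np.allclose(rel["relative_extension"], 0.0)
        assert excluded == []

    def test_formula_minus_thirty_percent(self):
        ext = np.ones(19)
        ext[-1] = 0.7          # 2016 vs baseline mean of 1.0
        rel, _ = gs.relative_extension(_growth_table({"a": ext}))
        assert rel.loc[rel.year == 2016, "relative_extension"].iloc[0] == \
            pytest.approx(-30.0)

    def test_baseline_mean_is_zero_for_every_core(self):
        rng = np.random.default_rng(0)
        tbl = _growth_table({f"c{i}": rng.uniform(0.5, 1.5, 19)
                             for i in range(6)})
        rel, _ = gs.relative_extension(tbl)
        base = rel[rel.year.between(1998, 2012)]
        for _, sub in base.groupby("core_id"):
            assert sub["relative_extension"].mean() == pytest.approx(0, abs=1e-9)

    def test_cores_with_gaps_excluded_and_reported(self):
        tbl = _growth_table({"full": 1.0, "short": 1.1})
        tbl = tbl[~((tbl.core_id == "short") & (tbl.year < 2005))]
        rel, excluded = gs.relative_extension(tbl)
        assert excluded == ["short"]
        assert set(rel["core_id"]) == {"full"}


class TestComposite:
    def test_identical_cores_zero_se(self):
        tbl = _growth_table({"a": 1.0, "b": 1.0})
        rel, _ = gs.relative_extension(tbl)
        comp = gs.composite(rel)
        assert np.allclose(comp["se"], 0.0)

    def test_opposite_cores_cancel(self):
        up, down = np.ones(19), np.ones(19)
        up[-1], down[-1] = 1.1, 0.9
        rel, _ = gs.relative_extension(_growth_table({"a": up, "b": down}))
        comp = gs.composite(rel)
        assert comp.loc[comp.year == 2016, "relative_extension"].iloc[0] == \
            pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_stacked_mean(self):
        rng = np.random.default_rng(1)
        tbl = _growth_table({f"c{i}": rng.uniform(0.5, 1.5, 19)
                             for i in range(5)})
        rel, _ = gs.relative_extension(tbl)
        comp = gs.composite(rel).set_index("year")
        for y, sub in rel.groupby("year"):
            assert comp.loc[y, "relative_extension"] == \
                pytest.approx(sub["relative_extension"].mean())

    def test_single_core_se_missing(self):
        rel, _ = gs.relative_extension(_growth_table({"a": 1.0}))
        comp = gs.composite(rel)
        assert comp["se"].isna().all()


class TestGLM:
    def test_exact_line_recovered(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2 * df["x"]
        fit = gs.fit_glm(df, "y", "x")
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=5)})
        df["y"] = 1.5 - 0.8 * df["x"] + rng.normal(0, 0.3, 5)
        fit = gs.fit_glm(df, "y", "x")
        A = np.column_stack([np.ones(5), df["x"]])
        beta = np.linalg.inv(A.T @ A) @ A.T @ df["y"].to_numpy()
        assert fit.params["intercept"] == pytest.approx(beta[0], rel=1e-10)
        assert fit.params["x"] == pytest.approx(beta[1], rel=1e-10)

    def test_slope_pvalue_uses_t_distribution(self):
        from scipy import stats
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=12)})
        df["y"] = 0.3 * df["x"] + rng.normal(0, 1, 12)
        fit = gs.fit_glm(df, "y", "x")
        t = fit.params["x"] / fit.bse["x"]
        assert fit.pvalues["x"] == pytest.approx(
            2 * stats.t.sf(abs(t), len(df) - 2))

    def test_zero_variance_covariate_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="zero variance"):
            gs.fit_glm(df, "y", "x")


class TestRmAnova:
    def _toy(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for c in range(3):
            base = rng.normal(1.2, 0.1)
            for j, b in enumerate(["b1", "b2", "b3", "b4"]):
                rows.append({"core_id": f"c{c}", "bin": b,
                             "extension_cm": base + rng.normal(0, 0.05)
                             + (shift if b == "b4" else 0)})
        return pd.DataFrame(rows)

    def test_identical_bin_means_give_zero_f(self):
        rows = [{"core_id": f"c{c}", "bin": b, "extension_cm": 1.0 + 0.1 * c}
                for c in range(4) for b in ["b1", "b2", "b3"]]
        res = gs.rm_anova_tukey(pd.DataFrame(rows))
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert not res.tukey["significant"].any()

    def test_sum_of_squares_partition_matches_bruteforce(self):
        df = self._toy(shift=0.2)
        res = gs.rm_anova_tukey(df)
        wide = df.pivot(index="core_id", columns="bin", values="extension_cm")
        x = wide.to_numpy()
        grand = x.mean()
        ss_total = ((x - grand) ** 2).sum()
        ss_bins = (x.shape[0] * (x.mean(axis=0) - grand) ** 2).sum()
        ss_subj = (x.shape[1] * (x.mean(axis=1) - grand) ** 2).sum()
        got = res.anova.set_index("source")["ss"]
        assert got["bins"] == pytest.approx(ss_bins, abs=1e-12)
        assert got["subjects"] == pytest.approx(ss_subj, abs=1e-12)
        assert got["bins"] + got["subjects"] + got["error"] == \
            pytest.approx(ss_total, abs=1e-9)

    def test_agrees_with_pingouin(self):
        import pingouin
        df = self._toy(shift=0.15, seed=3)
        res = gs.rm_anova_tukey(df)
        ref = pingouin.rm_anova(data=df, dv="extension_cm", within="bin",
                                subject="core_id", detailed=True)
        assert res.F == pytest.approx(float(ref.loc[0, "F"]), rel=1e-9)
        assert res.p == pytest.approx(float(ref.loc[0, "p_unc"]), rel=1e-6)

    def test_step_down_final_bin_detected(self):
        res = gs.rm_anova_tukey(self._toy(shift=-0.3, seed=1))
        assert res.p < 0.05
        sig = res.tukey[res.tukey["significant"]]
        assert all("b4" in (a, b) for a, b in zip(sig.level_a, sig.level_b))

    def test_incomplete_subjects_excluded(self):
        df = self._toy()
        df = df[~((df.core_id == "c0") & (df["bin"] == "b4"))]
        res = gs.rm_anova_tukey(df)
        assert res.excluded_subjects == ["c0"]
        assert res.n_subjects == 2


class TestMixedModel:
    def test_collapses_to_ols_without_random_structure(self):
        rng = np.random.default_rng(6)
        rows = []
        for c in range(4):
            for y in range(2000, 2010):
                x = rng.normal()
                rows.append({"core_id": f"c{c}", "location_id": "L",
                             "year": y, "x": x,
                             "y": 1.0 + 0.5 * x + rng.normal(0, 0.2)})
        df = pd.DataFrame(rows)
        mm = gs.fit_mixed_model(df, gs.ModelSpec(response="y", fixed=("x",),
                                                 random=(), ar1=False))
        ols = gs.fit_glm(df, "y", "x")
        assert mm.params["x"] == pytest.approx(ols.params["x"], abs=1e-6)
        assert mm.params["intercept"] == pytest.approx(
            ols.params["intercept"], abs=1e-6)
        assert mm.loglik == pytest.approx(ols.loglik, abs=1e-6)

    def test_matches_nlme_oracle(self, tmp_path):
        """ML fit agrees with R nlme::lme (random intercept + corAR1)."""
        rng = np.random.default_rng(42)
        rows = []
        for c in range(6):
            b = rng.normal(0, 0.15)
            e = np.empty(12)
            e[0] = rng.normal(0, 0.2)
            for t in range(1, 12):
                e[t] = 0.4 * e[t - 1] + np.sqrt(1 - 0.16) * rng.normal(0, 0.2)
            x = rng.normal(0, 1, 12)
            for t in range(12):
                rows.append({"core_id": f"c{c}", "location_id": "L",
                             "year": 2000 + t, "x": x[t],
                             "y": 1.0 + 0.3 * x[t] + b + e[t]})
        df = pd.DataFrame(rows)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        fit = gs.fit_mixed_model(df, gs.ModelSpec(response="y", fixed=("x",),
                                                  random=("core",), ar1=True))
        script = tmp_path / "fit.R"
        script.write_text(f"""
            library(nlme)
            d <- read.csv("{csv}")
            m <- lme(y ~ x, random = ~1|core_id,
                     correlation = corAR1(form = ~year|core_id),
                     data = d, method = "ML")
            cat(fixef(m),
                as.numeric(coef(m$modelStruct$corStruct, unconstrained=FALSE)),
                logLik(m), sep="\\n")
        """)
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ref = [float(v) for v in out.stdout.split()]
        assert fit.params["intercept"] == pytest.approx(ref[0], abs=1e-4)
        assert fit.params["x"] == pytest.approx(ref[1], abs=1e-4)
        assert fit.rho == pytest.approx(ref[2], abs=1e-3)
        assert fit.loglik == pytest.approx(ref[3], abs=1e-3)

    def test_recovers_generating_coefficients_within_ci(self):
        s = study.generate_study(seed=17)
        fit = gs.fit_mixed_model(s["growth"], method="reml")
        ci = fit.conf_int()
        p = s["params"]
        for name, true in [("kd490", p.beta_kd),
                           ("sst_summer", p.beta_sst_summer),
                           ("dhw", p.beta_dhw)]:
            assert ci.loc[name, "lower"] <= true <= ci.loc[name, "upper"]
        assert fit.params["kd490"] < 0

    def test_aic_identity_and_order_invariance(self):
        s = study.generate_study(seed=8)
        g = s["growth"]
        fits = [gs.fit_mixed_model(g, gs.ModelSpec(fixed=f))
                for f in [("kd490",), ("kd490", "dhw"),
                          ("kd490", "sst_summer", "dhw")]]
        for f in fits:
            assert f.aic == pytest.approx(2 * f.n_parameters - 2 * f.loglik)
        ranked = gs.model_selection_aic(fits)
        ranked_rev = gs.model_selection_aic(fits[::-1])
        assert ranked["name"].tolist() == ranked_rev["name"].tolist()
        assert ranked["delta_aic"].iloc[0] == 0.0

    def test_mixed_responses_rejected(self):
        df = pd.DataFrame({"core_id": list("aabb"), "location_id": "L",
                           "year": [1, 2, 1, 2],
                           "u": [1.0, 2, 3, 4], "v": [1.0, 2, 3, 4],
                           "x": [0.1, 0.2, 0.3, 0.4]})
        fa = gs.fit_glm(df, "u", "x")
        fb = gs.fit_glm(df, "v", "x")
        with pytest.raises(ValueError, match="different responses"):
            gs.model_selection_aic([fa, fb])

    def test_single_core_rejected(self):
        df = pd.DataFrame({"core_id": "only", "location_id": "L",
                           "year": range(2000, 2010),
                           "extension_cm": np.linspace(1, 1.5, 10),
                           "kd490": 0.05, "sst_summer": 27.9, "dhw": 0.0})
        with pytest.raises(ValueError, match="two cores"):
            gs.fit_mixed_model(df)
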