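"""Risk-model fitting: design construction, GLM, Laplace GLMM."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from darkcut import models, simulate
from darkcut.models import (
    base_model_spec,
    build_design,
    climate_model_specs,
    fit_logistic,
    fit_mixed_logistic,
    run_model_suite,
)
from darkcut.records import crude_odds_ratio


def _binary_frame(n=400, seed=0, beta=0.9, intercept=-1.0):
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    p = 1 / (1 + np.exp(-(intercept + beta * x)))
    y = (rng.random(n) < p).astype(float)
    return y, pd.DataFrame({"intercept": 1.0, "x": x})


class TestBuildDesign:
    def test_base_design_shape_and_order(self, small_herd):
        recs, _ = small_herd
        y, X, groups, nd = build_design(recs, base_model_spec())
        assert X.columns[0] == "intercept"
        assert "dof_per_10d" in X.columns
        # feedlot E is aliased with abattoir under the supply structure
        assert "feedlot[E]" not in X.columns
        assert "feedlot[D]" in X.columns
        assert groups == {} and nd == 0

    def test_dof_scaled_per_10_days(self, small_herd):
        recs, _ = small_herd
        y, X, _, _ = build_design(recs, base_model_spec())
        i = recs.dropna(subset=["dof"]).index
        assert X["dof_per_10d"].to_numpy() == pytest.approx(
            recs.loc[i, "dof"].to_numpy() / 10.0
        )

    def test_missing_exposure_rows_dropped_with_count(self, small_herd):
        recs, _ = small_herd
        recs = recs.copy()
        rng = np.random.default_rng(0)
        recs["rain_total_7"] = np.nan
        keep = recs.sample(300, random_state=0).index
        recs.loc[keep, "rain_total_7"] = rng.exponential(5.0, 300)
        for col in ("sr_mean", "ws_mean", "rh_mean", "ta_mean"):
            recs[col] = rng.normal(10.0, 2.0, len(recs))
        spec = [s for s in climate_model_specs()
                if s.key == ("climate1", "mean")][0]
        y, X, groups, nd = build_design(recs, spec)
        assert nd == len(recs) - 300
        assert set(groups) == {"feedlot", "kill_date"}

    def test_single_level_factor_named_in_error(self, small_herd):
        recs, _ = small_herd
        recs = recs.copy()
        recs["hgp"] = "yes"
        with pytest.raises(ValueError, match="hgp"):
            build_design(recs, base_model_spec())

    def test_aliased_column_named_in_error(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "dc": rng.random(100) < 0.3,
            "a": rng.normal(size=100),
        })
        df["b"] = 2.0 * df["a"]  # exact collinearity
        spec = models.ModelSpec(
            name="x", continuous={"a": ("a", 1.0), "b": ("b", 1.0)}
        )
        with pytest.raises(ValueError, match="rank deficient"):
            build_design(df, spec)


class TestLogistic:
    def test_single_binary_covariate_matches_crude_or(self):
        y, X = _binary_frame(seed=3)
        fit = fit_logistic(y, X)
        x = X["x"].to_numpy()
        a = ((y == 1) & (x == 1)).sum()
        b = ((y == 0) & (x == 1)).sum()
        c = ((y == 1) & (x == 0)).sum()
        d = ((y == 0) & (x == 0)).sum()
        or_, _ = crude_odds_ratio(a, b, c, d)
        assert fit.odds_ratio("x") == pytest.approx(or_, abs=1e-6)

    def test_intercept_only_closed_form(self):
        y = np.r_[np.ones(30), np.zeros(70)]
        X = pd.DataFrame({"intercept": np.ones(100)})
        fit = fit_logistic(y, X)
        assert fit.terms.loc["intercept", "estimate"] == pytest.approx(
            np.log(0.3 / 0.7), abs=1e-8
        )

    def test_likelihood_ascent_over_null_model(self):
        y, X = _binary_frame(seed=4)
        full = fit_logistic(y, X)
        null = fit_logistic(y, X[["intercept"]])
        assert full.loglik >= null.loglik

    def test_covariate_scaling_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=500)
        y = (rng.random(500) < 1 / (1 + np.exp(-0.5 * x))).astype(float)
        X1 = pd.DataFrame({"intercept": 1.0, "x": x})
        Xk = pd.DataFrame({"intercept": 1.0, "x": 10.0 * x})
        b1 = fit_logistic(y, X1).terms.loc["x", "estimate"]
        bk = fit_logistic(y, Xk).terms.loc["x", "estimate"]
        assert bk == pytest.approx(b1 / 10.0, abs=1e-6)

    def test_null_generative_or_near_one(self):
        rng = np.random.default_rng(12)
        n = 4000
        x = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.3).astype(float)  # independent of x
        fit = fit_logistic(y, pd.DataFrame({"intercept": 1.0, "x": x}))
        lo, hi = fit.ci("x")
        assert lo < 1.0 < hi

    def test_separation_flagged(self):
        y = np.r_[np.ones(20), np.zeros(20)]
        X = pd.DataFrame({"intercept": 1.0, "x": y.copy()})
        fit = fit_logistic(y, X)
        assert any("separation" in w for w in fit.warnings)


class TestMixedLogistic:
    def _grouped(self, seed, sigma, q=40, m=150, beta=0.8):
        rng = np.random.default_rng(seed)
        n = q * m
        x = rng.normal(size=n)
        codes = np.repeat(np.arange(q), m)
        u = rng.normal(0, sigma, q)
        eta = -1.0 + beta * x + u[codes]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        return y, pd.DataFrame({"intercept": 1.0, "x": x}), codes

    def test_single_group_rejected(self):
        y, X, _ = self._grouped(0, 0.5, q=2, m=20)
        with pytest.raises(ValueError, match="2 levels"):
            fit_mixed_logistic(y, X, {"g": (np.zeros(40, int), ["only"])})

    def test_zero_variance_reduces_to_glm(self):
        y, X, codes = self._grouped(1, 0.0)
        mixed = fit_mixed_logistic(
            y, X, {"g": (codes, list(range(40)))},
            sigma_bounds=(0.0, 1e-9),
        )
        glm = fit_logistic(y, X)
        assert mixed.random_variances["g"] == 0.0
        diff = np.abs(
            mixed.terms["estimate"].to_numpy()
            - glm.terms["estimate"].to_numpy()
        ).max()
        assert diff < 1e-4

    def test_variance_recovered(self):
        y, X, codes = self._grouped(7, 0.5, q=150, m=80)
        fit = fit_mixed_logistic(y, X, {"g": (codes, list(range(150)))})
        # true variance 0.25; ML over 150 groups
        assert fit.random_variances["g"] == pytest.approx(0.25, abs=0.1)
        assert fit.terms.loc["x", "estimate"] == pytest.approx(0.8, abs=0.1)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_agrees_with_lme4_on_crossed_intercepts(self, tmp_path):
        rng = np.random.default_rng(42)
        n = 4000
        x = rng.normal(size=n)
        f = rng.integers(0, 6, n)
        d = rng.integers(0, 60, n)
        uf = rng.normal(0, 0.4, 6)
        vd = rng.normal(0, 0.3, 60)
        eta = -1.2 + 0.7 * x + uf[f] + vd[d]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": x, "f": f, "d": d}).to_csv(
            csv, index=False
        )
        fit = fit_mixed_logistic(
            y, pd.DataFrame({"intercept": 1.0, "x": x}),
            {"f": (f, list(range(6))), "d": (d, list(range(60)))},
        )
        script = (
            "suppressMessages(library(lme4));"
            f"d <- read.csv('{csv}');"
            "m <- glmer(y ~ x + (1|f) + (1|d), data=d, family=binomial);"
            "co <- summary(m)$coefficients;"
            "v <- as.data.frame(VarCorr(m));"
            "cat(co[1,1], co[2,1], co[1,2], co[2,2],"
            "    v$vcov[v$grp=='f'], v$vcov[v$grp=='d'], sep='\\n')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            check=True,
        )
        b0, b1, se0, se1, vf, vd_ = (float(v) for v in out.stdout.split())
        assert fit.terms.loc["intercept", "estimate"] == pytest.approx(
            b0, abs=5e-3
        )
        assert fit.terms.loc["x", "estimate"] == pytest.approx(b1, abs=5e-3)
        assert fit.terms.loc["intercept", "se"] == pytest.approx(se0, rel=0.05)
        assert fit.terms.loc["x", "se"] == pytest.approx(se1, rel=0.05)
        assert fit.random_variances["f"] == pytest.approx(vf, abs=0.01)
        assert fit.random_variances["d"] == pytest.approx(vd_, abs=0.01)


class TestSuite:
    def test_thirteen_fits_reported(self):
        conf = simulate.HerdSimConfig(seed=21).scaled(2500)
        recs, _, _ = simulate.simulate_dataset(conf, with_weather=True)
        res = run_model_suite(recs)
        assert len(res) == 13
        ok = [k for k, v in res.items() if not isinstance(v, str)]
        assert ("base", "") in ok
        assert len(ok) == 13

    def test_no_exposures_yields_base_plus_skips(self, small_herd):
        recs, _ = small_herd
        res = run_model_suite(recs)
        assert len(res) == 13
        assert not isinstance(res[("base", "")], str)
        skips = [v for v in res.values() if isinstance(v, str)]
        assert len(skips) == 12

    def test_or_table_columns_match_variant(self):
        conf = simulate.HerdSimConfig(seed=22).scaled(2000)
        recs, _, _ = simulate.simulate_dataset(conf, with_weather=True)
        spec = [s for s in climate_model_specs()
                if s.key == ("climate3", "hli86")][0]
        res = run_model_suite(recs, [spec])
        fit = res[("climate3", "hli86")]
        assert "hours_hli_ge86_per_day" in fit.terms.index
        assert "rain_total_7" in fit.terms.index
        assert "ta_mean" not in fit.terms.index
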