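import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from pathvol.mixed_models import (fit_lmm, fit_logistic_mixed,
                                  fit_overlap_models, fit_volume_method_season,
                                  fit_volume_npositions, fit_volume_vswim,
                                  r2_nakagawa, rank_models)


def simulate_lmm_table(rng, n_fish=8, n_days=120, beta=(2.0, 0.5),
                       sd_fish=0.5, sd_resid=0.8):
    rows = []
    for i in range(n_fish):
        b = rng.normal(0, sd_fish)
        x = rng.uniform(-1, 1, n_days)
        y = beta[0] + beta[1] * x + b + rng.normal(0, sd_resid, n_days)
        for xi, yi in zip(x, y):
            rows.append({"fish_id": f"f{i}", "x": xi, "y": yi})
    return pd.DataFrame(rows)


class TestR2Nakagawa:
    def test_equal_components_closed_form(self):
        assert r2_nakagawa(1.0, 1.0, 1.0) == pytest.approx((1 / 3, 2 / 3))

    def test_no_fixed_effects(self):
        m, c = r2_nakagawa(0.0, 1.0, 1.0)
        assert m == 0.0 and c == pytest.approx(0.5)

    def test_zero_random_variance_collapses(self):
        m, c = r2_nakagawa(1.0, 0.0, 1.0)
        assert m == c

    def test_zero_total_variance_errors(self):
        with pytest.raises(ValueError):
            r2_nakagawa(0.0, 0.0, 0.0)


class TestFitLmm:
    def test_recovers_slope_and_variances(self):
        rng = np.random.default_rng(21)
        df = simulate_lmm_table(rng)
        res = fit_lmm(df, "y ~ x", "fish_id")
        assert res.params["x"] == pytest.approx(0.5, abs=3 * res.bse["x"])
        assert res.var_resid == pytest.approx(0.64, rel=0.2)
        assert res.fit_method == "ML"

    def test_single_group_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [0, 1, 2],
                           "fish_id": ["f1"] * 3})
        with pytest.raises(ValueError, match="groups"):
            fit_lmm(df, "y ~ x", "fish_id")

    def test_refit_reproduces_aic(self):
        rng = np.random.default_rng(4)
        df = simulate_lmm_table(rng, n_fish=5, n_days=40)
        a = fit_lmm(df, "y ~ x", "fish_id").aic
        b = fit_lmm(df, "y ~ x", "fish_id").aic
        assert a == pytest.approx(b, abs=1e-6)

    def test_r2_ordering(self):
        rng = np.random.default_rng(8)
        df = simulate_lmm_table(rng)
        res = fit_lmm(df, "y ~ x", "fish_id")
        assert 0 <= res.r2_marginal <= res.r2_conditional <= 1


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not on PATH")
class TestAgainstLme4:
    def test_ml_loglik_matches_lme4(self, tmp_path):
        """Independent oracle: the same ML LMM fitted by R lme4."""
        rng = np.random.default_rng(17)
        df = simulate_lmm_table(rng, n_fish=6, n_days=50)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""\
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(y ~ x + (1 | fish_id), data = d, REML = FALSE)
            cat(sprintf("%.6f %.6f %.6f", logLik(m), AIC(m), fixef(m)[2]))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        llf_r, aic_r, slope_r = map(float, out.stdout.split())
        res = fit_lmm(df, "y ~ x", "fish_id")
        assert res.loglik == pytest.approx(llf_r, abs=1e-3)
        assert res.aic == pytest.approx(aic_r, abs=1e-2)
        assert res.params["x"] == pytest.approx(slope_r, abs=1e-4)


class TestVolumeModels:
    def test_quadratic_generator_recovered(self):
        rng = np.random.default_rng(12)
        beta0, beta1, beta2 = 10.184, 0.013, -3e-05
        rows = []
        for i in range(9):
            b = rng.normal(0, 0.5)
            n_pos = rng.integers(10, 401, 200)
            mu = beta0 + beta1 * n_pos + beta2 * n_pos ** 2 + b
            y = mu + rng.normal(0, 1.5, 200)
            rows += [{"fish_id": f"f{i}", "n_positions": int(n), "log_volume": yi}
                     for n, yi in zip(n_pos, y)]
        df = pd.DataFrame(rows)
        results = fit_volume_npositions(df)
        best = results[0]
        assert best.label == "n_positions + n_positions^2"
        assert best.delta_aic == 0.0
        assert best.params["n_positions"] == pytest.approx(
            beta1, abs=3 * best.bse["n_positions"])
        assert best.params["n_positions_sq"] == pytest.approx(
            beta2, abs=3 * best.bse["n_positions_sq"])

    def test_null_generator_keeps_intercept_competitive(self):
        rng = np.random.default_rng(31)
        rows = []
        for i in range(9):
            b = rng.normal(0, 0.5)
            n_pos = rng.integers(10, 401, 150)
            y = 10.0 + b + rng.normal(0, 1.5, 150)
            rows += [{"fish_id": f"f{i}", "n_positions": int(n), "log_volume": yi}
                     for n, yi in zip(n_pos, y)]
        results = fit_volume_npositions(pd.DataFrame(rows))
        null = next(r for r in results if r.label == "intercept_only")
        assert null.delta_aic <= 4.0  # within ~2 AIC per extra parameter

    def test_intercept_only_marginal_r2_zero(self):
        rng = np.random.default_rng(32)
        df = simulate_lmm_table(rng, n_fish=5, n_days=30)
        res = fit_lmm(df, "y ~ 1", "fish_id")
        assert res.r2_marginal == 0.0

    def test_vswim_no_signal_favors_null(self):
        rng = np.random.default_rng(33)
        rows = []
        for i in range(6):
            b = rng.normal(0, 0.3)
            for day in range(30):
                base = 10 + b + rng.normal(0, 0.5)
                for q in ("Q50", "Q75", "Q95", "Q100"):
                    for mode in ("pooled", "fish_season"):
                        rows.append({"fish_id": f"f{i}",
                                     "vswim_quantile": q, "vswim_mode": mode,
                                     "log_volume": base})
        results = fit_volume_vswim(pd.DataFrame(rows))
        null = next(r for r in results if r.label == "intercept_only")
        full = next(r for r in results if r.label != "intercept_only")
        assert null.delta_aic <= 2 * 4  # within the parameter-count penalty
        slopes = [v for k, v in full.params.items() if k != "Intercept"]
        assert np.allclose(slopes, 0.0, atol=1e-6)

    def test_vswim_shift_recovered(self):
        rng = np.random.default_rng(34)
        rows = []
        for i in range(6):
            b = rng.normal(0, 0.3)
            for day in range(40):
                for q in ("Q50", "Q75", "Q95", "Q100"):
                    for mode in ("pooled", "fish_season"):
                        y = 10 + b + (0.5 if q == "Q100" else 0.0) \
                            + rng.normal(0, 0.4)
                        rows.append({"fish_id": f"f{i}",
                                     "vswim_quantile": q, "vswim_mode": mode,
                                     "log_volume": y})
        results = fit_volume_vswim(pd.DataFrame(rows))
        full = next(r for r in results if r.label != "intercept_only")
        term = "C(vswim_quantile)[T.Q50]"  # Q100 is the reference level
        assert full.params[term] == pytest.approx(-0.5,
                                                  abs=3 * full.bse[term])

    def test_method_effect_beats_season_only(self):
        rng = np.random.default_rng(35)
        rows = []
        effects = {"ppv": 1.0, "kud2d": 0.5, "kud3d": 0.0}
        for i in range(6):
            b = rng.normal(0, 0.3)
            for day in range(40):
                season = ("winter", "spring")[day % 2]
                for method, eff in effects.items():
                    rows.append({"fish_id": f"f{i}", "method": method,
                                 "season": season,
                                 "log_volume": 10 + eff + b
                                 + rng.normal(0, 0.5)})
        results = fit_volume_method_season(pd.DataFrame(rows))
        by_label = {r.label: r for r in results}
        assert by_label["method"].aic < by_label["season"].aic
        assert results[0].delta_aic == 0.0


class TestLogisticMixed:
    def test_matches_plain_logit_without_group_effect(self):
        """sigma -> 0 limit: GH-quadrature ML equals ordinary logistic ML."""
        import statsmodels.api as sm
        rng = np.random.default_rng(40)
        n = 1200
        x = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 1.2 * x)))
        y = rng.uniform(size=n) < p
        df = pd.DataFrame({"y": y.astype(int), "x": x,
                           "g": rng.integers(0, 30, n)})
        res = fit_logistic_mixed(df, "y ~ x", "g")
        plain = sm.Logit(df["y"], sm.add_constant(df["x"])).fit(disp=False)
        assert res.params["x"] == pytest.approx(plain.params["x"], abs=0.05)
        assert res.params["Intercept"] == pytest.approx(plain.params["const"],
                                                        abs=0.05)
        # GH marginal likelihood can only match or beat plain ML
        assert res.loglik >= plain.llf - 0.5

    def test_seasonal_contrast_sign(self):
        rng = np.random.default_rng(41)
        rows = []
        for pair in range(30):
            b = rng.normal(0, 0.5)
            for day in range(40):
                season = "spring" if day < 20 else "winter"
                logit = {"spring": -0.27, "winter": -1.49}[season] + b
                rows.append({"pair": f"p{pair}", "season": season,
                             "present": int(rng.uniform()
                                            < 1 / (1 + np.exp(-logit)))})
        res = fit_logistic_mixed(pd.DataFrame(rows),
                                 "present ~ C(season)", "pair")
        assert res.params["C(season)[T.winter]"] < 0

    def test_all_present_takes_penalized_path(self):
        df = pd.DataFrame({
            "present": [1] * 60,
            "overlap_m3": [100.0] * 60,
            "season": ["spring", "winter"] * 30,
            "method": ["ppv"] * 60,
            "fish_a": ["f1"] * 60,
            "fish_b": [f"f{i % 5 + 2}" for i in range(60)],
        })
        out = fit_overlap_models(df)
        fitted = out["presence"]
        full = next(r for r in fitted if r.label != "intercept_only")
        null = next(r for r in fitted if r.label == "intercept_only")
        assert null.penalized or full.penalized
        p_hat = 1 / (1 + np.exp(-null.params["Intercept"]))
        assert p_hat > 0.9

    def test_magnitude_model_excludes_absent_records(self):
        rng = np.random.default_rng(43)
        rows = []
        for pair in range(12):
            for day in range(20):
                present = rng.uniform() < 0.5
                rows.append({
                    "fish_a": "a", "fish_b": f"b{pair}",
                    "season": ("spring", "winter")[day % 2],
                    "method": ("ppv", "kud3d")[(day // 2) % 2],
                    "present": int(present),
                    "overlap_m3": float(rng.lognormal(8, 1)) if present else 0.0,
                })
        df = pd.DataFrame(rows)
        out = fit_overlap_models(df)
        assert out["magnitude"][0].n_obs == int(df["present"].sum())


class TestRankModels:
    def test_best_model_has_zero_delta(self):
        rng = np.random.default_rng(50)
        df = simulate_lmm_table(rng, n_fish=5, n_days=30)
        results = rank_models([fit_lmm(df, "y ~ 1", "fish_id", "null"),
                               fit_lmm(df, "y ~ x", "fish_id", "x")])
        assert results[0].delta_aic == 0.0
        assert all(r.delta_aic >= 0 for r in results)
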