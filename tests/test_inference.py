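"""Model fitting, AICc selection, and reporting."""

import subprocess
import textwrap
import warnings

import numpy as np
import pandas as pd
import pytest

from codactivity import (
    ModelSpec,
    fit_model,
    residual_diagnostics,
    select_aicc,
    summarize_result,
)
from codactivity.glmm import MixedFitResult, aicc, fit_weighted_lmm
from codactivity.inference import build_design


def make_lm_table(n, sex_eff=0.0, length_eff=0.0, sd=0.3, seed=0):
    r = np.random.default_rng(seed)
    sex = np.array(["F", "M"])[r.permutation(np.arange(n)) % 2]
    length = r.normal(60, 8, n)
    y = 1.0 + sex_eff * (sex == "M") + length_eff * length + r.normal(0, sd, n)
    return pd.DataFrame(
        {"sex": sex, "length_cm": length, "mean_activity": y, "weight": np.ones(n)}
    )


def make_glmm_table(
    n_fish=40, interaction=0.5, tau=0.15, shape=30.0, seed=0, response="mean_activity"
):
    r = np.random.default_rng(seed)
    sex = np.repeat(np.array(["F", "M"])[np.arange(n_fish) % 2], 2)
    fish = np.repeat([f"f{i}" for i in range(n_fish)], 2)
    deep = np.tile([0.0, 1.0], n_fish)
    b = np.repeat(r.normal(0, np.sqrt(tau), n_fish), 2)
    eta = -0.8 + 0.05 * (sex == "M") - 0.4 * deep + interaction * (sex == "M") * deep + b
    mu = np.exp(eta)
    y = r.gamma(shape, mu / shape)
    return pd.DataFrame(
        {
            "fish_id": fish,
            "sex": sex,
            "depth_category": np.where(deep == 1, "deep", "shallow"),
            response: y,
            "length_cm": r.normal(60, 8, 2 * n_fish),
            "weight": np.full(2 * n_fish, 7.0),
            "year": 2021,
        }
    )


class TestDesign:
    def test_reference_levels_and_names(self):
        t = pd.DataFrame(
            {
                "sex": ["F", "M"],
                "length_cm": [60.0, 50.0],
                "depth_category": ["shallow", "deep"],
            }
        )
        X, names = build_design(
            t, ("sex", "length", "depth_category", "sex:depth_category")
        )
        assert names[0] == "(Intercept)"
        assert "Sex [M]" in names and "Depth Cat [>20m]" in names
        # female/shallow row is all-reference: intercept only
        assert X[0].tolist() == [1.0, 0.0, 60.0, 0.0, 0.0]


class TestGaussianModels:
    def test_lm_recovers_sex_effect_at_study_size(self):
        # a net-pen-sized dataset (16 fish) with a strong male effect
        table = make_lm_table(16, sex_eff=1.11, sd=0.3, seed=5)
        res = fit_model(
            ModelSpec("mean_activity", "gaussian_lm", ("sex",), weights=None), table
        )
        coef = res.coefficients.set_index("term")
        est, se = coef.loc["Sex [M]", ["estimate", "se"]]
        assert abs(est - 1.11) < 3 * se
        assert coef.loc["Sex [M]", "p"] < 0.001

    def test_equal_weights_match_unweighted(self):
        table = make_lm_table(30, sex_eff=0.5, seed=1)
        spec_w = ModelSpec("mean_activity", "gaussian_lm", ("sex", "length"))
        spec_u = ModelSpec("mean_activity", "gaussian_lm", ("sex", "length"), weights=None)
        a = fit_model(spec_w, table).coefficients["estimate"].to_numpy()
        b = fit_model(spec_u, table).coefficients["estimate"].to_numpy()
        assert a == pytest.approx(b)

    def test_weighted_lmm_matches_lme4(self, tmp_path):
        r = np.random.default_rng(2)
        n_g, per = 6, 20
        g = np.repeat(np.arange(n_g), per)
        x = r.normal(size=n_g * per)
        w = r.uniform(1, 5, n_g * per)
        y = 1.0 + 0.8 * x + r.normal(0, 0.5, n_g)[g] + r.normal(0, np.sqrt(1 / w))
        df = pd.DataFrame({"y": y, "x": x, "g": g, "w": w})
        csv = tmp_path / "lmm.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv('{csv}')
            m <- lmer(y ~ x + (1|g), data=d, weights=w, REML=FALSE)
            cat(fixef(m), as.numeric(logLik(m)), sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        b0, b1, ll = (float(v) for v in out.stdout.strip().splitlines()[-3:])
        fit = fit_weighted_lmm(y, np.column_stack([np.ones_like(x), x]), g, w)
        assert fit.beta == pytest.approx([b0, b1], abs=1e-4)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)


class TestGlmm:
    def test_gamma_glmm_recovers_interaction(self):
        table = make_glmm_table(n_fish=60, interaction=0.5, seed=3)
        spec = ModelSpec(
            "mean_activity",
            "gamma_log_glmm",
            ("sex", "depth_category", "sex:depth_category"),
            ("fish_id",),
        )
        res = fit_model(spec, table)
        coef = res.coefficients.set_index("term")
        est = coef.loc["Sex [M] × Depth Cat [>20m]", "estimate"]
        se = coef.loc["Sex [M] × Depth Cat [>20m]", "se"]
        assert abs(est - 0.5) < 3 * se
        assert res.random_variances["tau00_fish"] > 0

    def test_gamma_glmm_matches_glmmtmb(self, tmp_path):
        # many observations per fish: the Laplace approximation used by the
        # R reference is then accurate and both fits target the same optimum
        r = np.random.default_rng(7)
        n_fish, n_rep = 30, 10
        sex = np.repeat(np.array(["F", "M"])[np.arange(n_fish) % 2], n_rep)
        fish = np.repeat([f"f{i}" for i in range(n_fish)], n_rep)
        deep = (np.arange(n_fish * n_rep) % 2).astype(float)
        b = np.repeat(r.normal(0, 0.3, n_fish), n_rep)
        eta = -0.8 - 0.4 * deep + 0.6 * (sex == "M") * deep + b
        y = r.gamma(30.0, np.exp(eta) / 30.0)
        table = pd.DataFrame(
            {
                "fish_id": fish,
                "sex": sex,
                "depth_category": np.where(deep == 1, "deep", "shallow"),
                "mean_activity": y,
                "length_cm": 60.0,
                "weight": 1.0,
            }
        )
        csv = tmp_path / "glmm.csv"
        table.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(glmmTMB))
            d <- read.csv('{csv}')
            d$deep <- as.integer(d$depth_category == 'deep')
            d$male <- as.integer(d$sex == 'M')
            m <- glmmTMB(mean_activity ~ male*deep + (1|fish_id),
                         family=Gamma(link='log'), data=d)
            co <- summary(m)$coefficients$cond
            cat(co[,1], co[,2], sep='\\n')
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        vals = [float(v) for v in out.stdout.strip().splitlines()[-8:]]
        r_beta, r_se = np.array(vals[:4]), np.array(vals[4:])
        spec = ModelSpec(
            "mean_activity",
            "gamma_log_glmm",
            ("sex", "depth_category", "sex:depth_category"),
            ("fish_id",),
            weights=None,
        )
        res = fit_model(spec, table)
        assert res.coefficients["estimate"].to_numpy() == pytest.approx(r_beta, abs=0.01)
        assert res.coefficients["se"].to_numpy() == pytest.approx(r_se, rel=0.05)

    def test_beta_glmm_recovers_interaction_sign(self):
        r = np.random.default_rng(11)
        n_fish = 50
        sex = np.repeat(np.array(["F", "M"])[np.arange(n_fish) % 2], 2)
        fish = np.repeat([f"f{i}" for i in range(n_fish)], 2)
        deep = np.tile([0.0, 1.0], n_fish)
        b = np.repeat(r.normal(0, 0.3, n_fish), 2)
        eta = -2.0 - 1.0 * deep + 0.8 * (sex == "M") * deep + b
        mu = 1 / (1 + np.exp(-eta))
        y = r.beta(mu * 40, (1 - mu) * 40)
        table = pd.DataFrame(
            {
                "fish_id": fish,
                "sex": sex,
                "depth_category": np.where(deep == 1, "deep", "shallow"),
                "p_hv_transformed": y,
                "length_cm": 60.0,
                "weight": 7.0,
            }
        )
        spec = ModelSpec(
            "p_hv_transformed",
            "beta_logit_glmm",
            ("sex", "depth_category", "sex:depth_category"),
            ("fish_id",),
        )
        res = fit_model(spec, table)
        coef = res.coefficients.set_index("term")
        inter = coef.loc["Sex [M] × Depth Cat [>20m]"]
        assert inter["estimate"] > 0
        assert inter["p"] < 0.05

    def test_gamma_zero_shift_note(self):
        table = make_glmm_table(n_fish=20, seed=9)
        table.loc[0, "mean_activity"] = 0.0
        spec = ModelSpec(
            "mean_activity", "gamma_log_glmm", ("sex",), ("fish_id",)
        )
        with pytest.warns(UserWarning, match="shifted"):
            res = fit_model(spec, table)
        assert any("shifted" in n for n in res.notes)


class TestAicc:
    def test_formula_small_sample(self):
        # AICc = AIC + 2k(k+1)/(n-k-1)
        assert aicc(-10.0, 3, 20) == pytest.approx(26.0 + 24 / 16)

    def test_reduces_to_aic_for_large_n(self):
        assert aicc(-10.0, 3, 10**6) == pytest.approx(26.0, abs=1e-4)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestSelection:
    def test_single_candidate_retained_trivially(self):
        table = make_lm_table(20, seed=4)
        sel = select_aicc(
            ModelSpec("mean_activity", "gaussian_lm", (), weights=None), table
        )
        assert sel.retained == ()
        assert len(sel.model_table) == 1

    def test_strong_single_covariate_retained(self):
        hits = 0
        for s in range(20):
            table = make_lm_table(8, sex_eff=2.0, seed=300 + s)
            sel = select_aicc(
                ModelSpec(
                    "mean_activity", "gaussian_lm", ("sex", "length", "sex:length")
                ),
                table,
            )
            hits += sel.retained == ("sex",)
        assert hits >= 16

    def test_pure_noise_usually_empty(self):
        empties = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(20):
                table = make_lm_table(6, seed=600 + s)
                sel = select_aicc(
                    ModelSpec(
                        "mean_activity", "gaussian_lm", ("sex", "length", "sex:length")
                    ),
                    table,
                )
                empties += sel.retained == ()
        assert empties >= 13

    def test_hierarchy_always_respected(self):
        table = make_glmm_table(n_fish=30, interaction=1.0, seed=13)
        spec = ModelSpec(
            "mean_activity",
            "gamma_log_glmm",
            ("sex", "depth_category", "sex:depth_category"),
            ("fish_id",),
        )
        sel = select_aicc(spec, table)
        if "sex:depth_category" in sel.retained:
            assert "sex" in sel.retained and "depth_category" in sel.retained


class TestReporting:
    def test_icc_closed_form(self):
        fit = MixedFitResult(
            family="gamma_log_glmm",
            beta=np.zeros(1),
            se=np.ones(1),
            names=["(Intercept)"],
            loglik=0.0,
            n_obs=10,
            k_params=3,
            tau_fish=1.0,
            resid_var=3.0,
        )
        assert fit.icc == pytest.approx(0.25)

    def test_summary_deterministic_and_annotated(self):
        table = make_lm_table(16, sex_eff=1.0, seed=8)
        spec = ModelSpec("mean_activity", "gaussian_lm", ("sex",))
        a = summarize_result(fit_model(spec, table))
        b = summarize_result(fit_model(spec, table))
        assert a == b
        assert "female" in a and "<20 m" in a
        assert "Sex [M]" in a

    def test_residual_diagnostics(self, tmp_path):
        table = make_lm_table(40, sex_eff=0.6, seed=2)
        res = fit_model(ModelSpec("mean_activity", "gaussian_lm", ("sex",)), table)
        path = tmp_path / "resid.png"
        d = residual_diagnostics(res, plot_path=str(path))
        assert set(d) >= {"skewness", "heteroscedasticity_index", "n"}
        assert abs(d["skewness"]) < 2.0
        assert path.exists()


class TestValidation:
    def test_interaction_without_mains_rejected(self):
        with pytest.raises(ValueError, match="requires"):
            ModelSpec("mean_activity", "gaussian_lm", ("sex:length",))

    def test_beta_family_requires_transformed_response(self):
        with pytest.raises(ValueError, match="transformed"):
            ModelSpec("mean_activity", "beta_logit_glmm", ("sex",), ("fish_id",))

    def test_single_level_categorical_rejected(self):
        table = make_lm_table(10, seed=3)
        table["sex"] = "F"
        with pytest.raises(ValueError, match="levels"):
            fit_model(ModelSpec("mean_activity", "gaussian_lm", ("sex",)), table)
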