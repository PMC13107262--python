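"""Model fitting and all-subsets AICc selection on per-fish aggregates.

The model set mirrors the analysis plan of the telemetry study:

* net-pen / Osen: weighted linear model of mean activity on sex, length
  and their interaction;
* Bakkasund general model: the same fixed effects with a year random
  intercept (weighted Gaussian LMM);
* depth-dependent spawning models: gamma GLMM (log link) of mean
  activity, and beta GLMM (logit link) of the squeezed high-activity
  proportion, on sex, depth category and their interaction, with a fish
  random intercept (plus year where multiple years are pooled).

All categorical effects use treatment contrasts with female and the
shallow (< 20 m) stratum as reference levels, so the intercept is the
female/shallow value.  Selection enumerates every hierarchically valid
fixed-effect subset, ranks by AICc from ML fits, and retains the union
of terms appearing in any model within 2 AICc units of the best.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .glmm import aicc, fit_glmm, fit_weighted_lmm

__all__ = [
    "ModelSpec",
    "ModelResult",
    "SelectionResult",
    "build_design",
    "fit_model",
    "select_aicc",
    "summarize_result",
    "residual_diagnostics",
]

FIXED_TERMS = ("sex", "length", "depth_category", "sex:length", "sex:depth_category")

_TERM_LABELS = {
    "sex": "Sex [M]",
    "length": "Length",
    "depth_category": "Depth Cat [>20m]",
    "sex:length": "Sex [M] × Length",
    "sex:depth_category": "Sex [M] × Depth Cat [>20m]",
}

REFERENCE_NOTE = "treatment contrasts; intercept = female, <20 m (shallow)"


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model description.

    ``response`` is a column of the aggregate table (``mean_activity``
    or ``p_hv_transformed``); ``family`` one of ``gaussian_lm``,
    ``gaussian_lmm``, ``gamma_log_glmm``, ``beta_logit_glmm``;
    ``fixed`` a subset of sex, length, depth_category and the sex
    interactions (interactions require their main effects); ``random``
    a subset of {year, fish_id}; ``weights`` ``"log_n"`` or None.
    """

    response: str
    family: str
    fixed: tuple[str, ...]
    random: tuple[str, ...] = ()
    weights: str | None = "log_n"

    def __post_init__(self) -> None:
        for t in self.fixed:
            if t not in FIXED_TERMS:
                raise ValueError(f"unknown fixed term: {t}")
            if ":" in t:
                a, b = t.split(":")
                if a not in self.fixed or b not in self.fixed:
                    raise ValueError(f"interaction {t} requires both main effects")
        if self.family == "beta_logit_glmm" and self.response != "p_hv_transformed":
            raise ValueError("beta family requires the transformed proportion response")
        for r in self.random:
            if r not in ("year", "fish_id"):
                raise ValueError(f"unknown random term: {r}")


@dataclass
class ModelResult:
    """Fitted model, rendered around the paper-style summary table."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p
    loglik: float
    aicc: float
    n_obs: int
    k_params: int
    random_variances: dict = field(default_factory=dict)
    icc: float | None = None
    r2_marginal: float | None = None
    r2_conditional: float | None = None
    fitted: np.ndarray | None = None
    residuals: np.ndarray | None = None
    converged: bool = True
    singular: bool = False
    reference: str = REFERENCE_NOTE
    notes: list[str] = field(default_factory=list)


def build_design(table: pd.DataFrame, fixed: tuple[str, ...]):
    """Treatment-contrast design matrix (reference: female, shallow)."""
    n = len(table)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    base = {}
    if "sex" in fixed:
        base["sex"] = (table["sex"].to_numpy() == "M").astype(float)
    if "length" in fixed:
        base["length"] = table["length_cm"].to_numpy(dtype=float)
    if "depth_category" in fixed:
        base["depth_category"] = (
            table["depth_category"].to_numpy() == "deep"
        ).astype(float)
    for t in ("sex", "length", "depth_category"):
        if t in fixed:
            cols.append(base[t])
            names.append(_TERM_LABELS[t])
    for t in ("sex:length", "sex:depth_category"):
        if t in fixed:
            a, b = t.split(":")
            cols.append(base[a] * base[b])
            names.append(_TERM_LABELS[t])
    return np.column_stack(cols), names


def _check_table(spec: ModelSpec, table: pd.DataFrame) -> None:
    needed = {spec.response}
    if "sex" in spec.fixed:
        needed.add("sex")
    if "length" in spec.fixed:
        needed.add("length_cm")
    if "depth_category" in spec.fixed:
        needed.add("depth_category")
    if spec.weights == "log_n":
        needed.add("weight")
    missing = needed - set(table.columns)
    if missing:
        raise ValueError(f"model table lacks columns: {sorted(missing)}")
    for t in ("sex", "depth_category"):
        if t in spec.fixed and table[t].nunique() < 2:
            raise ValueError(f"categorical {t} needs >= 2 levels in the data")


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> ModelResult:
    """Weighted maximum-likelihood fit of one model spec.

    Mixed models are fitted by ML (not REML) so log-likelihoods are
    comparable across fixed-effect subsets; coefficients are on the link
    scale (identity / log / logit).  A gamma response containing zeros
    (possible in quiet feeding-season aggregates) is shifted up by half
    the smallest positive value, with a note.
    """
    _check_table(spec, table)
    y = table[spec.response].to_numpy(dtype=float)
    X, names = build_design(table, spec.fixed)
    w = (
        table["weight"].to_numpy(dtype=float)
        if spec.weights == "log_n"
        else np.ones(len(table))
    )
    notes = []
    if spec.family == "gamma_log_glmm" and np.any(y <= 0):
        pos = y[y > 0]
        if pos.size == 0:
            raise ValueError("gamma response has no positive values")
        shift = 0.5 * pos.min()
        y = y + shift
        notes.append(f"zero responses shifted by {shift:.3g} for the gamma family")
        warnings.warn(notes[-1], stacklevel=2)

    if spec.family == "gaussian_lm":
        res = sm.WLS(y, X, weights=w).fit()
        k = X.shape[1] + 1
        coef = pd.DataFrame(
            {
                "term": names,
                "estimate": res.params,
                "se": res.bse,
                "ci_low": res.conf_int()[:, 0],
                "ci_high": res.conf_int()[:, 1],
                "p": res.pvalues,
            }
        )
        fitted = np.asarray(res.fittedvalues)
        return ModelResult(
            spec=spec,
            coefficients=coef,
            loglik=float(res.llf),
            aicc=aicc(float(res.llf), k, len(y)),
            n_obs=len(y),
            k_params=k,
            r2_marginal=float(res.rsquared),
            r2_conditional=float(res.rsquared_adj),
            fitted=fitted,
            residuals=y - fitted,
            notes=notes,
        )

    if spec.family == "gaussian_lmm":
        if "year" not in spec.random:
            raise ValueError("gaussian_lmm requires a year random effect")
        fit = fit_weighted_lmm(y, X, table["year"].to_numpy(), w, names=names)
        rand = {"sigma2": fit.resid_var, "tau00_year": fit.tau_year}
    elif spec.family in ("gamma_log_glmm", "beta_logit_glmm"):
        if "fish_id" not in spec.random:
            raise ValueError(f"{spec.family} requires a fish_id random effect")
        year = (
            table["year"].to_numpy() if "year" in spec.random else None
        )
        fit = fit_glmm(
            y,
            X,
            table["fish_id"].to_numpy(),
            spec.family,
            weights=w,
            year_groups=year,
            names=names,
        )
        rand = {"sigma2": fit.resid_var, "tau00_fish": fit.tau_fish}
        if fit.tau_year is not None:
            rand["tau00_year"] = fit.tau_year
        if fit.dispersion is not None:
            rand["dispersion"] = fit.dispersion
    else:
        raise ValueError(f"unknown family: {spec.family}")

    ci = fit.conf_int()
    coef = pd.DataFrame(
        {
            "term": fit.names,
            "estimate": fit.beta,
            "se": fit.se,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "p": fit.p_values,
        }
    )
    r2m = r2c = None
    if fit.resid_var is not None:
        var_fix = float(np.var(X @ fit.beta))
        denom = var_fix + fit.tau_total + fit.resid_var
        if denom > 0:
            r2m = var_fix / denom
            r2c = (var_fix + fit.tau_total) / denom
    fitted = fit.fitted
    return ModelResult(
        spec=spec,
        coefficients=coef,
        loglik=fit.loglik,
        aicc=aicc(fit.loglik, fit.k_params, fit.n_obs),
        n_obs=fit.n_obs,
        k_params=fit.k_params,
        random_variances=rand,
        icc=fit.icc,
        r2_marginal=r2m,
        r2_conditional=r2c,
        fitted=fitted,
        residuals=None if fitted is None else y - fitted,
        converged=fit.converged,
        singular=fit.singular,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# all-subsets AICc selection


def _hierarchical_subsets(terms: tuple[str, ...]):
    """Every subset of ``terms`` in which interactions have their mains."""
    out = []
    for r in range(len(terms) + 1):
        for combo in itertools.combinations(terms, r):
            ok = all(
                a in combo and b in combo
                for t in combo
                if ":" in t
                for a, b in [t.split(":")]
            )
            if ok:
                out.append(tuple(combo))
    return out


@dataclass
class SelectionResult:
    """Outcome of all-subsets AICc selection with the 2-unit rule."""

    model_table: pd.DataFrame  # terms, k, loglik, AICc, delta
    retained: tuple[str, ...]
    best: tuple[str, ...]
    final: ModelResult


def select_aicc(spec: ModelSpec, table: pd.DataFrame) -> SelectionResult:
    """Dredge-style all-subsets selection with the 2-AICc retention rule.

    Enumerates every hierarchically valid subset of ``spec.fixed``
    (random effects always kept), fits each by ML, ranks by AICc, and
    retains the union of fixed terms appearing in the best model or any
    model within 2 AICc units of it; the final model refits that union.
    Candidates whose parameter count leaves AICc undefined (n <= k + 1)
    are skipped with a warning.
    """
    rows = []
    for terms in _hierarchical_subsets(spec.fixed):
        sub = replace(spec, fixed=terms)
        try:
            res = fit_model(sub, table)
        except ValueError as err:
            warnings.warn(f"candidate {terms or '(intercept)'} skipped: {err}", stacklevel=2)
            continue
        rows.append(
            {
                "terms": terms,
                "k": res.k_params,
                "loglik": res.loglik,
                "aicc": res.aicc,
            }
        )
    if not rows:
        raise ValueError("no fittable candidate models")
    mt = pd.DataFrame(rows).sort_values("aicc", kind="stable", ignore_index=True)
    mt["delta"] = mt["aicc"] - mt["aicc"].iloc[0]
    near = mt[mt["delta"] <= 2.0]
    retained = tuple(t for t in spec.fixed if any(t in terms for terms in near["terms"]))
    final = fit_model(replace(spec, fixed=retained), table)
    return SelectionResult(
        model_table=mt,
        retained=retained,
        best=tuple(mt["terms"].iloc[0]),
        final=final,
    )


# ---------------------------------------------------------------------------
# reporting


def summarize_result(result: ModelResult) -> str:
    """Human-readable summary table (fixed effects, then random part).

    Deterministic formatting: the same fitted result always renders to
    byte-identical text.
    """
    lines = []
    lines.append(f"Response: {result.spec.response}   Family: {result.spec.family}")
    lines.append(f"Reference levels: {result.reference}")
    lines.append("")
    lines.append(f"{'Predictors':<28}{'Estimates':>10}{'CI':>22}{'p':>10}")
    for row in result.coefficients.itertuples():
        ci = f"{row.ci_low:.2f} – {row.ci_high:.2f}"
        p = "<0.001" if row.p < 0.001 else f"{row.p:.3f}"
        lines.append(f"{row.term:<28}{row.estimate:>10.2f}{ci:>22}{p:>10}")
    if result.random_variances:
        lines.append("Random effects")
        for k, v in result.random_variances.items():
            if v is not None:
                lines.append(f"  {k:<26}{v:>10.2f}")
        if result.icc is not None:
            lines.append(f"  {'ICC':<26}{result.icc:>10.2f}")
    lines.append(f"Observations{result.n_obs:>26}")
    if result.r2_marginal is not None:
        r2c = "NA" if result.r2_conditional is None else f"{result.r2_conditional:.3f}"
        lines.append(f"Marginal R2 / Conditional R2   {result.r2_marginal:.3f}/{r2c}")
    lines.append(f"AICc{result.aicc:>34.2f}")
    if result.singular:
        lines.append("note: a random-effect variance was pinned at 0")
    for n in result.notes:
        lines.append(f"note: {n}")
    return "\n".join(lines) + "\n"


def residual_diagnostics(result: ModelResult, plot_path: str | None = None) -> dict:
    """Numeric stand-ins for visual residual inspection.

    Returns residual skewness and a heteroscedasticity index (Spearman
    correlation between |residual| and fitted value); optionally writes
    a residual-vs-fitted scatter with a histogram panel.
    """
    if result.residuals is None or result.fitted is None:
        raise ValueError("result carries no residuals")
    r = np.asarray(result.residuals, dtype=float)
    f = np.asarray(result.fitted, dtype=float)
    skew = float(stats.skew(r)) if len(r) > 2 else np.nan
    if len(r) > 2 and np.ptp(f) > 0:
        het = float(stats.spearmanr(np.abs(r), f).statistic)
    else:
        het = np.nan
    out = {"skewness": skew, "heteroscedasticity_index": het, "n": int(len(r))}
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(8, 3.2))
        axes[0].scatter(f, r, s=12, alpha=0.7)
        axes[0].axhline(0.0, color="grey", lw=0.8)
        axes[0].set_xlabel("fitted")
        axes[0].set_ylabel("residual")
        axes[1].hist(r, bins=20, color="steelblue")
        axes[1].set_xlabel("residual")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
        out["plot"] = plot_path
    return out
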