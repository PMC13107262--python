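"""Right-censored (Tobit) modelling and imputation of tag-ceiling values.

Accelerometer tags transmit the ceiling value whenever the smoothed
acceleration saturates their dynamic range, so transmitted activity data
are right-censored at a known threshold (3.43 or 4.9 m/s^2 depending on
tag model).  This module fits a censored-Gaussian linear model by maximum
likelihood (density terms for interior values, upper-tail survival terms
for ceiling values) and replaces each ceiling value by a random draw from
the fitted upper tail (truncated normal above the ceiling at that
observation's linear predictor).  Imputation is stochastic single-draw,
preserving the variance that downstream weighted means rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "CensoredModelFit",
    "fit_tobit",
    "fit_tobit_groups",
    "impute_censored",
    "impute_pairs",
]


@dataclass
class CensoredModelFit:
    """Fitted right-censored Gaussian model.

    ``coefficients`` are on the response (m/s^2) scale; ``sigma`` is the
    residual s.d.; ``ceiling`` the censoring threshold(s).  ``vcov``
    covers (coefficients, log sigma).
    """

    coefficients: np.ndarray
    sigma: float
    ceiling: float | np.ndarray
    n_total: int
    n_censored: int
    converged: bool
    loglik: float
    vcov: np.ndarray | None = None
    names: list[str] = field(default_factory=list)
    group_index: pd.Index | None = None  # set by the grouped fitter

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_censored > self.n_total:
            raise ValueError("n_censored cannot exceed n_total")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coefficients

    def se(self) -> np.ndarray | None:
        if self.vcov is None:
            return None
        return np.sqrt(np.diag(self.vcov))


def _censored_indicator(y: np.ndarray, ceiling) -> np.ndarray:
    """Ceiling values are censored; interior values are not.  Tags report
    exactly the ceiling on saturation, so equality marks censoring."""
    return np.asarray(y, dtype=float) >= np.asarray(ceiling, dtype=float)


def _nll_and_grad(params, y, X, cens, unc):
    k = X.shape[1]
    beta = params[:k]
    sigma = np.exp(params[k])
    mu = X @ beta
    z_unc = (y[unc] - mu[unc]) / sigma
    ll = np.sum(stats.norm.logpdf(z_unc) - np.log(sigma))
    # survival terms for ceiling observations
    z_c = (y[cens] - mu[cens]) / sigma
    ll += np.sum(stats.norm.logsf(z_c))
    # gradient
    g_beta = np.zeros(k)
    g_logsig = 0.0
    if unc.any():
        g_beta += X[unc].T @ (z_unc / sigma)
        g_logsig += np.sum(z_unc**2 - 1.0)
    if cens.any():
        mills = np.exp(stats.norm.logpdf(z_c) - stats.norm.logsf(z_c))
        g_beta += X[cens].T @ (mills / sigma)
        g_logsig += np.sum(mills * z_c)
    return -ll, -np.concatenate([g_beta, [g_logsig]])


def fit_tobit(
    y,
    X,
    ceiling,
    names: list[str] | None = None,
    compute_vcov: bool = True,
) -> CensoredModelFit:
    """Maximum-likelihood fit of a right-censored Gaussian linear model.

    Parameters
    ----------
    y
        Response values; observations equal to (or above) ``ceiling``
        are treated as censored at it.
    X
        Design matrix (n x k), including the intercept column.
    ceiling
        Scalar censoring threshold, or one per observation (mixed tag
        models).

    With no censored observations the likelihood reduces to the Gaussian
    and the estimates equal ordinary least squares.  All-censored input
    raises (the likelihood is unbounded).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    cens = _censored_indicator(y, ceiling)
    unc = ~cens
    if not unc.any():
        raise ValueError("all observations censored: Tobit likelihood unbounded")
    # OLS start values
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma0 = float(np.std(resid, ddof=min(X.shape[1], len(y) - 1))) or 1.0
    x0 = np.concatenate([beta0, [np.log(sigma0)]])
    res = optimize.minimize(
        _nll_and_grad,
        x0,
        args=(y, X, cens, unc),
        jac=True,
        method="BFGS",
        options={"maxiter": 500, "gtol": 1e-7},
    )
    k = X.shape[1]
    beta = res.x[:k]
    sigma = float(np.exp(res.x[k]))
    # BFGS can stop on precision loss with the optimum in hand; accept a
    # stationary point whose gradient is negligible at this sample size
    grad_ok = bool(np.max(np.abs(res.jac)) < 1e-3 * max(1.0, len(y) ** 0.5))
    success = bool(res.success or grad_ok)
    vcov = None
    if compute_vcov:
        try:
            H = approx_hess1(res.x, lambda p: _nll_and_grad(p, y, X, cens, unc)[0])
            vcov_full = np.linalg.inv(H)
            # delta method: report vcov on (beta, sigma) scale
            J = np.eye(k + 1)
            J[k, k] = sigma
            vcov = J @ vcov_full @ J.T
        except np.linalg.LinAlgError:  # pragma: no cover - degenerate designs
            vcov = None
    if not success:
        warnings.warn("censored-Gaussian fit did not converge", stacklevel=2)
    return CensoredModelFit(
        coefficients=beta,
        sigma=sigma,
        ceiling=ceiling,
        n_total=len(y),
        n_censored=int(cens.sum()),
        converged=success,
        loglik=float(-res.fun),
        vcov=vcov,
        names=names or [f"x{i}" for i in range(k)],
    )


def fit_tobit_groups(
    y,
    groups,
    ceiling,
    max_iter: int = 500,
    tol: float = 1e-9,
) -> CensoredModelFit:
    """Censored-Gaussian fit with one mean per group and common sigma.

    EM algorithm specialised to a categorical (group-mean) design: the
    E-step replaces each censored observation by the conditional mean
    and variance of the upper tail of the current Gaussian; the M-step
    updates group means and the common residual s.d. in closed form.
    Maximises the same likelihood as :func:`fit_tobit` with a one-hot
    design, but in O(n) per iteration, which is what the per-fish
    imputation step inside the pipeline needs.
    """
    y = np.asarray(y, dtype=float)
    C = np.broadcast_to(np.asarray(ceiling, dtype=float), y.shape)
    codes, index = pd.factorize(np.asarray(groups))
    index = pd.Index(index)
    n_groups = len(index)
    cens = _censored_indicator(y, C)
    unc = ~cens
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    if not unc.any():
        raise ValueError("all observations censored: Tobit likelihood unbounded")
    if (np.bincount(codes[cens], minlength=n_groups) == counts).any():
        raise ValueError("some group is fully censored: its mean is unbounded")
    # start from uncensored means (global fallback for safety)
    sums = np.bincount(codes[unc], weights=y[unc], minlength=n_groups)
    n_unc = np.bincount(codes[unc], minlength=n_groups).astype(float)
    mu = np.where(n_unc > 0, sums / np.maximum(n_unc, 1), y[unc].mean())
    sigma = float(np.std(y[unc])) or 1.0
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        zc = (C[cens] - mu[codes[cens]]) / sigma
        mills = np.exp(stats.norm.logpdf(zc) - stats.norm.logsf(zc))
        m = mu[codes[cens]] + sigma * mills  # E[y* | y* > C]
        v = sigma**2 * (1.0 + zc * mills - mills**2)  # Var[y* | y* > C]
        ey = y.copy()
        ey[cens] = m
        mu = np.bincount(codes, weights=ey, minlength=n_groups) / counts
        resid2 = (ey - mu[codes]) ** 2
        extra = np.zeros_like(y)
        extra[cens] = v
        sigma = float(np.sqrt(np.sum(resid2 + extra) / len(y)))
        ll = _group_loglik(y, codes, mu, sigma, cens, C)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return CensoredModelFit(
        coefficients=mu,
        sigma=sigma,
        ceiling=ceiling,
        n_total=len(y),
        n_censored=int(cens.sum()),
        converged=converged,
        loglik=float(ll),
        names=[str(g) for g in index],
        group_index=index,
    )


def _group_loglik(y, codes, mu, sigma, cens, C):
    unc = ~cens
    z = (y[unc] - mu[codes[unc]]) / sigma
    ll = np.sum(stats.norm.logpdf(z) - np.log(sigma))
    zc = (C[cens] - mu[codes[cens]]) / sigma
    return ll + np.sum(stats.norm.logsf(zc))


def impute_censored(
    values,
    fit: CensoredModelFit,
    rng: np.random.Generator,
    linear_predictor=None,
) -> np.ndarray:
    """Replace ceiling values by draws from the fitted upper tail.

    Each censored observation is replaced by a truncated-normal draw
    above its ceiling, centred at its linear predictor with the fitted
    residual s.d.; uncensored values pass through untouched, so all
    imputed values are >= the ceiling and imputation never decreases a
    value.  Refuses to impute from a non-converged fit.
    """
    if not fit.converged:
        raise ValueError("refusing to impute from a non-converged censored fit")
    y = np.asarray(values, dtype=float).copy()
    C = np.broadcast_to(np.asarray(fit.ceiling, dtype=float), y.shape)
    cens = _censored_indicator(y, C)
    if not cens.any():
        return y
    if linear_predictor is None:
        raise ValueError("need the per-observation linear predictor to impute")
    mu = np.broadcast_to(np.asarray(linear_predictor, dtype=float), y.shape)
    a = (C[cens] - mu[cens]) / fit.sigma
    draws = stats.truncnorm.rvs(
        a, np.inf, loc=mu[cens], scale=fit.sigma, random_state=rng
    )
    y[cens] = draws
    return y


def impute_pairs(
    pairs: pd.DataFrame,
    fish_meta: pd.DataFrame,
    rng: np.random.Generator,
    value_col: str = "accel",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Impute ceiling-censored activity values in a paired table.

    Fits one censored-Gaussian model per (ground, year) dataset with
    fish identity as the categorical covariate (each fish its own mean,
    common residual s.d.), then replaces ceiling values by stochastic
    upper-tail draws.  The ceiling is the tag spec's, per fish, so mixed
    tag models within a dataset are handled.

    Returns the table with an added ``accel_imputed`` column and a
    per-fish imputation report (``n_censored``, fitted ``sigma``).
    """
    from .tags import TAG_SPECS

    if len(pairs) == 0:
        out = pairs.copy()
        out["accel_imputed"] = pd.Series(dtype=float)
        return out, pd.DataFrame(columns=["fish_id", "n", "n_censored", "sigma"])
    meta = fish_meta.set_index("fish_id")
    ceil_lut = {f: TAG_SPECS[t].accel_max for f, t in meta["tag_spec_name"].items()}
    out = pairs.copy()
    out["accel_imputed"] = out[value_col].astype(float)
    report_rows = []
    ground = out["fish_id"].map(meta["ground"])
    year = out["fish_id"].map(meta["year"])
    for (g, yr), grp in out.groupby([ground, year], sort=False, observed=True):
        y = grp[value_col].to_numpy(dtype=float)
        fish = grp["fish_id"].to_numpy()
        C = np.array([ceil_lut[f] for f in fish])
        cens = _censored_indicator(y, C)
        if not cens.any():
            sigma = np.nan
        else:
            try:
                fit = fit_tobit_groups(y, fish, C)
            except ValueError as err:
                warnings.warn(
                    f"imputation skipped for dataset ({g}, {yr}): {err}",
                    stacklevel=2,
                )
                sigma = np.nan
                fit = None
            if fit is not None:
                codes = fit.group_index.get_indexer(fish)
                lp = fit.coefficients[codes]
                out.loc[grp.index, "accel_imputed"] = impute_censored(
                    y, fit, rng, linear_predictor=lp
                )
                sigma = fit.sigma
        per_fish = pd.DataFrame(
            {
                "fish_id": fish,
                "cens": cens,
            }
        ).groupby("fish_id")["cens"]
        for fid, s in per_fish.agg(["size", "sum"]).iterrows():
            report_rows.append(
                {
                    "fish_id": fid,
                    "n": int(s["size"]),
                    "n_censored": int(s["sum"]),
                    "sigma": sigma,
                }
            )
    report = pd.DataFrame(report_rows, columns=["fish_id", "n", "n_censored", "sigma"])
    return out, report
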