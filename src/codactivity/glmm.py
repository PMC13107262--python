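"""Weighted mixed-effects estimation.

Two fitters back the inference layer:

* :func:`fit_weighted_lmm` — Gaussian linear mixed model with one random
  intercept and precision weights, by direct maximisation of the
  marginal likelihood (the random intercept integrates out in closed
  form; Woodbury identities keep each group O(group size)).

* :func:`fit_glmm` — gamma(log link) or beta(logit link) regression with
  a fish-level random intercept, optionally nested inside a year-level
  intercept, by adaptive-free Gauss-Hermite quadrature of the marginal
  likelihood.  Weights enter as precision (prior) weights in the GLM
  sense: they scale the gamma shape / beta precision per observation, so
  a constant rescaling of all weights is absorbed by the dispersion
  parameter.

Both return :class:`MixedFitResult` with ML log-likelihood (comparable
across fixed-effect subsets for information-criterion selection) and
Wald inference for the fixed effects from the numerically evaluated
Hessian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = ["MixedFitResult", "fit_weighted_lmm", "fit_glmm", "aicc"]

_SINGULAR_TAU = 1e-5  # variance below this is reported as pinned at 0


@dataclass
class MixedFitResult:
    """Fitted mixed (or plain) model on the link scale."""

    family: str
    beta: np.ndarray
    se: np.ndarray
    names: list[str]
    loglik: float
    n_obs: int
    k_params: int
    tau_fish: float | None = None
    tau_year: float | None = None
    resid_var: float | None = None  # observation-level variance (latent scale)
    dispersion: float | None = None  # gamma shape / beta precision
    fitted: np.ndarray | None = None  # response-scale fitted values (fixed part)
    converged: bool = True
    singular: bool = False
    messages: list[str] = field(default_factory=list)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.beta / self.se

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        q = stats.norm.ppf(0.5 + level / 2.0)
        return np.column_stack([self.beta - q * self.se, self.beta + q * self.se])

    @property
    def tau_total(self) -> float:
        return (self.tau_fish or 0.0) + (self.tau_year or 0.0)

    @property
    def icc(self) -> float | None:
        """Intraclass correlation tau00 / (tau00 + sigma^2)."""
        if self.resid_var is None or self.tau_total == 0.0:
            return None
        return self.tau_total / (self.tau_total + self.resid_var)


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike criterion.

    AICc = AIC + 2k(k+1)/(n-k-1); undefined (raises) when n <= k + 1.
    """
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


# ---------------------------------------------------------------------------
# Gaussian LMM, one random intercept, precision weights


def _lmm_profile(theta, y, X, codes, n_groups, w):
    """Profile out beta at (log sigma2, log tau); return (nll, beta, XtSiX)."""
    sigma2 = np.exp(theta[0])
    tau = np.exp(theta[1])
    d = sigma2 / w  # diagonal of the conditional covariance
    inv_d = 1.0 / d
    # per-group Woodbury: Sigma^-1 = D^-1 - tau/(1+tau*s) * (D^-1 1)(D^-1 1)^T
    s = np.bincount(codes, weights=inv_d, minlength=n_groups)
    shrink = tau / (1.0 + tau * s)
    u_x = np.zeros((n_groups, X.shape[1]))
    for j in range(X.shape[1]):
        u_x[:, j] = np.bincount(codes, weights=inv_d * X[:, j], minlength=n_groups)
    u_y = np.bincount(codes, weights=inv_d * y, minlength=n_groups)
    XtSiX = X.T @ (X * inv_d[:, None]) - u_x.T @ (u_x * shrink[:, None])
    XtSiy = X.T @ (y * inv_d) - u_x.T @ (u_y * shrink)
    beta = np.linalg.solve(XtSiX, XtSiy)
    r = y - X @ beta
    u_r = np.bincount(codes, weights=inv_d * r, minlength=n_groups)
    quad = float(r @ (r * inv_d) - (u_r * shrink) @ u_r)
    logdet = float(np.sum(np.log(d)) + np.sum(np.log1p(tau * s)))
    nll = 0.5 * (len(y) * np.log(2.0 * np.pi) + logdet + quad)
    return nll, beta, XtSiX


def fit_weighted_lmm(
    y,
    X,
    groups,
    weights=None,
    names: list[str] | None = None,
) -> MixedFitResult:
    """ML fit of y = X beta + b_group + e with precision weights.

    ``Var(e_i) = sigma^2 / w_i``; ``b ~ N(0, tau)``.  The Wald covariance
    of beta is the GLS covariance at the ML variance estimates.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    codes, index = pd.factorize(np.asarray(groups))
    n_groups = len(index)
    # start values from the weighted residual variance
    beta0, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], y * np.sqrt(w), rcond=None)
    r0 = y - X @ beta0
    v0 = float(np.average(r0**2, weights=w)) or 1.0
    x0 = np.array([np.log(v0), np.log(max(v0 / 4.0, 1e-4))])
    obj = lambda th: _lmm_profile(th, y, X, codes, n_groups, w)[0]
    res = optimize.minimize(
        obj,
        x0,
        method="L-BFGS-B",
        bounds=[(-15.0, 15.0), (-15.0, 15.0)],
    )
    nll, beta, XtSiX = _lmm_profile(res.x, y, X, codes, n_groups, w)
    sigma2 = float(np.exp(res.x[0]))
    tau = float(np.exp(res.x[1]))
    singular = tau < _SINGULAR_TAU
    if singular:
        warnings.warn("random-intercept variance pinned at 0 (singular fit)", stacklevel=2)
        tau = 0.0
    vcov = np.linalg.inv(XtSiX)
    fitted = X @ beta
    return MixedFitResult(
        family="gaussian_lmm",
        beta=beta,
        se=np.sqrt(np.diag(vcov)),
        names=names or [f"x{i}" for i in range(X.shape[1])],
        loglik=float(-nll),
        n_obs=len(y),
        k_params=X.shape[1] + 2,
        tau_fish=None,
        tau_year=tau,
        resid_var=sigma2,
        fitted=fitted,
        converged=bool(res.success),
        singular=singular,
    )


# ---------------------------------------------------------------------------
# gamma / beta GLMM via Gauss-Hermite quadrature


def _cond_loglik(family, y, eta, disp_w):
    """Elementwise conditional log density at linear predictor eta."""
    if family == "gamma_log_glmm":
        mu = np.exp(eta)
        k = disp_w
        return k * np.log(k / mu) + (k - 1.0) * np.log(y) - k * y / mu - special.gammaln(k)
    mu = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)
    a = mu * disp_w
    b = (1.0 - mu) * disp_w
    return (
        special.gammaln(disp_w)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )


def _cond_d1d2(family, y, eta, disp_w):
    """First/second derivatives of the conditional log density w.r.t. eta."""
    if family == "gamma_log_glmm":
        r = y * np.exp(-eta)
        return disp_w * (r - 1.0), -disp_w * r
    mu = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)
    v = mu * (1.0 - mu)
    a = mu * disp_w
    b = (1.0 - mu) * disp_w
    resid = np.log(y) - np.log1p(-y) - special.digamma(a) + special.digamma(b)
    d1 = disp_w * v * resid
    d2 = (
        disp_w * v * (1.0 - 2.0 * mu) * resid
        - (disp_w * v) ** 2 * (special.polygamma(1, a) + special.polygamma(1, b))
    )
    return d1, np.minimum(d2, -1e-10)


def _fish_modes(family, y, eta0, disp_w, fish_codes, n_fish, tau, b_start):
    """Per-fish conditional modes and curvatures of the random intercept.

    Damped Newton on h_i(b) = sum_j log f(y_ij | eta_ij + b) - b^2/(2 tau);
    h is concave for both families, so this converges in a few steps.
    """
    b = b_start.copy()
    H = np.full(n_fish, -1.0 / tau)
    for _ in range(60):
        eta = eta0 + b[fish_codes]
        d1, d2 = _cond_d1d2(family, y, eta, disp_w)
        g = np.bincount(fish_codes, weights=d1, minlength=n_fish) - b / tau
        H = np.bincount(fish_codes, weights=d2, minlength=n_fish) - 1.0 / tau
        step = np.clip(g / H, -1.0, 1.0)
        b = b - step
        if np.max(np.abs(g)) < 1e-9:
            break
    return b, -H  # mode, conditional precision (positive)


def _agq_fish_loglik(
    family, y, eta0, disp_w, fish_codes, n_fish, tau, gh_x, gh_logw, state
):
    """Adaptive Gauss-Hermite marginal log-likelihood per fish.

    Nodes are centred at each fish's conditional mode and scaled by its
    conditional s.d., so the quadrature stays accurate when the data
    dominate the prior (many detections per fish)."""
    b_hat, prec = _fish_modes(
        family, y, eta0, disp_w, fish_codes, n_fish, tau, state["b"]
    )
    state["b"] = b_hat
    sig = 1.0 / np.sqrt(prec)
    M = gh_x.size
    contrib = np.empty((M, n_fish))
    for m in range(M):
        bm = b_hat + np.sqrt(2.0) * sig * gh_x[m]
        eta = eta0 + bm[fish_codes]
        ll_obs = _cond_loglik(family, y, eta, disp_w)
        ll_fish = np.bincount(fish_codes, weights=ll_obs, minlength=n_fish)
        ll_fish += -0.5 * bm * bm / tau - 0.5 * np.log(2.0 * np.pi * tau)
        contrib[m] = ll_fish + gh_logw[m] + gh_x[m] ** 2 + 0.5 * np.log(2.0) + np.log(sig)
    return special.logsumexp(contrib, axis=0)


def _glmm_nll(
    params, y, X, w, fish_codes, n_fish, family, gh_x, gh_logw,
    year_of_fish=None, n_years=0, state=None,
):
    k = X.shape[1]
    beta = params[:k]
    tau_f = np.exp(params[k])
    disp = np.exp(params[-1])
    disp_w = disp * w
    eta0 = X @ beta
    if state is None:
        state = {"b": np.zeros(n_fish)}

    def fish_ll(shift_obs):
        return _agq_fish_loglik(
            family, y, eta0 + shift_obs, disp_w, fish_codes, n_fish, tau_f,
            gh_x, gh_logw, state,
        )

    if year_of_fish is None:
        return -float(np.sum(fish_ll(0.0)))

    # nested year level: adaptive outer quadrature; the outer mode is
    # located by Newton with finite differences of the inner integral
    tau_y = np.exp(params[k + 1])
    u = state.setdefault("u", np.zeros(n_years))
    h = 1e-4

    def year_obj(u_vec):
        lf = fish_ll(u_vec[year_of_fish[fish_codes]])
        per_year = np.bincount(year_of_fish, weights=lf, minlength=n_years)
        return per_year - 0.5 * u_vec * u_vec / tau_y - 0.5 * np.log(2.0 * np.pi * tau_y)

    for _ in range(25):
        f0 = year_obj(u)
        fp = year_obj(u + h)
        fm = year_obj(u - h)
        g = (fp - fm) / (2 * h)
        H = np.minimum((fp - 2 * f0 + fm) / (h * h), -1.0 / tau_y * 0.01)
        step = np.clip(g / H, -1.0, 1.0)
        u = u - step
        if np.max(np.abs(g)) < 1e-7:
            break
    state["u"] = u
    prec_y = np.maximum(-(year_obj(u + h) - 2 * year_obj(u) + year_obj(u - h)) / (h * h), 1e-8)
    sig_y = 1.0 / np.sqrt(prec_y)
    M = gh_x.size
    contrib = np.empty((M, n_years))
    for m in range(M):
        um = u + np.sqrt(2.0) * sig_y * gh_x[m]
        contrib[m] = (
            year_obj(um) + gh_logw[m] + gh_x[m] ** 2 + 0.5 * np.log(2.0) + np.log(sig_y)
        )
    return -float(np.sum(special.logsumexp(contrib, axis=0)))


def fit_glmm(
    y,
    X,
    fish_groups,
    family: str,
    weights=None,
    year_groups=None,
    names: list[str] | None = None,
    n_nodes: int = 15,
) -> MixedFitResult:
    """ML fit of a gamma(log) or beta(logit) random-intercept model.

    ``fish_groups`` defines the (always present) fish-level intercept;
    ``year_groups``, if given, adds a year-level intercept in which fish
    are nested (each fish belongs to one year).  Weights are precision
    weights: per-observation gamma shape ``k * w`` or beta precision
    ``phi * w``.
    """
    if family not in ("gamma_log_glmm", "beta_logit_glmm"):
        raise ValueError(f"unknown GLMM family: {family}")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    k = X.shape[1]
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    fish_codes, fish_index = pd.factorize(np.asarray(fish_groups))
    n_fish = len(fish_index)
    year_of_fish = None
    n_years = 0
    if year_groups is not None:
        year_arr = np.asarray(year_groups)
        year_codes, year_index = pd.factorize(year_arr)
        n_years = len(year_index)
        # year of each fish (nesting: every fish belongs to one year)
        yf = np.full(n_fish, -1, dtype=int)
        for fc, yc in zip(fish_codes, year_codes):
            if yf[fc] == -1:
                yf[fc] = yc
            elif yf[fc] != yc:
                raise ValueError("fish must be nested in years")
        year_of_fish = yf
    gh_x, gh_w = np.polynomial.hermite.hermgauss(n_nodes)
    gh_logw = np.log(gh_w)

    if family == "gamma_log_glmm":
        if np.any(y <= 0):
            raise ValueError("gamma response must be strictly positive")
        eta_start = np.log(y)
        disp_start = max(
            1.0 / max(np.var(y / np.exp(eta_start.mean())), 1e-3), 0.5
        )
    else:
        if np.any((y <= 0) | (y >= 1)):
            raise ValueError("beta response must lie strictly in (0, 1)")
        eta_start = special.logit(y)
        disp_start = 10.0
    beta0, *_ = np.linalg.lstsq(X * np.sqrt(w)[:, None], eta_start * np.sqrt(w), rcond=None)
    resid = eta_start - X @ beta0
    tau0 = max(float(np.var(resid)) / 2.0, 1e-3)
    x0 = np.concatenate(
        [beta0, [np.log(tau0)]]
        + ([[np.log(tau0 / 4.0)]] if year_of_fish is not None else [])
        + [[np.log(disp_start)]]
    )
    state = {"b": np.zeros(n_fish)}
    args = (
        y, X, w, fish_codes, n_fish, family, gh_x, gh_logw,
        year_of_fish, n_years, state,
    )
    n_var = 1 + (year_of_fish is not None)
    bounds = (
        [(None, None)] * k
        + [(-12.0, 6.0)] * n_var
        + [(-8.0, 12.0)]
    )
    res = optimize.minimize(
        _glmm_nll, x0, args=args, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 400},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"GLMM fit flagged: {res.message}", stacklevel=2)
    beta = res.x[:k]
    tau_f = float(np.exp(res.x[k]))
    tau_y = float(np.exp(res.x[k + 1])) if year_of_fish is not None else None
    disp = float(np.exp(res.x[-1]))
    singular = tau_f < _SINGULAR_TAU or (tau_y is not None and tau_y < _SINGULAR_TAU)
    if tau_f < _SINGULAR_TAU:
        tau_f = 0.0
    if tau_y is not None and tau_y < _SINGULAR_TAU:
        tau_y = 0.0
    if singular:
        warnings.warn("random-intercept variance pinned at 0 (singular fit)", stacklevel=2)
    # Wald covariance from the observed information (fixed effects block)
    se = np.full(k, np.nan)
    try:
        H = approx_hess1(res.x, lambda p: _glmm_nll(p, *args))
        cov = np.linalg.pinv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:k], 0.0, None))
    except (np.linalg.LinAlgError, ValueError):  # pragma: no cover
        converged = False
    # observation-level latent-scale variance for ICC / R2
    if family == "gamma_log_glmm":
        resid_var = float(special.polygamma(1, disp))  # trigamma(shape)
    else:
        mu_hat = special.expit(X @ beta)
        resid_var = float(np.mean(1.0 / ((1.0 + disp) * mu_hat * (1.0 - mu_hat))))
    fitted = (
        np.exp(X @ beta) if family == "gamma_log_glmm" else special.expit(X @ beta)
    )
    return MixedFitResult(
        family=family,
        beta=beta,
        se=se,
        names=names or [f"x{i}" for i in range(k)],
        loglik=float(-res.fun),
        n_obs=len(y),
        k_params=k + n_var + 1,
        tau_fish=tau_f,
        tau_year=tau_y,
        resid_var=resid_var,
        dispersion=disp,
        fitted=fitted,
        converged=converged,
        singular=singular,
    )
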