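"""Maximum-likelihood MIMIC model for uniform-DIF testing.

The model has a single latent factor theta measured by k items, with the
binary grouping covariate x regressed on theta (path gamma) and directly on
one *studied* item (path beta):

    theta = gamma * x + zeta,                 zeta  ~ (0, psi_zeta)
    y_i   = tau_i + lambda_i * theta
            + beta * x * [i == studied] + eps_i,   eps_i ~ (0, psi_i)

A nonzero beta means the studied item's expected score differs between groups
at equal trait levels — uniform DIF.  Item scores are treated as numeric
(1..J) and the model is fitted by normal-theory maximum likelihood on the
joint mean/covariance structure of (items, covariate), with the covariate's
own mean and variance fixed at their sample values (fixed-x convention).

Writing c = gamma * lambda + beta * e_s, the implied moments are

    mu_y    = tau + c * mean(x),
    Sig_yy  = psi_zeta * lambda lambda' + var(x) * c c' + diag(psi),
    Sig_yx  = var(x) * c,

which is positive definite whenever all variances are positive, so the
log-variance search space is unconstrained.  Identification fixes the first
anchor item's loading at 1 and leaves psi_zeta free; the latent intercept is
absorbed into the item intercepts.  Standard errors come from the inverse
expected (Fisher) information at the optimum scaled by N-1, and the DIF test
is the two-sided Wald z = beta / se(beta).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm

from .synthetic_data import Dataset

__all__ = [
    "MimicSpec",
    "MimicFit",
    "implied_moments",
    "fml_discrepancy",
    "fit_mimic",
    "wald_dif_test",
    "fit_indices",
    "model_df",
    "n_free_params",
]

_GRAD_TOL = 1e-6
_MAX_ITER = 500
_HEYWOOD_VAR = 1e-8
_LOG_VAR_BOUNDS = (-23.0, 23.0)  # variances in [1e-10, 1e10] during search


@dataclass(frozen=True)
class MimicSpec:
    """Which item receives the tested direct group path; others are anchors.

    ``extra_direct_items`` lists additional items whose direct group paths are
    freed (estimated but not tested).  Freeing the path of an item known or
    suspected to have DIF keeps it from contaminating the anchor set while a
    different item is under test.
    """

    n_items: int
    studied_item: int
    extra_direct_items: tuple[int, ...] = ()
    identification: str = "first_loading_fixed"
    covariate_treatment: str = "exogenous_fixed"

    def __post_init__(self) -> None:
        if self.n_items < 3:
            raise ValueError("MIMIC needs at least 3 items for identification")
        if not 0 <= self.studied_item < self.n_items:
            raise ValueError("studied_item out of range")
        extras = tuple(self.extra_direct_items)
        if len(set(extras)) != len(extras) or self.studied_item in extras:
            raise ValueError("extra_direct_items must be distinct from each other and the studied item")
        for m in extras:
            if not 0 <= m < self.n_items:
                raise ValueError(f"direct-path item {m} out of range")
        if len(extras) >= self.n_items - 2:
            raise ValueError("at least two anchor items without direct paths are required")
        object.__setattr__(self, "extra_direct_items", extras)
        if self.identification != "first_loading_fixed":
            raise ValueError("only first_loading_fixed identification is supported")
        if self.covariate_treatment != "exogenous_fixed":
            raise ValueError("only exogenous_fixed covariate treatment is supported")

    @property
    def direct_items(self) -> tuple[int, ...]:
        """Items with a direct group path, tested item first."""
        return (self.studied_item, *self.extra_direct_items)

    @property
    def fixed_loading_item(self) -> int:
        """The first anchor item without a direct path; its loading is fixed at 1."""
        return next(i for i in range(self.n_items) if i not in self.direct_items)

    @property
    def free_loading_items(self) -> list[int]:
        return [i for i in range(self.n_items) if i != self.fixed_loading_item]

    @property
    def n_params(self) -> int:
        return n_free_params(self.n_items, len(self.extra_direct_items))

    @property
    def df(self) -> int:
        """Degrees of freedom of the item moment structure conditional on x.

        Modeled moments: k item means, k(k+1)/2 item (co)variances, k item-x
        covariances (x's own mean and variance are fixed at sample values),
        minus the free parameters.
        """
        k = self.n_items
        return (k * (k + 5)) // 2 - self.n_params


def n_free_params(k: int, n_extra_direct: int = 0) -> int:
    """k-1 loadings, k intercepts, k residual variances, gamma, the direct
    path(s), and psi_zeta."""
    return 3 * k + 2 + n_extra_direct


def model_df(k: int) -> int:
    """Degrees of freedom of the single-direct-path model on k items."""
    return (k * (k + 5)) // 2 - n_free_params(k)


def _unpack(params: np.ndarray, spec: MimicSpec):
    """Natural-scale parameter vector -> (lam, tau, psi, gamma, betas, psi_z).

    ``betas`` is aligned with ``spec.direct_items`` (tested item first).
    """
    k = spec.n_items
    if params.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} parameters, got {params.shape}")
    nb = len(spec.direct_items)
    lam = np.ones(k)
    lam[spec.free_loading_items] = params[: k - 1]
    tau = params[k - 1 : 2 * k - 1]
    psi = params[2 * k - 1 : 3 * k - 1]
    gamma = params[3 * k - 1]
    betas = params[3 * k : 3 * k + nb]
    psi_z = params[3 * k + nb]
    return lam, tau, psi, gamma, betas, psi_z


def implied_moments(
    params: np.ndarray,
    spec: MimicSpec,
    covariate_variance: float,
    covariate_mean: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-implied mean vector and covariance matrix of (items, covariate)."""
    params = np.asarray(params, dtype=float)
    lam, tau, psi, gamma, betas, psi_z = _unpack(params, spec)
    k = spec.n_items
    vx, mx = covariate_variance, covariate_mean
    c = gamma * lam
    c[list(spec.direct_items)] += betas
    mu = np.empty(k + 1)
    mu[:k] = tau + c * mx
    mu[k] = mx
    sig = np.empty((k + 1, k + 1))
    sig[:k, :k] = psi_z * np.outer(lam, lam) + vx * np.outer(c, c) + np.diag(psi)
    sig[:k, k] = sig[k, :k] = vx * c
    sig[k, k] = vx
    return mu, sig


def fml_discrepancy(sample_mean, sample_cov, implied_mean, implied_cov) -> float:
    """Normal-theory ML discrepancy between sample and implied moments.

    F = log|Sigma| + tr(S Sigma^-1) - log|S| - p + (m - mu)' Sigma^-1 (m - mu),
    nonnegative and zero exactly when the moments agree.
    """
    m = np.asarray(sample_mean, dtype=float)
    S = np.asarray(sample_cov, dtype=float)
    mu = np.asarray(implied_mean, dtype=float)
    sig = np.asarray(implied_cov, dtype=float)
    p = m.shape[0]
    c, low = cho_factor(sig, lower=True)
    logdet_sig = 2.0 * np.sum(np.log(np.diag(c)))
    sign_s, logdet_s = np.linalg.slogdet(S)
    if sign_s <= 0:
        raise np.linalg.LinAlgError("sample covariance is singular")
    d = m - mu
    tr_term = np.trace(cho_solve((c, low), S))
    mean_term = d @ cho_solve((c, low), d)
    return float(logdet_sig + tr_term - logdet_s - p + mean_term)


@dataclass
class MimicFit:
    """Estimates, tests, and diagnostics from one MIMIC fit."""

    loadings: np.ndarray
    intercepts: np.ndarray
    residual_variances: np.ndarray
    gamma: float
    beta: float
    zeta_variance: float
    se_beta: float
    se_gamma: float
    fml: float
    chi_square: float
    df: int
    n_obs: int
    converged: bool
    heywood: bool
    fit_indices: dict = field(default_factory=dict)
    n_iter: int = 0
    studied_item: int = 0

    @property
    def z(self) -> float:
        return self.beta / self.se_beta

    @property
    def p_value(self) -> float:
        return wald_dif_test(self.beta, self.se_beta)[1]

    def to_dict(self) -> dict:
        return {
            "loadings": self.loadings.tolist(),
            "intercepts": self.intercepts.tolist(),
            "residual_variances": self.residual_variances.tolist(),
            "gamma": self.gamma,
            "beta": self.beta,
            "zeta_variance": self.zeta_variance,
            "se_beta": self.se_beta,
            "se_gamma": self.se_gamma,
            "z": self.z,
            "p_value": self.p_value,
            "fml": self.fml,
            "chi_square": self.chi_square,
            "df": self.df,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "heywood": self.heywood,
            "fit_indices": dict(self.fit_indices),
            "studied_item": self.studied_item,
        }


def _moment_derivatives(params: np.ndarray, spec: MimicSpec, vx: float, mx: float):
    """Per-parameter derivatives (dmu, dSigma) on the natural scale."""
    lam, tau, psi, gamma, betas, psi_z = _unpack(params, spec)
    k = spec.n_items
    c = gamma * lam
    c[list(spec.direct_items)] += betas
    q = spec.n_params
    p = k + 1
    dmu = np.zeros((q, p))
    dsig = np.zeros((q, p, p))
    idx = 0
    for i in spec.free_loading_items:
        e = np.zeros(k)
        e[i] = 1.0
        dyy = psi_z * (np.outer(e, lam) + np.outer(lam, e)) + vx * gamma * (
            np.outer(e, c) + np.outer(c, e)
        )
        dsig[idx, :k, :k] = dyy
        dsig[idx, :k, k] = dsig[idx, k, :k] = vx * gamma * e
        dmu[idx, :k] = gamma * mx * e
        idx += 1
    for i in range(k):  # intercepts
        dmu[idx, i] = 1.0
        idx += 1
    for i in range(k):  # residual variances
        dsig[idx, i, i] = 1.0
        idx += 1
    # gamma
    dsig[idx, :k, :k] = vx * (np.outer(lam, c) + np.outer(c, lam))
    dsig[idx, :k, k] = dsig[idx, k, :k] = vx * lam
    dmu[idx, :k] = mx * lam
    idx += 1
    # direct group-to-item paths
    for m in spec.direct_items:
        e = np.zeros(k)
        e[m] = 1.0
        dsig[idx, :k, :k] = vx * (np.outer(e, c) + np.outer(c, e))
        dsig[idx, :k, k] = dsig[idx, k, :k] = vx * e
        dmu[idx, :k] = mx * e
        idx += 1
    # zeta variance
    dsig[idx, :k, :k] = np.outer(lam, lam)
    return dmu, dsig


def _fml_and_grad(
    params: np.ndarray, spec: MimicSpec, mbar, S, vx: float, mx: float,
    logdet_s: float | None = None,
) -> tuple[float, np.ndarray]:
    """F_ML and its analytic gradient on the natural parameter scale."""
    if logdet_s is None:
        logdet_s = np.linalg.slogdet(S)[1]
    lam, tau, psi, gamma, betas, psi_z = _unpack(params, spec)
    k = spec.n_items
    direct = list(spec.direct_items)
    c = gamma * lam
    c[direct] += betas
    mu = np.empty(k + 1)
    mu[:k] = tau + c * mx
    mu[k] = mx
    sig = np.empty((k + 1, k + 1))
    sig[:k, :k] = psi_z * np.outer(lam, lam) + vx * np.outer(c, c) + np.diag(psi)
    sig[:k, k] = sig[k, :k] = vx * c
    sig[k, k] = vx

    cf, low = cho_factor(sig, lower=True)
    logdet_sig = 2.0 * np.sum(np.log(np.diag(cf)))
    A = cho_solve((cf, low), np.eye(k + 1))
    d = mbar - mu
    Ad = A @ d
    AS = A @ S
    f = logdet_sig + np.trace(AS) + d @ Ad - logdet_s - (k + 1)

    # dF/dSigma = A(Sigma - S - dd')A = A - A S A - (Ad)(Ad)'
    G = A - AS @ A - np.outer(Ad, Ad)
    gy = -2.0 * Ad[:k]  # dF/dmu_y (mu_x is fixed)
    Gyy = G[:k, :k]
    Gyx = G[:k, k]

    dFdc = 2.0 * vx * (Gyy @ c) + 2.0 * vx * Gyx + mx * gy
    nb = len(direct)
    grad = np.empty(spec.n_params)
    glam = 2.0 * psi_z * (Gyy @ lam) + gamma * dFdc
    grad[: k - 1] = glam[spec.free_loading_items]
    grad[k - 1 : 2 * k - 1] = gy
    grad[2 * k - 1 : 3 * k - 1] = np.diag(Gyy)
    grad[3 * k - 1] = dFdc @ lam
    grad[3 * k : 3 * k + nb] = dFdc[direct]
    grad[3 * k + nb] = lam @ Gyy @ lam
    return float(f), grad


def _start_values(spec: MimicSpec, mbar: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Deterministic starting point: unit loadings, sample means as intercepts,
    half the item variances as residual variances, null structural paths."""
    k = spec.n_items
    item_var = np.diag(S)[:k]
    params = np.zeros(spec.n_params)
    params[: k - 1] = 1.0
    params[k - 1 : 2 * k - 1] = mbar[:k]
    params[2 * k - 1 : 3 * k - 1] = 0.5 * item_var
    params[-1] = 0.5 * item_var[0]  # zeta variance; gamma and betas start at 0
    return params


def _to_transformed(params: np.ndarray, k: int) -> np.ndarray:
    t = params.copy()
    t[2 * k - 1 : 3 * k - 1] = np.log(params[2 * k - 1 : 3 * k - 1])
    t[-1] = np.log(params[-1])
    return t


def _from_transformed(t: np.ndarray, k: int) -> np.ndarray:
    params = t.copy()
    params[2 * k - 1 : 3 * k - 1] = np.exp(t[2 * k - 1 : 3 * k - 1])
    params[-1] = np.exp(t[-1])
    return params


def fit_mimic(data: Dataset, spec: MimicSpec) -> MimicFit:
    """Fit the MIMIC model by ML and return estimates, SEs, and diagnostics.

    Responses are scored numerically 1..J.  The discrepancy is minimized by
    L-BFGS-B on a log-variance parameterization from a deterministic start, so
    repeated fits on identical data are identical.  Optimizer failure or an
    improper (Heywood) solution is reported via flags, never raised.
    """
    k = spec.n_items
    if data.n_items != k:
        raise ValueError("dataset and spec disagree on the number of items")
    z = np.column_stack([data.responses.astype(float), data.group.astype(float)])
    N = z.shape[0]
    if N < spec.n_params + 1:
        raise ValueError("too few observations for the number of free parameters")
    mbar = z.mean(axis=0)
    S = np.cov(z, rowvar=False, ddof=1)
    vx, mx = S[k, k], mbar[k]
    if vx <= 0:
        raise ValueError("grouping covariate has zero variance")
    logdet_s = np.linalg.slogdet(S)[1]

    def objective(t: np.ndarray) -> tuple[float, np.ndarray]:
        params = _from_transformed(t, k)
        f, g = _fml_and_grad(params, spec, mbar, S, vx, mx, logdet_s)
        # chain rule for the log-variance coordinates
        g = g.copy()
        g[2 * k - 1 : 3 * k - 1] *= params[2 * k - 1 : 3 * k - 1]
        g[-1] *= params[-1]
        return f, g

    t0 = _to_transformed(_start_values(spec, mbar, S), k)
    lo, hi = _LOG_VAR_BOUNDS
    n_paths = 1 + len(spec.direct_items)  # gamma plus the direct paths
    bounds = (
        [(None, None)] * (2 * k - 1) + [(lo, hi)] * k
        + [(None, None)] * n_paths + [(lo, hi)]
    )
    res = optimize.minimize(
        objective,
        t0,
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": _MAX_ITER, "ftol": 1e-13, "gtol": _GRAD_TOL},
    )
    params = _from_transformed(res.x, k)
    lam, tau, psi, gamma, betas, psi_z = _unpack(params, spec)
    fml, grad = _fml_and_grad(params, spec, mbar, S, vx, mx, logdet_s)
    converged = bool(np.max(np.abs(res.jac)) < 10 * _GRAD_TOL) or bool(res.success)

    mu, sig = implied_moments(params, spec, vx, mx)
    sd = np.sqrt(np.diag(sig))
    corr_ok = np.all(np.abs(sig / np.outer(sd, sd)) <= 1.0 + 1e-10)
    heywood = bool(np.any(psi < _HEYWOOD_VAR) or psi_z < _HEYWOOD_VAR or not corr_ok)

    se = _standard_errors(params, spec, sig, vx, mx, N)
    chi_square = (N - 1) * fml
    df = spec.df
    base_chi, base_df = _baseline_chi_square(mbar, S, N, k)
    indices = fit_indices(chi_square, df, base_chi, base_df, N, S, sig)

    return MimicFit(
        loadings=lam,
        intercepts=tau,
        residual_variances=psi,
        gamma=float(gamma),
        beta=float(betas[0]),
        zeta_variance=float(psi_z),
        se_beta=float(se[3 * k]),
        se_gamma=float(se[3 * k - 1]),
        fml=float(fml),
        chi_square=float(chi_square),
        df=df,
        n_obs=N,
        converged=converged,
        heywood=heywood,
        fit_indices=indices,
        n_iter=int(res.nit),
        studied_item=spec.studied_item,
    )


def _standard_errors(
    params: np.ndarray, spec: MimicSpec, sig: np.ndarray, vx: float, mx: float, N: int
) -> np.ndarray:
    """SEs from the inverse expected information scaled by N-1.

    Per-observation Fisher information of the multivariate-normal model:
    I_ab = 1/2 tr(Sigma^-1 dSig_a Sigma^-1 dSig_b) + dmu_a' Sigma^-1 dmu_b.
    Falls back to a pseudo-inverse when the information matrix is singular.
    """
    k = spec.n_items
    dmu, dsig = _moment_derivatives(params, spec, vx, mx)
    A = np.linalg.inv(sig)
    AD = np.einsum("ij,qjk->qik", A, dsig)
    info = 0.5 * np.einsum("qik,rki->qr", AD, AD) + dmu @ A @ dmu.T
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    var = np.diag(cov) / (N - 1)
    return np.sqrt(np.maximum(var, 0.0))


def _baseline_chi_square(mbar, S, N: int, k: int) -> tuple[float, int]:
    """Independence baseline: free item means/variances, all covariances zero.

    F_baseline has the closed form sum(log S_ii) - log|S| and df = k(k+1)/2.
    """
    sign, logdet_s = np.linalg.slogdet(S)
    f_b = float(np.sum(np.log(np.diag(S))) - logdet_s)
    df_b = (k * (k + 1)) // 2
    return (N - 1) * f_b, df_b


def wald_dif_test(beta: float, se_beta: float) -> tuple[float, float]:
    """Two-sided Wald test of the direct group-to-item path."""
    if not se_beta > 0:
        raise ValueError("se_beta must be positive")
    z = beta / se_beta
    p = 2.0 * norm.sf(abs(z))
    return float(z), float(p)


def fit_indices(
    chi_square: float,
    df: int,
    baseline_chi_square: float,
    baseline_df: int,
    N: int,
    sample_cov,
    implied_cov,
) -> dict:
    """Conventional covariance-structure fit indices.

    RMSEA from the noncentrality estimate max(chi2 - df, 0); CFI/TLI against
    the independence baseline; RMR as the root mean square of the unique
    residual (co)variances; GFI = 1 - tr((Sig^-1 (S-Sig))^2) / tr((Sig^-1 S)^2).
    A saturated model (df = 0) reports RMSEA 0 by convention.
    """
    S = np.asarray(sample_cov, dtype=float)
    sig = np.asarray(implied_cov, dtype=float)
    ncp = max(chi_square - df, 0.0)
    rmsea = float(np.sqrt(ncp / (df * (N - 1)))) if df > 0 else 0.0
    base_ncp = max(baseline_chi_square - baseline_df, 0.0)
    denom = max(base_ncp, ncp)
    cfi = 1.0 if denom == 0 else 1.0 - ncp / denom
    if df > 0 and baseline_df > 0 and baseline_chi_square / baseline_df > 1.0:
        tli = (baseline_chi_square / baseline_df - chi_square / df) / (
            baseline_chi_square / baseline_df - 1.0
        )
    else:
        tli = 1.0
    resid = S - sig
    iu = np.triu_indices_from(resid)
    rmr = float(np.sqrt(np.mean(resid[iu] ** 2)))
    W = np.linalg.solve(sig, resid)
    V = np.linalg.solve(sig, S)
    gfi = float(1.0 - np.trace(W @ W) / np.trace(V @ V))
    return {
        "rmsea": max(rmsea, 0.0),
        "rmr": rmr,
        "tli": float(min(max(tli, 0.0), 1.0)),
        "cfi": float(min(max(cfi, 0.0), 1.0)),
        "gfi": float(min(max(gfi, 0.0), 1.0)),
    }
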