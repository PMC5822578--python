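"""Full-information maximum likelihood estimation for incomplete tables.

Rows are grouped by missingness pattern; each pattern contributes the
multivariate-Gaussian log-density of its observed sub-vector under the
corresponding sub-mean/sub-covariance.  With pattern-level sufficient
statistics (count, mean, scatter) the log-likelihood is

    l = sum_k -n_k/2 [ p_k log 2pi + log|S_k| + tr(S_k^-1 W_k)
                       + (xbar_k - mu_k)' S_k^-1 (xbar_k - mu_k) ]

where W_k is the within-pattern scatter divided by n_k.  Gradients with
respect to the model parameters are assembled by chaining the analytic score
in (mu, Sigma) with a finite-difference Jacobian of the (cheap, data-free)
moment map, which keeps optimization fast for any spec.

Also provides the saturated FIML fit (EM for the unstructured multivariate
normal) and the independence baseline, both needed for chi-square-based fit
indices, and the delta-method standardized solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import ModelSpec, MomentStructure

__all__ = [
    "MissingPatterns",
    "FittedModel",
    "compute_patterns",
    "loglik_moments",
    "fiml_loglik",
    "fit",
    "fit_saturated",
    "fit_baseline",
    "standardize",
]

_SENTINEL = -1e15
LN2PI = np.log(2.0 * np.pi)


@dataclass
class MissingPatterns:
    """Pattern-level sufficient statistics of an incomplete data matrix."""

    masks: list  # boolean arrays over variables (True = observed)
    counts: list
    means: list  # mean of observed sub-vector per pattern
    scatters: list  # scatter/n about the pattern mean (p_k x p_k)
    n_used: int
    n_dropped: int  # rows with every variable missing

    @property
    def n_patterns(self) -> int:
        return len(self.masks)


def compute_patterns(Y: np.ndarray) -> MissingPatterns:
    """Group rows of ``Y`` (NaN = missing) by missingness pattern."""
    Y = np.asarray(Y, dtype=float)
    obs = np.isfinite(Y)
    any_obs = obs.any(axis=1)
    n_dropped = int((~any_obs).sum())
    Y, obs = Y[any_obs], obs[any_obs]
    masks, counts, means, scatters = [], [], [], []
    # encode each row's pattern as bytes for grouping
    keys = np.packbits(obs, axis=1)
    _, inverse = np.unique(keys, axis=0, return_inverse=True)
    for g in range(inverse.max() + 1):
        rows = Y[inverse == g]
        mask = np.isfinite(rows[0])
        sub = rows[:, mask]
        n_k = sub.shape[0]
        xbar = sub.mean(axis=0)
        d = sub - xbar
        masks.append(mask)
        counts.append(n_k)
        means.append(xbar)
        scatters.append(d.T @ d / n_k)
    return MissingPatterns(
        masks=masks,
        counts=counts,
        means=means,
        scatters=scatters,
        n_used=int(any_obs.sum()),
        n_dropped=n_dropped,
    )


def loglik_moments(mu: np.ndarray, Sigma: np.ndarray, patterns: MissingPatterns) -> float:
    """FIML log-likelihood of (mu, Sigma) given pattern statistics."""
    total = 0.0
    for mask, n_k, xbar, W in zip(
        patterns.masks, patterns.counts, patterns.means, patterns.scatters
    ):
        S = Sigma[np.ix_(mask, mask)]
        try:
            c, low = np.linalg.cholesky(S), True
        except np.linalg.LinAlgError:
            return _SENTINEL
        logdet = 2.0 * np.log(np.diag(c)).sum()
        d = xbar - mu[mask]
        Sinv_W = np.linalg.solve(S, W)  # actually S^-1 W; trace below
        z = np.linalg.solve(c, d)
        quad = z @ z
        p_k = mask.sum()
        total += -0.5 * n_k * (p_k * LN2PI + logdet + np.trace(Sinv_W) + quad)
    if not np.isfinite(total):
        return _SENTINEL
    return float(total)


def score_moments(mu: np.ndarray, Sigma: np.ndarray, patterns: MissingPatterns):
    """Analytic score dl/dmu (p,) and dl/dSigma (p, p; symmetric)."""
    p = mu.shape[0]
    dmu = np.zeros(p)
    dSig = np.zeros((p, p))
    for mask, n_k, xbar, W in zip(
        patterns.masks, patterns.counts, patterns.means, patterns.scatters
    ):
        S = Sigma[np.ix_(mask, mask)]
        G = np.linalg.inv(S)
        d = xbar - mu[mask]
        Gd = G @ d
        A = 0.5 * n_k * (G @ (W + np.outer(d, d)) @ G - G)
        dmu[mask] += n_k * Gd
        dSig[np.ix_(mask, mask)] += A
    return dmu, 0.5 * (dSig + dSig.T)


# ---------------------------------------------------------------------- #
# model likelihood and gradient


def fiml_loglik(theta: np.ndarray, patterns: MissingPatterns, spec: ModelSpec) -> float:
    """Log-likelihood of ``spec`` at ``theta``; optimizer-safe on bad points."""
    try:
        mom = spec.implied_moments(theta)
    except (np.linalg.LinAlgError, FloatingPointError, OverflowError):
        return _SENTINEL
    if not (np.all(np.isfinite(mom.mu)) and np.all(np.isfinite(mom.Sigma))):
        return _SENTINEL
    return loglik_moments(mom.mu, mom.Sigma, patterns)


def _moment_jacobian(spec: ModelSpec, theta: np.ndarray, step: float = 1e-6):
    """Finite-difference Jacobians of mu and Sigma w.r.t. theta (data-free)."""
    q = theta.shape[0]
    p = spec.n_observed
    Jmu = np.empty((q, p))
    JSig = np.empty((q, p, p))
    for j in range(q):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        mp, mm = spec.implied_moments(tp), spec.implied_moments(tm)
        Jmu[j] = (mp.mu - mm.mu) / (2 * h)
        JSig[j] = (mp.Sigma - mm.Sigma) / (2 * h)
    return Jmu, JSig


def fiml_gradient(theta: np.ndarray, patterns: MissingPatterns, spec: ModelSpec) -> np.ndarray:
    mom = spec.implied_moments(theta)
    dmu, dSig = score_moments(mom.mu, mom.Sigma, patterns)
    Jmu, JSig = _moment_jacobian(spec, theta)
    return Jmu @ dmu + np.einsum("qij,ij->q", JSig, dSig)


# ---------------------------------------------------------------------- #
# fitted model container


@dataclass
class FittedModel:
    """Estimates, uncertainties and diagnostics for one fitted spec."""

    spec: ModelSpec
    theta: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    se_ok: bool
    n_used: int
    n_dropped: int
    iterations: int
    gradient_norm: float
    message: str = ""
    start_theta: np.ndarray | None = None

    @property
    def param_names(self) -> list:
        return self.spec.parameter_names

    def implied_moments(self) -> MomentStructure:
        return self.spec.implied_moments(self.theta)

    def structural_covariance(self) -> np.ndarray:
        *_, Psi = self.spec.unpack(self.theta)
        return Psi

    def structural_means(self) -> np.ndarray:
        _, _, _, alpha, _ = self.spec.unpack(self.theta)
        return alpha

    def parameter_table(self) -> pd.DataFrame:
        roles = [n.split("[")[0] for n in self.param_names]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.theta / self.se
        p = 2.0 * stats.norm.sf(np.abs(z))
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "role": roles,
                "estimate": self.theta,
                "se": self.se,
                "z": z,
                "p": p,
            }
        )

    def run_record(self) -> dict:
        return {
            "loglik": self.loglik,
            "converged": self.converged,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "iterations": self.iterations,
            "gradient_norm": self.gradient_norm,
            "se_ok": self.se_ok,
        }


# ---------------------------------------------------------------------- #
# starting values


def start_values(spec: ModelSpec, Y: pd.DataFrame) -> np.ndarray:
    """Data-driven admissible starting values.

    Measurement starts come from complete-case moments (marker-based loading
    regressions, half-variance residuals); structural covariances start at
    half the complete-case covariances of marker-level/difference proxies.
    """
    cols = {name: Y[name].to_numpy(dtype=float) for name in spec.observed}

    def nanvar(x):
        v = np.nanvar(x)
        return v if np.isfinite(v) and v > 0 else 1.0

    def nancov(x, y):
        m = np.isfinite(x) & np.isfinite(y)
        if m.sum() < 3:
            return 0.0
        return float(np.cov(x[m], y[m], ddof=0)[0, 1])

    markers = {d: spec.indicators[d][0] for d in spec.domains}
    loadings, intercepts, resid = {}, {}, {}
    phi = {}
    for d in spec.domains:
        mcol = cols[f"{markers[d]}_w2"]
        phi[d] = max(0.7 * nanvar(mcol), 1e-6)
        for ind in spec.indicators[d]:
            x2 = cols[f"{ind}_w2"]
            intercepts[ind] = float(np.nanmean(x2))
            if ind == markers[d]:
                loadings[ind] = 1.0
            else:
                loadings[ind] = nancov(x2, mcol) / phi[d]
            resid[(ind, 2)] = max(0.5 * nanvar(x2), 1e-8)
            resid[(ind, 3)] = max(0.5 * nanvar(cols[f"{ind}_w3"]), 1e-8)

    # structural proxies: biomarker columns and marker level/difference
    k = spec.n_latent
    nd = len(spec.domains)
    bio2, bio3 = cols[spec.observed[0]], cols[spec.observed[1]]
    proxies = [bio2, bio3 - bio2]
    proxies += [cols[f"{markers[d]}_w2"] for d in spec.domains]
    proxies += [cols[f"{markers[d]}_w3"] - cols[f"{markers[d]}_w2"] for d in spec.domains]
    P = np.column_stack(proxies)
    complete = np.all(np.isfinite(P), axis=1)
    if complete.sum() >= k + 2:
        C = np.cov(P[complete].T, ddof=0)
        pm = P[complete].mean(axis=0)
    else:  # fall back to diagonal available-case moments
        C = np.diag([nanvar(x) for x in proxies])
        pm = np.array([np.nan_to_num(np.nanmean(x)) for x in proxies])
    Psi0 = 0.5 * C
    # keep cognitive level variances tied to the loading-regression scale
    for j, d in enumerate(spec.domains):
        Psi0[2 + j, 2 + j] = phi[d]
    w, V = np.linalg.eigh(0.5 * (Psi0 + Psi0.T))
    floor = max(1e-8, 1e-4 * w.max())
    Psi0 = V @ np.diag(np.maximum(w, floor)) @ V.T
    alpha0 = np.zeros(k)
    alpha0[0], alpha0[1] = pm[0], pm[1]
    alpha0[2 + nd :] = pm[2 + nd :]
    return spec.pack(loadings, intercepts, resid, alpha0, Psi0)


# ---------------------------------------------------------------------- #
# fit

# The optimizer works on data rescaled to roughly unit variance (one scale
# factor per *variable*, shared by its two waves, so the fixed unit paths and
# invariance constraints are preserved).  Every free parameter then maps back
# to native units by a constant affine map theta_native = a * theta_scaled + b
# (loadings and moments are linear in the column scales; log-variances and
# log-Cholesky diagonals shift), so estimates, covariance and SEs are
# transformed exactly after convergence.


def _column_scales(spec: ModelSpec, Y: pd.DataFrame) -> np.ndarray:
    scales = {}
    for name in spec.observed:
        base = name[:-3]
        if base not in scales:
            s = np.nanstd(Y[f"{base}_w2"].to_numpy(dtype=float))
            scales[base] = float(s) if np.isfinite(s) and s > 0 else 1.0
    return np.array([scales[name[:-3]] for name in spec.observed]), scales


def _affine_map(spec: ModelSpec, scales: dict) -> tuple:
    """(a, b) with theta_native = a * theta_scaled + b."""
    markers = {d: spec.indicators[d][0] for d in spec.domains}
    d_bio = scales[spec.biomarker]
    d_m = {d: scales[markers[d]] for d in spec.domains}
    a, b = [], []
    for ind in spec._free_loadings:
        a.append(scales[ind] / d_m[spec._ind_dom[ind]])
        b.append(0.0)
    for ind in spec.indicator_list:
        a.append(scales[ind])
        b.append(0.0)
    for _w in (2, 3):
        for ind in spec.indicator_list:
            a.append(1.0)
            b.append(2.0 * np.log(scales[ind]))
    s_lat = [d_bio, d_bio] + [d_m[d] for d in spec.domains] + [d_m[d] for d in spec.domains]
    a += [d_bio, d_bio] + [d_m[d] for d in spec.domains]
    b += [0.0] * (2 + len(spec.domains))
    for i in range(spec.n_latent):
        for j in range(i + 1):
            if i == j:
                a.append(1.0)
                b.append(np.log(s_lat[i]))
            else:
                a.append(s_lat[i])
                b.append(0.0)
    return np.asarray(a), np.asarray(b)


def patterns_log_jacobian(patterns: MissingPatterns, col_scale: np.ndarray) -> float:
    """Log-density Jacobian of the column rescaling (sum of log scales over
    every observed entry); converts a scaled-data log-likelihood to native
    units."""
    log_s = np.log(col_scale)
    return float(
        sum(n_k * log_s[mask].sum() for mask, n_k in zip(patterns.masks, patterns.counts))
    )


def _numerical_hessian(fun_grad, theta: np.ndarray, step: float = 1e-4) -> np.ndarray:
    q = theta.shape[0]
    H = np.empty((q, q))
    for j in range(q):
        h = step * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        H[:, j] = (fun_grad(tp) - fun_grad(tm)) / (2 * h)
    return 0.5 * (H + H.T)


def fit(
    spec: ModelSpec,
    table: pd.DataFrame,
    theta0: np.ndarray | None = None,
    max_iter: int = 5000,
    gtol: float = 1e-6,
    ftol: float = 1e-10,
    compute_se: bool = True,
) -> FittedModel:
    """Estimate ``spec`` from an incomplete table by FIML.

    Quasi-Newton (L-BFGS-B) maximization from data-driven starting values;
    standard errors from the inverse of the numerical observed-information
    matrix (central differences of the analytic-chain gradient).
    """
    Y = table[list(spec.observed)]
    Ymat = Y.to_numpy(dtype=float)
    nobs = np.isfinite(Ymat).sum(axis=0)
    thin = [n for n, c in zip(spec.observed, nobs) if c < 2]
    if thin:
        raise ValueError(f"variables with < 2 observed values: {thin}")

    col_scale, scale_map = _column_scales(spec, Y)
    a_map, b_map = _affine_map(spec, scale_map)
    Ys = pd.DataFrame(Ymat / col_scale, columns=list(spec.observed))
    patterns = compute_patterns(Ys.to_numpy(dtype=float))
    if patterns.n_used < 1:
        raise ValueError("no rows with any observed analysis variable")

    if theta0 is None:
        theta0s = start_values(spec, Ys)
    else:
        theta0s = (np.asarray(theta0, dtype=float) - b_map) / a_map

    def neg(theta):
        return -fiml_loglik(theta, patterns, spec)

    def grad(theta):
        ll = fiml_loglik(theta, patterns, spec)
        if ll <= _SENTINEL:
            return np.zeros_like(theta)
        return -fiml_gradient(theta, patterns, spec)

    res = optimize.minimize(
        neg,
        theta0s,
        jac=grad,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": ftol, "gtol": gtol, "maxcor": 30},
    )
    theta_s = res.x
    ll0 = fiml_loglik(theta0s, patterns, spec)
    ll = -res.fun
    if ll < ll0:  # never return a point worse than the start
        theta_s, ll = theta0s, ll0
    gnorm = float(np.max(np.abs(grad(theta_s))))
    converged = bool(res.success or gnorm < 1e-3)

    q = theta_s.shape[0]
    se = np.full(q, np.nan)
    cov = np.full((q, q), np.nan)
    se_ok = False
    if compute_se:
        H = _numerical_hessian(lambda t: -fiml_gradient(t, patterns, spec), theta_s)
        try:
            cov = np.linalg.inv(H)
            dg = np.diag(cov)
            se_ok = bool(np.all(dg > 0))
            if not se_ok:
                cov = np.linalg.pinv(H)
                dg = np.diag(cov)
            se = np.sqrt(np.clip(dg, 0.0, None))
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(H)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    # map the scaled-space solution back to native units (exact affine map)
    theta = a_map * theta_s + b_map
    theta0_nat = a_map * theta0s + b_map
    cov = cov * np.outer(a_map, a_map)
    se = se * np.abs(a_map)
    ll = ll - patterns_log_jacobian(patterns, col_scale)
    return FittedModel(
        spec=spec,
        theta=theta,
        se=se,
        cov=cov,
        loglik=ll,
        converged=converged,
        se_ok=se_ok,
        n_used=patterns.n_used,
        n_dropped=patterns.n_dropped,
        iterations=int(res.nit),
        gradient_norm=gnorm,
        message=str(res.message),
        start_theta=theta0_nat,
    )


# ---------------------------------------------------------------------- #
# saturated and baseline reference fits


@dataclass
class ReferenceFit:
    """Unstructured (saturated) or independence (baseline) FIML fit."""

    mu: np.ndarray
    Sigma: np.ndarray
    loglik: float
    n_params: int
    n_used: int
    converged: bool
    iterations: int
    columns: tuple = field(default_factory=tuple)


def fit_saturated(table: pd.DataFrame, tol: float = 1e-10, max_iter: int = 2000) -> ReferenceFit:
    """Saturated FIML fit (free mean vector and covariance) via EM.

    On complete data this equals the sample moments (ML divisor n) after a
    single step.
    """
    Y = table.to_numpy(dtype=float)
    patterns = compute_patterns(Y)
    p = Y.shape[1]
    mu = np.array([np.nanmean(Y[:, j]) for j in range(p)])
    var = np.array([max(np.nanvar(Y[:, j]), 1e-10) for j in range(p)])
    complete = np.all(np.isfinite(Y), axis=1)
    if complete.sum() > p + 1:
        Sigma = np.cov(Y[complete].T, ddof=0)
        w, V = np.linalg.eigh(Sigma)
        Sigma = V @ np.diag(np.maximum(w, 1e-8 * max(w.max(), 1.0))) @ V.T
    else:
        Sigma = np.diag(var)
    n = patterns.n_used
    ll_old = loglik_moments(mu, Sigma, patterns)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sum_y = np.zeros(p)
        sum_yy = np.zeros((p, p))
        for mask, n_k, xbar, W in zip(
            patterns.masks, patterns.counts, patterns.means, patterns.scatters
        ):
            o = np.where(mask)[0]
            m = np.where(~mask)[0]
            Soo = Sigma[np.ix_(o, o)]
            Ey = np.zeros(p)
            Ey[o] = xbar
            Eyy = np.zeros((p, p))
            # observed-observed second moment: scatter + mean outer product
            Eyy[np.ix_(o, o)] = W + np.outer(xbar, xbar)
            if m.size:
                B = Sigma[np.ix_(m, o)] @ np.linalg.inv(Soo)
                mhat_mean = mu[m] + B @ (xbar - mu[o])
                Ey[m] = mhat_mean
                Cc = Sigma[np.ix_(m, m)] - B @ Sigma[np.ix_(o, m)]
                # E[y_m y_o'] and E[y_m y_m'] from the conditional distribution
                Eyy[np.ix_(m, o)] = np.outer(mhat_mean, xbar) + B @ W
                Eyy[np.ix_(o, m)] = Eyy[np.ix_(m, o)].T
                Eyy[np.ix_(m, m)] = (
                    Cc
                    + B @ W @ B.T
                    + np.outer(mhat_mean, mhat_mean)
                )
            sum_y += n_k * Ey
            sum_yy += n_k * Eyy
        mu = sum_y / n
        Sigma = sum_yy / n - np.outer(mu, mu)
        Sigma = 0.5 * (Sigma + Sigma.T)
        ll = loglik_moments(mu, Sigma, patterns)
        if ll <= _SENTINEL:
            break
        if abs(ll - ll_old) < tol * max(1.0, abs(ll)):
            ll_old = ll
            converged = True
            break
        ll_old = ll
    return ReferenceFit(
        mu=mu,
        Sigma=Sigma,
        loglik=float(ll_old),
        n_params=p + p * (p + 1) // 2,
        n_used=n,
        converged=converged,
        iterations=it,
        columns=tuple(table.columns),
    )


def fit_baseline(table: pd.DataFrame) -> ReferenceFit:
    """Independence baseline: free means and variances, zero covariances.

    With a diagonal covariance the FIML solution is closed form: each
    variable's observed-case mean and ML variance.
    """
    Y = table.to_numpy(dtype=float)
    p = Y.shape[1]
    mu = np.empty(p)
    var = np.empty(p)
    ll = 0.0
    for j in range(p):
        x = Y[:, j]
        x = x[np.isfinite(x)]
        mu[j] = x.mean()
        var[j] = max(x.var(), 1e-12)
        ll += -0.5 * (x.size * (LN2PI + np.log(var[j])) + ((x - mu[j]) ** 2).sum() / var[j])
    any_obs = np.isfinite(Y).any(axis=1)
    return ReferenceFit(
        mu=mu,
        Sigma=np.diag(var),
        loglik=float(ll),
        n_params=2 * p,
        n_used=int(any_obs.sum()),
        converged=True,
        iterations=0,
        columns=tuple(table.columns),
    )


# ---------------------------------------------------------------------- #
# standardized solution


def _standardized_vector(spec: ModelSpec, theta: np.ndarray) -> tuple:
    """All structural correlations and SD-unit change means, with labels."""
    _, _, _, alpha, Psi = spec.unpack(theta)
    sd = np.sqrt(np.diag(Psi))
    k = spec.n_latent
    labels, vals = [], []
    for i in range(k):
        for j in range(i + 1, k):
            labels.append(("correlation", spec.latents[i], spec.latents[j]))
            vals.append(Psi[i, j] / (sd[i] * sd[j]))
    nd = len(spec.domains)
    pairs = [("bio_change", "bio_level")] + [
        (f"{d}_change", f"{d}_level") for d in spec.domains
    ]
    for ch, lev in pairs:
        labels.append(("std_change_mean", ch, lev))
        vals.append(alpha[spec.structural_index(ch)] / sd[spec.structural_index(lev)])
    return labels, np.array(vals)


def standardize(fitted: FittedModel) -> pd.DataFrame:
    """Standardized structural solution with delta-method standard errors.

    Covariances are divided by the product of model-implied SDs; change means
    by the model-implied SD of the corresponding baseline level (so they read
    as 'change of X baseline SDs').
    """
    spec, theta = fitted.spec, fitted.theta
    labels, vals = _standardized_vector(spec, theta)
    q = theta.shape[0]
    J = np.empty((len(vals), q))
    for j in range(q):
        h = 1e-5 * max(1.0, abs(theta[j]))
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h
        tm[j] -= h
        _, vp = _standardized_vector(spec, tp)
        _, vm = _standardized_vector(spec, tm)
        J[:, j] = (vp - vm) / (2 * h)
    if np.all(np.isfinite(fitted.cov)):
        var = np.einsum("iq,qr,ir->i", J, fitted.cov, J)
        se = np.sqrt(np.clip(var, 0.0, None))
    else:
        se = np.full(len(vals), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = vals / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "kind": [l[0] for l in labels],
            "var1": [l[1] for l in labels],
            "var2": [l[2] for l in labels],
            "estimate": vals,
            "se": se,
            "z": z,
            "p": p,
        }
    )
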