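"""Binomial mixed-effects logistic regression via the Laplace approximation.

Fits  y_i ~ Bernoulli(expit(offset_i + x_i' beta + sum_g b_g[code_gi]))
with independent Gaussian random intercepts per grouping factor,
b_g ~ N(0, tau_g^2 I).  The marginal likelihood is approximated by a Laplace
integral around the joint mode of the random effects (found by damped
Newton), and (beta, log tau) maximized by L-BFGS-B — the same algorithm
family as lme4's default `glmer` fit.  Wald intervals come from the numeric
Hessian of the Laplace marginal deviance in beta at the optimum, with the
variance parameters held at their estimates (lme4's convention).

Random-effect dimensions here are small (tens), so dense linear algebra is
used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit

_LOG_SD_MIN, _LOG_SD_MAX = np.log(1e-4), np.log(20.0)
_BETA_MAX = 15.0


class GlmmError(ValueError):
    pass


@dataclass
class LaplaceFit:
    beta: np.ndarray
    beta_se: np.ndarray
    tau2: dict[str, float]  # random-intercept variances per grouping factor
    loglik: float
    converged: bool
    separation: bool
    ranef_modes: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    n_obs: int = 0
    messages: list[str] = field(default_factory=list)


def _encode_groups(
    groups: dict[str, Sequence],
) -> tuple[list[str], list[np.ndarray], list[int]]:
    names, codes, sizes = [], [], []
    for name, values in groups.items():
        vals = np.asarray(values)
        _, inv = np.unique(vals, return_inverse=True)
        names.append(name)
        codes.append(inv.astype(np.intp))
        sizes.append(int(inv.max()) + 1)
    return names, codes, sizes


def fit_laplace(
    y: np.ndarray,
    X: np.ndarray,
    groups: dict[str, Sequence],
    offset: np.ndarray | float = 0.0,
    start_beta: Optional[np.ndarray] = None,
) -> LaplaceFit:
    """Fit the mixed logistic model; ``groups`` maps factor name -> codes."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise GlmmError("y and X disagree on n")
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (n,)).copy()
    names, codes, sizes = _encode_groups(groups)
    q = int(np.sum(sizes))
    starts = np.concatenate([[0], np.cumsum(sizes)])  # block boundaries in b

    separation = bool(y.min() == y.max())
    messages: list[str] = []
    if separation:
        messages.append("complete separation: all responses identical")

    b_warm = np.zeros(q)

    def eta_of(beta: np.ndarray, b: np.ndarray) -> np.ndarray:
        eta = offset + X @ beta
        for g, code in enumerate(codes):
            eta = eta + b[starts[g] : starts[g + 1]][code]
        return eta

    def inner_mode(beta: np.ndarray, prec: np.ndarray) -> tuple[np.ndarray, float, np.ndarray]:
        """Newton for the penalized log-likelihood in b; returns (bhat, f(bhat), H)."""
        nonlocal b_warm
        b = b_warm.copy()
        lam = np.repeat(prec, sizes)  # per-coordinate prior precision

        def f_val(b: np.ndarray) -> float:
            eta = eta_of(beta, b)
            # -loglik with stable log1p(exp)
            nll = np.sum(np.logaddexp(0.0, eta) - y * eta)
            return nll + 0.5 * np.sum(lam * b * b)

        fb = f_val(b)
        H = np.diag(lam)
        for _ in range(80):
            eta = eta_of(beta, b)
            mu = expit(eta)
            resid = mu - y
            grad = np.empty(q)
            w = mu * (1.0 - mu)
            H = np.zeros((q, q))
            for g, code in enumerate(codes):
                grad[starts[g] : starts[g + 1]] = np.bincount(
                    code, weights=resid, minlength=sizes[g]
                )
                for h in range(g, len(codes)):
                    block = np.zeros((sizes[g], sizes[h]))
                    np.add.at(block, (code, codes[h]), w)
                    H[starts[g] : starts[g + 1], starts[h] : starts[h + 1]] = block
                    if h != g:
                        H[starts[h] : starts[h + 1], starts[g] : starts[g + 1]] = block.T
            grad += lam * b
            H[np.diag_indices(q)] += lam
            if np.max(np.abs(grad)) < 1e-9:
                break
            step = np.linalg.solve(H, grad)
            t = 1.0
            for _ in range(30):
                b_new = b - t * step
                f_new = f_val(b_new)
                if f_new <= fb + 1e-12:
                    b, fb = b_new, f_new
                    break
                t *= 0.5
            else:
                break
        b_warm = b.copy()
        return b, fb, H

    def marginal_nll(theta: np.ndarray) -> float:
        beta = theta[:p]
        log_sd = theta[p:]
        tau2 = np.exp(2.0 * log_sd)
        prec = 1.0 / tau2
        _, fb, H = inner_mode(beta, prec)
        sign, logdet_H = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        logdet_D = float(np.sum(np.repeat(2.0 * log_sd, sizes)))
        return fb + 0.5 * logdet_D + 0.5 * logdet_H

    if start_beta is None:
        # crude logistic start for the intercept on the offset scale
        pbar = float(np.clip(y.mean(), 1e-3, 1 - 1e-3))
        b0 = np.log(pbar / (1 - pbar)) - float(np.mean(offset))
        start_beta = np.zeros(p)
        start_beta[0] = np.clip(b0, -3, 3)
    x0 = np.concatenate([start_beta, np.full(len(sizes), np.log(0.5))])
    bounds = [(-_BETA_MAX, _BETA_MAX)] * p + [(_LOG_SD_MIN, _LOG_SD_MAX)] * len(sizes)
    res = optimize.minimize(
        marginal_nll, x0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 200, "ftol": 1e-11, "gtol": 1e-7},
    )
    beta_hat = res.x[:p]
    log_sd_hat = res.x[p:]
    tau2 = {name: float(np.exp(2.0 * s)) for name, s in zip(names, log_sd_hat)}

    # Wald covariance for beta: numeric Hessian of the marginal deviance in
    # beta at the optimum, variance parameters fixed.
    def nll_beta(beta: np.ndarray) -> float:
        return marginal_nll(np.concatenate([beta, log_sd_hat]))

    eps = 1e-4
    Hb = np.zeros((p, p))
    f0 = nll_beta(beta_hat)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            if i == j:
                val = (nll_beta(beta_hat + ei) - 2 * f0 + nll_beta(beta_hat - ei)) / eps**2
            else:
                val = (
                    nll_beta(beta_hat + ei + ej)
                    - nll_beta(beta_hat + ei - ej)
                    - nll_beta(beta_hat - ei + ej)
                    + nll_beta(beta_hat - ei - ej)
                ) / (4 * eps**2)
            Hb[i, j] = Hb[j, i] = val
    try:
        cov = np.linalg.inv(Hb)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        if np.any(np.diag(cov) <= 0):
            messages.append("non-positive-definite Wald Hessian")
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        messages.append("singular Wald Hessian")

    prec_hat = 1.0 / np.exp(2.0 * log_sd_hat)
    b_hat, _, _ = inner_mode(beta_hat, prec_hat)
    modes = {
        name: b_hat[starts[g] : starts[g + 1]].copy() for g, name in enumerate(names)
    }
    converged = bool(res.success) and not separation
    if not res.success:
        messages.append(f"optimizer: {res.message}")
    return LaplaceFit(
        beta=beta_hat,
        beta_se=se,
        tau2=tau2,
        loglik=-float(res.fun),
        converged=converged,
        separation=separation,
        ranef_modes=modes,
        n_obs=n,
        messages=messages,
    )
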