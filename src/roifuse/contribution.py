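"""Modality contribution via Cox-Snell R-squared ratios.

A logistic regression log(p/(1-p)) = X'b models group membership from a
feature block.  The fit of each single-modality block and of the fused
block is summarised by the Cox-Snell index

    R^2 = 1 - exp(2 * (l0 - l1) / n),

where l0 and l1 are the intercept-only and model log-likelihoods; the
contribution of a modality to the fusion is R^2_modality / R^2_fusion.

Fits use damped Newton iterations on the (optionally ridge-penalised)
log-likelihood; the intercept is never penalised, and R^2 is always
computed from the plain (unpenalised) log-likelihood evaluated at the
fitted coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_GTOL = 1e-8
_MAX_ITER = 200


@dataclass
class LogisticFit:
    beta: np.ndarray  # intercept first
    prob: np.ndarray
    loglik: float
    loglik_null: float
    n: int
    ridge: float
    converged: bool
    n_iter: int


@dataclass
class ContributionResult:
    r2: dict[str, float]  # per block, plus "fusion"
    ratios: dict[str, float]  # r2[block] / r2["fusion"]
    fits: dict[str, LogisticFit]


def _bernoulli_loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable for large |eta|
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only model (closed form)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    n1 = y.sum()
    n0 = n - n1
    ll = 0.0
    if n1 > 0:
        ll += n1 * np.log(n1 / n)
    if n0 > 0:
        ll += n0 * np.log(n0 / n)
    return float(ll)


def fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0) -> LogisticFit:
    """Maximum-likelihood (or ridge-penalised) logistic regression.

    ``ridge`` adds (ridge/2)*||b||^2 to the negative log-likelihood for the
    slope coefficients only.  Convergence requires the gradient max-norm to
    fall below 1e-8.  With ridge = 0, quasi-separated data drive ||b|| to
    infinity; this is detected and reported as an error rather than a
    spurious fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    if ridge < 0:
        raise ValueError("ridge penalty must be >= 0")
    n, k = X.shape
    Z = np.column_stack([np.ones(n), X])
    pen = np.r_[0.0, np.full(k, ridge)]  # intercept unpenalised
    beta = np.zeros(k + 1)
    converged = False
    it = 0
    prev_obj = -np.inf
    for it in range(1, _MAX_ITER + 1):
        eta = Z @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = Z.T @ (y - p) - pen * beta
        gmax = float(np.max(np.abs(grad)))
        cur_obj = _bernoulli_loglik(eta, y) - 0.5 * (pen * beta**2).sum()
        if gmax < _GTOL:
            converged = True
            break
        if cur_obj - prev_obj < 1e-12 * (1.0 + abs(cur_obj)):
            # objective no longer improves at float precision; accept the
            # point as the optimum if the gradient is already negligible
            converged = gmax < 1e-5 * max(1.0, abs(cur_obj))
            break
        prev_obj = cur_obj
        w = np.maximum(p * (1.0 - p), 1e-12)
        H = (Z * w[:, None]).T @ Z + np.diag(pen + 1e-14)
        step = np.linalg.solve(H, grad)
        # backtracking line search on the penalised log-likelihood
        t = 1.0
        while t > 1e-10:
            cand = beta + t * step
            cand_obj = _bernoulli_loglik(Z @ cand, y) - 0.5 * (pen * cand**2).sum()
            if cand_obj >= cur_obj:
                break
            t /= 2.0
        if t <= 1e-10:
            converged = gmax < 1e-5 * max(1.0, abs(cur_obj))
            break
        beta = beta + t * step
    eta = Z @ beta
    if ridge == 0.0:
        # under (quasi-)separation the gradient also vanishes as ||b|| -> inf,
        # so a converged iteration with a huge, perfectly separating slope
        # vector is a divergence in disguise
        margins = np.where(y == 1, eta, -eta)
        if np.max(np.abs(beta[1:])) > 15.0 and np.min(margins) > 0:
            raise FloatingPointError(
                "complete or quasi-complete separation: the MLE is infinite; "
                "refit with a positive ridge penalty"
            )
    if not converged:
        if ridge == 0.0:
            raise FloatingPointError(
                "logistic MLE did not converge (possible separation); "
                "refit with a positive ridge penalty"
            )
        raise FloatingPointError("ridge-penalised logistic fit did not converge")
    prob = 1.0 / (1.0 + np.exp(-eta))
    return LogisticFit(
        beta=beta,
        prob=prob,
        loglik=_bernoulli_loglik(eta, y),
        loglik_null=null_loglik(y),
        n=n,
        ridge=ridge,
        converged=converged,
        n_iter=it,
    )


def cox_snell_r2(fit: LogisticFit) -> float:
    """Cox-Snell R^2 = 1 - exp(2*(l0 - l1)/n) of a logistic fit."""
    if fit.loglik < fit.loglik_null - 1e-6:
        raise ValueError(
            "model log-likelihood below the null beyond tolerance; the fit failed"
        )
    return float(1.0 - np.exp(2.0 * (fit.loglik_null - fit.loglik) / fit.n))


def contribution_ratios(
    X_by_modality: dict[str, np.ndarray],
    y: np.ndarray,
    X_fusion: np.ndarray | None = None,
    ridge: float = 1e-4,
) -> ContributionResult:
    """Cox-Snell R^2 of each modality block and of their fusion, with ratios.

    ``X_fusion`` defaults to the column-wise concatenation of the modality
    blocks.  All fits share the same subjects and the same ridge penalty.
    If the fusion model has R^2 = 0, ratios are undefined and returned as
    NaN.
    """
    y = np.asarray(y)
    if X_fusion is None:
        X_fusion = np.column_stack([np.asarray(v, float) for v in X_by_modality.values()])
    fits = {name: fit_logistic(X, y, ridge=ridge) for name, X in X_by_modality.items()}
    fits["fusion"] = fit_logistic(X_fusion, y, ridge=ridge)
    r2 = {name: cox_snell_r2(fit) for name, fit in fits.items()}
    denom = r2["fusion"]
    ratios = {
        name: (r2[name] / denom if denom > 0 else float("nan"))
        for name in X_by_modality
    }
    return ContributionResult(r2=r2, ratios=ratios, fits=fits)
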