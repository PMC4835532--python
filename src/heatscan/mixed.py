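"""A small REML engine for the crossed random-effect models used here.

The trial models are Gaussian mixed models

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, sigma2_k I),  e ~ N(0, sigma2_e I)

with a handful of variance components but potentially thousands of random
levels (genotypes, genotype x location cells, incomplete blocks).  The
restricted likelihood is profiled over ``sigma2_e`` and maximized over the
variance ratios ``lambda_k = sigma2_k / sigma2_e``; each evaluation solves
Henderson's mixed-model equations with a sparse LU factorization, which
also yields the log-determinants the REML criterion needs:

    -2 l_R(lambda) = (n - p) log(y' P y) + log|H| + log|X' H^-1 X| + const,

with ``H = I + sum_k lambda_k Z_k Z_k'`` and ``y'Py`` the penalized
residual sum of squares of the augmented least-squares problem.

Fixed effects come out as the GLS solution at the optimum; negative
variance components cannot occur (ratios live on a log scale and are
truncated to zero at the lower bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, sparse
from scipy.sparse.linalg import splu

_LOG_LAMBDA_LO, _LOG_LAMBDA_HI = -14.0, 14.0
_ZERO_TOL = 1e-5  # ratios below exp(_LOG_LAMBDA_LO)*e are reported as 0


def dummy_matrix(labels) -> tuple[sparse.csr_matrix, list]:
    """Sparse 0/1 indicator matrix for a label vector, one column per level."""
    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    n = len(codes)
    Z = sparse.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, len(levels))
    )
    return Z, list(levels)


def sum_zero_encode(labels) -> tuple[np.ndarray, list]:
    """Dense sum-to-zero (effects) coding; columns for all levels but the
    last, whose effect is minus the sum of the others."""
    codes, levels = pd.factorize(np.asarray(labels), sort=True)
    k = len(levels)
    X = np.zeros((len(codes), k - 1))
    for j in range(k - 1):
        X[codes == j, j] = 1.0
    X[codes == k - 1, :] = -1.0
    return X, list(levels)


def expand_sum_zero(coefs: np.ndarray) -> np.ndarray:
    """All-level effects from sum-to-zero coefficients (appends -sum)."""
    return np.concatenate([coefs, [-coefs.sum()]])


def nested_sum_zero_encode(outer, inner) -> tuple[np.ndarray, list[str]]:
    """Sum-to-zero coding of ``inner`` nested within ``outer``: for each
    outer level, one column per inner level but the last, constrained to
    sum to zero within that outer level.  Keeps a fixed outer main effect
    estimable alongside the nested term."""
    outer = np.asarray(outer)
    inner = np.asarray(inner)
    cols, names = [], []
    for o in pd.unique(outer):
        sel = outer == o
        levels = pd.unique(inner[sel])
        levels = sorted(levels)
        for lv in levels[:-1]:
            col = np.zeros(len(outer))
            col[sel & (inner == lv)] = 1.0
            col[sel & (inner == levels[-1])] = -1.0
            cols.append(col)
            names.append(f"{o}:{lv}")
    X = np.column_stack(cols) if cols else np.zeros((len(outer), 0))
    return X, names


@dataclass
class MixedFit:
    beta: np.ndarray
    beta_names: list[str]
    cov_beta: np.ndarray | None
    varcomps: dict[str, float]  # includes "residual"
    random_levels: dict[str, list]
    random_effects: dict[str, np.ndarray]
    fitted: np.ndarray
    resid: np.ndarray
    n: int
    p: int
    reml_criterion: float

    def fixef(self, prefix: str) -> dict[str, float]:
        return {nm: float(b) for nm, b in zip(self.beta_names, self.beta)
                if nm.startswith(prefix)}


def fit_mixed(
    y: np.ndarray,
    X: np.ndarray,
    beta_names: list[str],
    random_terms: dict[str, tuple[sparse.spmatrix, list]],
    compute_cov: bool = False,
    maxiter: int = 300,
) -> MixedFit:
    """REML fit of a mixed model with independent random terms.

    Parameters
    ----------
    random_terms
        Mapping term name -> (Z indicator matrix, level names).
    compute_cov
        Also return the GLS covariance of the fixed effects (needed for
        Wald tests; costs one extra solve per fixed-effect column).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n != len(y):
        raise ValueError("X and y have inconsistent lengths")
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            "fixed-effect design is singular; check the model terms "
            "(e.g. a condition fully confounded with a location)"
        )

    names = list(random_terms)
    Zs = [sparse.csr_matrix(random_terms[nm][0]) for nm in names]
    qs = [Z.shape[1] for Z in Zs]
    q = int(sum(qs))

    if q == 0:
        return _ols_fit(y, X, beta_names, compute_cov)

    A = sparse.hstack([sparse.csr_matrix(X)] + Zs, format="csc")
    G0 = (A.T @ A).tocsc()
    g0 = A.T @ y
    yty = float(y @ y)
    pen = sparse.diags(np.concatenate([np.zeros(p), np.ones(q)])).tocsc()

    block = np.concatenate([[0] * p] + [[k + 1] * qk for k, qk in enumerate(qs)])

    def assemble(lam: np.ndarray):
        s = np.where(block == 0, 1.0, np.sqrt(lam[block - 1].clip(min=0)))
        D = sparse.diags(s)
        M = (D @ G0 @ D + pen).tocsc()
        return M, s

    def criterion(log_lam: np.ndarray) -> float:
        lam = np.exp(np.clip(log_lam, _LOG_LAMBDA_LO, _LOG_LAMBDA_HI))
        M, s = assemble(lam)
        lu = splu(M, permc_spec="MMD_AT_PLUS_A")
        rhs = s * g0
        theta = lu.solve(rhs)
        ypy = max(yty - float(theta @ rhs), 1e-290)
        logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
        return (n - p) * np.log(ypy) + logdet

    if len(names) == 1:
        res = optimize.minimize_scalar(
            lambda t: criterion(np.array([t])),
            bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI), method="bounded",
            options={"xatol": 1e-4},
        )
        log_lam = np.array([res.x])
        crit = float(res.fun)
    else:
        # Cyclic coordinate descent on the log-ratio scale.  The nested
        # random terms of the trial models (blocks within replications,
        # genotype within its interactions) put flat ridges in the REML
        # surface that derail simplex methods; 1-D bounded searches per
        # component are slower per sweep but land reliably.
        x = np.zeros(len(names))
        prev = criterion(x)
        crit = prev
        max_sweeps = max(3, maxiter // 100)
        for _ in range(max_sweeps):
            for k in range(len(names)):
                def f1(t: float, k: int = k) -> float:
                    xx = x.copy()
                    xx[k] = t
                    return criterion(xx)
                res = optimize.minimize_scalar(
                    f1, bounds=(_LOG_LAMBDA_LO, _LOG_LAMBDA_HI),
                    method="bounded", options={"xatol": 2e-3})
                x[k] = res.x
                crit = float(res.fun)
            if prev - crit < 0.02:
                break
            prev = crit
        log_lam = x

    lam = np.exp(log_lam)
    M, s = assemble(lam)
    lu = splu(M, permc_spec="MMD_AT_PLUS_A")
    rhs = s * g0
    theta = lu.solve(rhs)
    ypy = max(yty - float(theta @ rhs), 0.0)
    sigma2_e = ypy / (n - p)

    beta = theta[:p]
    # back-scale the random effects (solution is for u_k / sqrt(lambda_k))
    u_scaled = theta[p:] * s[p:]
    random_effects, random_levels = {}, {}
    off = 0
    varcomps = {}
    for nm, qk, lk in zip(names, qs, lam):
        random_effects[nm] = u_scaled[off:off + qk]
        random_levels[nm] = list(random_terms[nm][1])
        sig = float(lk * sigma2_e)
        varcomps[nm] = 0.0 if lk <= np.exp(_LOG_LAMBDA_LO) * 1.01 else sig
        off += qk
    varcomps["residual"] = float(sigma2_e)

    fitted = X @ beta + sum(Z @ random_effects[nm] for nm, Z in zip(names, Zs))
    cov_beta = None
    if compute_cov:
        cols = np.zeros((p + q, p))
        cols[:p, :] = np.eye(p)
        Minv_cols = lu.solve(cols)
        cov_beta = sigma2_e * Minv_cols[:p, :]
        cov_beta = (cov_beta + cov_beta.T) / 2

    return MixedFit(
        beta=beta, beta_names=list(beta_names), cov_beta=cov_beta,
        varcomps=varcomps, random_levels=random_levels,
        random_effects=random_effects, fitted=fitted, resid=y - fitted,
        n=n, p=p, reml_criterion=crit,
    )


def _ols_fit(y, X, beta_names, compute_cov) -> MixedFit:
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.pinv(X.T @ X) if compute_cov else None
    return MixedFit(beta=beta, beta_names=list(beta_names), cov_beta=cov,
                    varcomps={"residual": sigma2}, random_levels={},
                    random_effects={}, fitted=fitted, resid=resid,
                    n=n, p=p, reml_criterion=float("nan"))


def wald_f_test(fit: MixedFit, term_cols: np.ndarray, ddf: float) -> tuple[float, float]:
    """Wald F test that a set of fixed-effect coefficients is zero.

    ``ddf`` is the denominator degrees of freedom supplied by the caller
    (a containment-style choice in the trial models).
    """
    from scipy import stats

    if fit.cov_beta is None:
        raise ValueError("fit was computed without compute_cov=True")
    b = fit.beta[term_cols]
    V = fit.cov_beta[np.ix_(term_cols, term_cols)]
    rank = len(b)
    F = float(b @ np.linalg.solve(V, b)) / rank
    pval = float(stats.f.sf(F, rank, ddf))
    return F, pval
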