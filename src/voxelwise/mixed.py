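"""Per-voxel linear mixed models with a single random intercept.

The longitudinal workhorse: ``y = X beta + Z b + e`` with one random
intercept per group (typically per subject, observations being repeat
visits), ``b ~ N(0, sigma2_g)``, ``e ~ N(0, sigma2_e)``. Estimation is
REML, profiled down to a one-dimensional search over the variance ratio
``lambda = sigma2_g / sigma2_e``: for fixed lambda both ``beta`` and
``sigma2_e`` have closed forms, so a bounded Brent minimization over
``log lambda in [-10, 10]`` fits one voxel in microseconds. The
block-diagonal structure of ``V = I + lambda Z Z'`` lets every quantity be
accumulated group by group without forming an n x n matrix.

Boundary fits (lambda -> 0) are reported as ``sigma2_g = 0``, where the
fixed effects coincide with OLS. Fixed-effect t maps use the conservative
``df = n - p - (n_groups - 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .modelspec import DesignBuilder, ModelSpec
from .parcellation import ParcelMap, parcellate
from .results import StatMapResult
from .volio import VoxelMatrix

__all__ = ["LMMResult", "fit_lmm_random_intercept", "reml_criterion"]

_LOGLAM_LO, _LOGLAM_HI = -10.0, 10.0
_BOUNDARY = np.exp(_LOGLAM_LO + 1e-6)


@dataclass
class LMMResult:
    """Fixed-effect maps plus variance-component maps."""

    stats: StatMapResult
    sigma2_g: np.ndarray
    sigma2_e: np.ndarray
    lambda_hat: np.ndarray
    n_groups: int


def _group_suff(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sufficient statistics for the Woodbury-style accumulation."""
    order = np.argsort(groups, kind="stable")
    Xo, yo, go = X[order], y[order], groups[order]
    uniq, starts = np.unique(go, return_index=True)
    bounds = np.append(starts, len(go))
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        Xg, yg = Xo[a:b], yo[a:b]
        out.append(
            (
                b - a,                      # m_g
                Xg.T @ Xg,                  # X'X
                Xg.T @ yg,                  # X'y
                float(yg @ yg),             # y'y
                Xg.sum(axis=0),             # column sums
                float(yg.sum()),
            )
        )
    return out


def reml_criterion(loglam: float, suff, n: int, p: int):
    """Profiled (-2) REML criterion at ``log lambda``; also returns beta, sigma2_e.

    criterion = log|V| + (n - p) log sigma2_e_hat + log|X' V^-1 X|
    with V = I + lambda Z Z' and sigma2_e_hat = r' V^-1 r / (n - p).
    """
    lam = np.exp(loglam)
    A = np.zeros((p, p))
    b = np.zeros(p)
    c = 0.0
    logdetV = 0.0
    for m, xtx, xty, yty, xs, ys in suff:
        shrink = lam / (1.0 + m * lam)
        A += xtx - shrink * np.outer(xs, xs)
        b += xty - shrink * xs * ys
        c += yty - shrink * ys * ys
        logdetV += np.log1p(m * lam)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf, None, None, None
    beta = np.linalg.solve(A, b)
    rss = max(c - beta @ b, 1e-300)  # r'V^-1 r via the normal-equation identity
    sigma2_e = rss / (n - p)
    crit = logdetV + (n - p) * np.log(sigma2_e) + logdetA
    return crit, beta, sigma2_e, A


def _fit_voxel_lmm(X, y, suff, n, p):
    res = optimize.minimize_scalar(
        lambda ll: reml_criterion(ll, suff, n, p)[0],
        bounds=(_LOGLAM_LO, _LOGLAM_HI),
        method="bounded",
        options={"xatol": 1e-8},
    )
    loglam = float(res.x)
    # prefer the boundary when it is as good: profiled criterion can be flat near 0
    c0 = reml_criterion(_LOGLAM_LO, suff, n, p)[0]
    if c0 <= res.fun + 1e-10:
        loglam = _LOGLAM_LO
    crit, beta, sigma2_e, A = reml_criterion(loglam, suff, n, p)
    lam = np.exp(loglam)
    if lam <= _BOUNDARY:
        lam = 0.0
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return beta, se, lam * sigma2_e, sigma2_e, lam


def fit_lmm_random_intercept(
    spec: ModelSpec,
    table,
    voxel_data: dict[str, VoxelMatrix] | None = None,
    pm: ParcelMap | None = None,
) -> LMMResult:
    """Voxel-wise random-intercept LMM for the model's grouping factor.

    Only a single random intercept is supported; random slopes are out of
    scope and rejected by construction (the grouping argument names a
    factor, not a formula).
    """
    if spec.grouping is None:
        raise ValueError("mixed model requires a grouping factor (spec.grouping)")
    if spec.family != "gaussian":
        raise ValueError("only Gaussian mixed models are supported")
    builder = DesignBuilder(spec, table, voxel_data)
    if builder.tau is None:
        raise ValueError("model references no voxel-wise data: nothing varies across voxels")
    groups = builder.group_codes()
    n_groups = int(groups.max()) + 1
    if n_groups < 2:
        raise ValueError("grouping factor must have at least 2 groups")
    sizes = np.bincount(groups)
    singletons_only = bool((sizes == 1).all())
    if singletons_only:
        warnings.warn(
            "every group has a single observation: the variance ratio is "
            "unidentifiable; sigma2_g forced to 0 (OLS fit)",
            stacklevel=2,
        )

    tau, p, n = builder.tau, builder.p, builder.n
    # with only singleton groups the model degrades to OLS: df = n - p
    df = float(n - p) if singletons_only else float(n - p - (n_groups - 1))
    if df <= 0:
        raise ValueError(
            f"too few observations (n={n}) for p={p} fixed effects and "
            f"{n_groups} groups"
        )
    if pm is None:
        pm = parcellate(tau, min(200, tau))

    beta = np.full((tau, p), np.nan)
    se = np.full((tau, p), np.nan)
    sigma2_g = np.zeros(tau)
    sigma2_e = np.zeros(tau)
    lambda_hat = np.zeros(tau)
    degenerate = np.zeros(tau, dtype=bool)
    converged = np.ones(tau, dtype=bool)

    static_X = None if builder.has_voxelwise else builder.design(None)
    static_suffX = None

    for k in range(pm.n_parcels):
        sl = pm.parcel_slice(k)
        for j in range(sl.start, sl.stop):
            X = static_X if static_X is not None else builder.design(j)
            y = builder.response(j)
            if np.isnan(y).any() or np.isnan(X).any():
                degenerate[j] = True
                converged[j] = False
                continue
            suff = _group_suff(X, y, groups)
            if singletons_only:
                crit, b, s2e, A = reml_criterion(_LOGLAM_LO, suff, n, p)
                cov = s2e * np.linalg.inv(A)
                beta[j], se[j] = b, np.sqrt(np.maximum(np.diag(cov), 0.0))
                sigma2_e[j] = s2e
                continue
            try:
                b, s, s2g, s2e, lam = _fit_voxel_lmm(X, y, suff, n, p)
            except np.linalg.LinAlgError:
                degenerate[j] = True
                converged[j] = False
                continue
            beta[j], se[j] = b, s
            sigma2_g[j], sigma2_e[j], lambda_hat[j] = s2g, s2e, lam

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    pval = np.where(np.isinf(t), 0.0, pval)
    stats_res = StatMapResult(
        term_names=list(builder.column_names),
        beta=beta,
        se=se,
        stat=t,
        pvalue=pval,
        df_residual=np.full(tau, df),
        converged=converged,
        degenerate=degenerate,
        stat_name="t",
        extra={"n_groups": n_groups},
    )
    return LMMResult(
        stats=stats_res,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        lambda_hat=lambda_hat,
        n_groups=n_groups,
    )
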