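"""Per-voxel ordinary least squares.

Two execution paths produce identical numbers:

* **shared-design path** — when no covariate is voxel-wise the design matrix
  is the same at every voxel, so it is QR-factored once and applied to all
  response columns in a single vectorized pass;
* **per-voxel path** — when the design itself changes across voxels (imaging
  covariates, interactions of images) each voxel's realized design is solved
  independently, chunked by parcel.

Per-voxel fits depend only on that voxel's data, so results are invariant to
the parcellation. Degenerate voxels (rank-deficient design, zero residual
variance) are flagged rather than aborting the run.

Inference is the standard Gaussian theory: ``t = beta / se`` with
``df = n - rank(X)`` and two-sided p-values. Subjects with NaN at a voxel
are dropped for that voxel only (per-voxel complete cases), unless
``strict`` is set, in which case NaN input is an error.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .modelspec import DesignBuilder, ModelSpec
from .parcellation import ParcelMap, parcellate
from .results import StatMapResult
from .volio import VoxelMatrix

__all__ = ["probe_outputs", "fit_linear"]

_RANK_TOL_FACTOR = 1e-10  # relative tolerance on QR diagonal for rank detection


def probe_outputs(
    spec: ModelSpec,
    table,
    voxel_data: dict[str, VoxelMatrix] | None = None,
) -> dict:
    """Single-voxel probe fit: report the output schema before any parcel work.

    Returns the design column (term) names and the statistic names every
    voxel fit will emit; raises immediately if even one voxel cannot be fit.
    """
    builder = DesignBuilder(spec, table, voxel_data)
    j = 0 if (builder.has_voxelwise or builder.voxelwise_response) else None
    X = builder.design(j)
    y = builder.response(j)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"too few subjects (n={X.shape[0]}) for {X.shape[1]} design columns"
        )
    _fit_voxel_ols(X, y)  # surfaces errors before the full run
    return {
        "terms": list(builder.column_names),
        "stats": ["beta", "se", "t", "p"],
        "n": builder.n,
        "p": builder.p,
    }


def _signed_ratio(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    """beta/se with the zero-variance convention: se=0 -> t=+/-inf (0 if beta=0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    zero_se = se == 0
    if np.any(zero_se):
        t = np.where(zero_se & (beta > 0), np.inf, t)
        t = np.where(zero_se & (beta < 0), -np.inf, t)
        t = np.where(zero_se & (beta == 0), 0.0, t)
    return t


def _fit_voxel_ols(X: np.ndarray, y: np.ndarray):
    """OLS at one voxel via QR. Returns (beta, se, df, rank_ok)."""
    n, p = X.shape
    Q, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    if diag.min() <= _RANK_TOL_FACTOR * max(n, p) * diag.max():
        return None, None, 0, False
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        return None, None, 0, False
    sigma2 = float(resid @ resid) / df
    Rinv = np.linalg.solve(R, np.eye(p))
    xtx_inv_diag = np.sum(Rinv * Rinv, axis=1)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv_diag, 0.0))
    return beta, se, df, True


def _pvalues(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1e-300))
    p = np.where(np.isinf(t), 0.0, p)
    return p


def fit_linear(
    spec: ModelSpec,
    table,
    voxel_data: dict[str, VoxelMatrix] | None = None,
    pm: ParcelMap | None = None,
    n_jobs: int = 1,
    strict: bool = False,
) -> StatMapResult:
    """Voxel-wise OLS for a Gaussian-family model.

    Emits per-term beta, standard-error, t and p maps plus per-voxel
    residual df and flags. ``pm`` controls chunking of the per-voxel path;
    it never changes the numbers.
    """
    if spec.family != "gaussian":
        raise ValueError("fit_linear requires family='gaussian' (see fit_glm)")
    builder = DesignBuilder(spec, table, voxel_data)
    if builder.tau is None:
        raise ValueError(
            "model references no voxel-wise data: nothing varies across voxels"
        )
    tau, p = builder.tau, builder.p
    if pm is None:
        pm = parcellate(tau, min(200, tau))

    beta = np.full((tau, p), np.nan)
    se = np.full((tau, p), np.nan)
    df_res = np.zeros(tau)
    degenerate = np.zeros(tau, dtype=bool)
    converged = np.ones(tau, dtype=bool)

    if not builder.has_voxelwise:
        # shared design: factor once, apply to every voxel's response column
        X = builder.design(None)
        Y = builder.response_matrix()  # n x tau
        if strict and np.isnan(Y).any():
            raise ValueError("NaN in response data (strict mode)")
        n = X.shape[0]
        Q, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        if diag.min() <= _RANK_TOL_FACTOR * max(n, p) * diag.max():
            raise ValueError("design matrix is rank deficient (collinear covariates)")
        nan_vox = np.flatnonzero(np.isnan(Y).any(axis=0))
        clean = np.setdiff1d(np.arange(tau), nan_vox)
        if clean.size:
            B = np.linalg.solve(R, Q.T @ Y[:, clean])          # p x m
            resid = Y[:, clean] - X @ B
            dof = n - p
            sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
            Rinv = np.linalg.solve(R, np.eye(p))
            xtx_inv_diag = np.sum(Rinv * Rinv, axis=1)          # length p
            S = np.sqrt(np.maximum(sigma2[None, :] * xtx_inv_diag[:, None], 0.0))
            beta[clean] = B.T
            se[clean] = S.T
            df_res[clean] = dof
            degenerate[clean] = sigma2 == 0
        for j in nan_vox:
            keep = ~np.isnan(Y[:, j])
            _store_voxel(X[keep], Y[keep, j], j, beta, se, df_res, degenerate, converged)
    else:
        # per-voxel designs, chunked by parcel
        for k in range(pm.n_parcels):
            sl = pm.parcel_slice(k)
            for j in range(sl.start, sl.stop):
                Xj = builder.design(j)
                yj = builder.response(j)
                keep = ~(np.isnan(yj) | np.isnan(Xj).any(axis=1))
                if strict and not keep.all():
                    raise ValueError(f"NaN in data at voxel {j} (strict mode)")
                _store_voxel(
                    Xj[keep], yj[keep], j, beta, se, df_res, degenerate, converged
                )

    t = _signed_ratio(beta, se)
    degenerate |= (se == 0).any(axis=1)
    pval = _pvalues(t, df_res[:, None])
    return StatMapResult(
        term_names=list(builder.column_names),
        beta=beta,
        se=se,
        stat=t,
        pvalue=pval,
        df_residual=df_res,
        converged=converged,
        degenerate=degenerate,
        stat_name="t",
    )


def _store_voxel(Xj, yj, j, beta, se, df_res, degenerate, converged):
    if Xj.shape[0] <= Xj.shape[1]:
        degenerate[j] = True
        converged[j] = False
        return
    b, s, dof, ok = _fit_voxel_ols(Xj, yj)
    if not ok:
        degenerate[j] = True
        converged[j] = False
        return
    beta[j] = b
    se[j] = s
    df_res[j] = dof
    if np.any(s == 0):
        degenerate[j] = True
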