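"""Per-voxel generalized linear models via iteratively reweighted least squares.

Supports binomial, Poisson, gamma and inverse-Gaussian responses (plus
Gaussian, for cross-checking against the OLS engine). Default links are
logit for binomial and log for the positive-mean families; canonical links
are selectable. Inference is Wald: ``z = beta / se`` from the final
weighted information matrix, with the scale fixed at 1 for binomial/Poisson
and estimated by the Pearson statistic for gamma/inverse-Gaussian.

Degenerate voxels (non-convergence, complete separation) are flagged and
NaN-ed; one pathological voxel never aborts a map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import stats

from .modelspec import DesignBuilder, ModelSpec
from .parcellation import ParcelMap, parcellate
from .results import StatMapResult
from .volio import VoxelMatrix

__all__ = ["GLMFamily", "get_family", "irls_fit", "fit_glm", "scaled_odds_ratio"]

_XTOL = 1e-12


@dataclass(frozen=True)
class Link:
    name: str
    g: Callable[[np.ndarray], np.ndarray]          # eta = g(mu)
    ginv: Callable[[np.ndarray], np.ndarray]       # mu = g^-1(eta)
    gprime: Callable[[np.ndarray], np.ndarray]     # d eta / d mu


def _clip01(mu):
    return np.clip(mu, 1e-10, 1 - 1e-10)


LINKS = {
    "identity": Link("identity", lambda m: m, lambda e: e, lambda m: np.ones_like(m)),
    "log": Link("log", np.log, np.exp, lambda m: 1.0 / m),
    "logit": Link(
        "logit",
        lambda m: np.log(m / (1 - m)),
        lambda e: 1.0 / (1.0 + np.exp(-e)),
        lambda m: 1.0 / (m * (1 - m)),
    ),
    "inverse": Link("inverse", lambda m: 1.0 / m, lambda e: 1.0 / e, lambda m: -1.0 / m**2),
    "inverse_squared": Link(
        "inverse_squared", lambda m: 1.0 / m**2, lambda e: e**-0.5, lambda m: -2.0 / m**3
    ),
}


@dataclass(frozen=True)
class GLMFamily:
    """Distribution family: variance function, deviance, default link, scale rule."""

    name: str
    link: Link
    variance: Callable[[np.ndarray], np.ndarray]
    deviance: Callable[[np.ndarray, np.ndarray], float]
    init_mu: Callable[[np.ndarray], np.ndarray]
    estimate_scale: bool  # Pearson scale for gamma / inverse-Gaussian


def _xlogy(x, y):
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(x == 0, 0.0, x * np.log(y))
    return out


def _dev_binomial(y, mu):
    mu = _clip01(mu)
    return float(2.0 * np.sum(_xlogy(y, y / mu) + _xlogy(1 - y, (1 - y) / (1 - mu))))


def _dev_poisson(y, mu):
    return float(2.0 * np.sum(_xlogy(y, y / mu) - (y - mu)))


def _dev_gamma(y, mu):
    return float(2.0 * np.sum(-np.log(y / mu) + (y - mu) / mu))


def _dev_invgauss(y, mu):
    return float(np.sum((y - mu) ** 2 / (mu**2 * y)))


def _dev_gaussian(y, mu):
    return float(np.sum((y - mu) ** 2))


_FAMILIES = {
    "gaussian": ("identity", lambda m: np.ones_like(m), _dev_gaussian, lambda y: y.copy(), True),
    "binomial": ("logit", lambda m: m * (1 - m), _dev_binomial, lambda y: (y + 0.5) / 2.0, False),
    "poisson": ("log", lambda m: m, _dev_poisson, lambda y: y + 0.5, False),
    "gamma": ("log", lambda m: m**2, _dev_gamma, lambda y: y.copy(), True),
    "inverse_gaussian": ("log", lambda m: m**3, _dev_invgauss, lambda y: y.copy(), True),
}

_CANONICAL = {
    "gaussian": "identity",
    "binomial": "logit",
    "poisson": "log",
    "gamma": "inverse",
    "inverse_gaussian": "inverse_squared",
}


def get_family(name: str, link: str | None = None) -> GLMFamily:
    """Family by name with its default link (canonical selectable via ``link``)."""
    if name not in _FAMILIES:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(_FAMILIES)}")
    default_link, var, dev, init, est_scale = _FAMILIES[name]
    link_name = link or default_link
    if link_name == "canonical":
        link_name = _CANONICAL[name]
    if link_name not in LINKS:
        raise ValueError(f"unknown link {link_name!r}")
    return GLMFamily(
        name=name,
        link=LINKS[link_name],
        variance=var,
        deviance=dev,
        init_mu=init,
        estimate_scale=est_scale,
    )


def _check_response(y: np.ndarray, family: GLMFamily) -> None:
    if family.name == "binomial":
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("binomial response must be binary 0/1")
        if y.min() == y.max():
            raise ValueError("response has a single level")
    elif family.name == "poisson":
        if (y < 0).any():
            raise ValueError("poisson response must be non-negative")
    elif family.name in ("gamma", "inverse_gaussian"):
        if (y <= 0).any():
            raise ValueError(f"{family.name} response must be strictly positive")


def irls_fit(
    X: np.ndarray,
    y: np.ndarray,
    family: GLMFamily,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """IRLS maximum likelihood for one design/response pair.

    Returns ``(beta, cov, deviance, converged, separated)``. Convergence is
    ``|delta deviance| < tol``; on complete separation (binomial linear
    predictor diverging) the flag is set and the last iterate returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} subjects cannot identify {p} coefficients")
    mu = family.init_mu(y)
    if family.name == "binomial":
        mu = _clip01(mu)
    eta = family.link.g(mu)
    dev = family.deviance(y, mu)
    converged = False
    separated = False
    beta = np.zeros(p)
    for _ in range(max_iter):
        gp = family.link.gprime(mu)
        W = 1.0 / (family.variance(mu) * gp**2)
        z = eta + (y - mu) * gp
        sw = np.sqrt(W)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        eta = X @ beta
        if family.name == "binomial" and np.max(np.abs(eta)) > 30:
            separated = True
        mu = family.link.ginv(eta)
        if family.name == "binomial":
            mu = _clip01(mu)
        elif family.name in ("poisson", "gamma", "inverse_gaussian"):
            mu = np.maximum(mu, 1e-10)
        dev_new = family.deviance(y, mu)
        if abs(dev_new - dev) < tol:
            dev = dev_new
            converged = True
            break
        dev = dev_new
    # a binomial deviance of ~0 means perfect classification: separation
    if family.name == "binomial" and dev < 1e-6:
        separated = True
    gp = family.link.gprime(mu)
    W = 1.0 / (family.variance(mu) * gp**2)
    info = (X * W[:, None]).T @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
        separated = True
    if family.estimate_scale:
        pearson = float(np.sum((y - mu) ** 2 / family.variance(mu)))
        cov = cov * (pearson / (n - p))
    return beta, cov, dev, converged, separated


def fit_glm(
    spec: ModelSpec,
    table,
    voxel_data: dict[str, VoxelMatrix] | None = None,
    pm: ParcelMap | None = None,
    link: str | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> StatMapResult:
    """Voxel-wise GLM: scalar response, voxel-wise predictors allowed.

    Emits per-term beta, se, Wald z and p maps plus convergence and
    separation flags; per-voxel deviance is stored in ``extra``.
    """
    family = get_family(spec.family, link)
    builder = DesignBuilder(spec, table, voxel_data)
    if builder.voxelwise_response:
        raise ValueError(
            "generalized models require a scalar response; voxel-wise "
            "responses are supported by the Gaussian engine only"
        )
    if builder.tau is None:
        raise ValueError("model references no voxel-wise data: nothing varies across voxels")
    y = builder.response()
    _check_response(y, family)
    tau, p = builder.tau, builder.p
    if pm is None:
        pm = parcellate(tau, min(200, tau))

    beta = np.full((tau, p), np.nan)
    se = np.full((tau, p), np.nan)
    df_res = np.zeros(tau)
    converged = np.zeros(tau, dtype=bool)
    degenerate = np.zeros(tau, dtype=bool)
    deviance = np.full(tau, np.nan)

    for k in range(pm.n_parcels):
        sl = pm.parcel_slice(k)
        for j in range(sl.start, sl.stop):
            Xj = builder.design(j)
            keep = ~(np.isnan(y) | np.isnan(Xj).any(axis=1))
            Xk, yk = Xj[keep], y[keep]
            try:
                b, cov, dev, conv, sep = irls_fit(
                    Xk, yk, family, tol=tol, max_iter=max_iter
                )
            except (ValueError, np.linalg.LinAlgError):
                degenerate[j] = True
                continue
            converged[j] = conv
            if sep or not conv:
                degenerate[j] = True
                if sep:
                    continue  # separation: flag-and-NaN
            beta[j] = b
            with np.errstate(invalid="ignore"):
                se[j] = np.sqrt(np.maximum(np.diag(cov), 0.0))
            df_res[j] = Xk.shape[0] - p
            deviance[j] = dev

    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.where(np.isinf(z), 0.0, pval)
    return StatMapResult(
        term_names=list(builder.column_names),
        beta=beta,
        se=se,
        stat=z,
        pvalue=pval,
        df_residual=df_res,
        converged=converged,
        degenerate=degenerate,
        stat_name="z",
        extra={"deviance": deviance, "family": family.name, "link": family.link.name},
    )


def scaled_odds_ratio(
    beta1: np.ndarray, predictor: VoxelMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Odds ratio per one-SD increase of the predictor: ``OR_j = exp(beta_j * sd_j)``.

    ``sd_j`` is the across-subject sample standard deviation of the
    predictor at voxel j, computed on the analysis sample after variable
    operations. Constant-predictor voxels (sd=0) carry no information:
    OR is set to 1 and flagged. Returns ``(or_map, flagged)``.
    """
    beta1 = np.asarray(beta1, dtype=float).ravel()
    if beta1.size != predictor.tau:
        raise ValueError("beta map and predictor disagree on voxel count")
    sd = predictor.data.std(axis=0, ddof=1)
    flagged = sd == 0
    or_map = np.where(flagged, 1.0, np.exp(beta1 * sd))
    return or_map, flagged
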