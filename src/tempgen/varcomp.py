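"""REML animal models: heritability and genetic correlation.

The animal model decomposes a phenotype as ``y = X beta + a + e`` with
``a ~ N(0, sigma2_a A)`` (additive genetic, ``A`` the pedigree
relationship matrix) and ``e ~ N(0, sigma2_e I)``.  Because ``A`` can be
eigendecomposed once, rotating the data by its eigenvectors makes the
covariance diagonal and the restricted likelihood cheap: the univariate
fit is a one-dimensional search over the heritability
``h2 = sigma2_a / (sigma2_a + sigma2_e)``, and the bivariate fit — which
adds the genetic correlation ``rho_g`` and residual correlation
``rho_e`` — reduces to independent 2x2 blocks per eigenvalue.

Significance of ``sigma2_a > 0`` uses the likelihood-ratio test against
the boundary null with the 50:50 chi2(0)/chi2(1) mixture reference;
``rho_g = 0`` is an interior hypothesis tested against chi2(1).
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceComponentsFit",
    "GeneticCorrelationFit",
    "eigendecompose",
    "reml_univariate",
    "reml_bivariate",
    "heritability_report",
]

_LOG2PI = np.log(2.0 * np.pi)
_H2_EPS = 1e-6


@dataclasses.dataclass
class VarianceComponentsFit:
    """Univariate animal-model REML fit."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    se_h2: float
    lrt_statistic: float
    p_value: float
    beta: dict[str, float]
    beta_se: dict[str, float]
    loglik: float
    converged: bool
    identifiable: bool
    n: int
    message: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class GeneticCorrelationFit:
    """Bivariate animal-model REML fit."""

    rho_g: float
    rho_e: float
    sigma2_a: tuple[float, float]
    sigma2_e: tuple[float, float]
    h2: tuple[float, float]
    se_rho_g: float
    lrt_statistic: float
    p_value: float
    loglik: float
    converged: bool
    n: int
    message: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def eigendecompose(A: np.ndarray, tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecompose a relationship matrix, validating near-PSD-ness.

    Returns eigenvalues (clipped at 0) and eigenvectors.  Raises if the
    most negative eigenvalue is materially below zero relative to the
    largest (a sign of a corrupted matrix rather than round-off).
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("A must be symmetric")
    d, U = np.linalg.eigh(A)
    if d[0] < -tol * max(d[-1], 1.0):
        raise ValueError(f"A is not positive semi-definite (min eigenvalue {d[0]:.3g})")
    return np.clip(d, 0.0, None), U


def _check_design(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if len(y) != X.shape[0]:
        raise ValueError("y and X have different numbers of rows")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    return y, X


def _univariate_restricted_ll(
    h2: float, d: np.ndarray, yr: np.ndarray, Xr: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Profile REML log-likelihood at variance ratio h2.

    Returns (loglik, sigma2_total, beta, cov_beta_unit) where the scaled
    covariance of beta is sigma2 * cov_beta_unit.
    """
    n, p = Xr.shape
    v = h2 * d + (1.0 - h2)
    v = np.clip(v, 1e-12, None)
    w = 1.0 / v
    XtWX = Xr.T @ (w[:, None] * Xr)
    XtWy = Xr.T @ (w * yr)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(np.sum(w * r * r))
    sigma2 = rss / (n - p)
    sign, logdet_m = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf, np.nan, beta, XtWX
    ll = -0.5 * (
        (n - p) * (_LOG2PI + np.log(sigma2) + 1.0)
        + float(np.sum(np.log(v)))
        + logdet_m
    )
    return ll, sigma2, beta, np.linalg.inv(XtWX)


def reml_univariate(
    y: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | None = None,
    eigen: tuple[np.ndarray, np.ndarray] | None = None,
    beta_names: Sequence[str] | None = None,
) -> VarianceComponentsFit:
    """Estimate heritability by REML on the eigen-rotated animal model.

    Parameters
    ----------
    y
        Phenotype vector (inverse-normal transformed upstream when that
        is the analysis convention).
    X
        Fixed-effect design, e.g. intercept and sex indicator.
    A
        Additive relationship matrix; alternatively pass a precomputed
        ``eigen=(values, vectors)`` to amortize the decomposition across
        many fits on the same pedigree.

    Notes
    -----
    The variance ratio is profiled on ``h2 in [0, 1]`` after rotating by
    the eigenvectors of ``A``; the standard error of ``h2`` comes from
    the numerical curvature of the restricted log-likelihood at the
    optimum, and the p-value from the boundary-corrected LRT against
    ``sigma2_a = 0`` with the 50:50 chi2(0)/chi2(1) mixture.
    """
    y, X = _check_design(y, X)
    if eigen is None:
        if A is None:
            raise ValueError("provide A or its eigendecomposition")
        eigen = eigendecompose(A)
    d, U = eigen
    n, p = X.shape
    if len(d) != n:
        raise ValueError("A and y dimensions disagree")
    yr = U.T @ y
    Xr = U.T @ X
    names = list(beta_names) if beta_names is not None else [f"b{j}" for j in range(p)]

    identifiable = float(d.max() - d.min()) > 1e-8

    def nll(h2: float) -> float:
        return -_univariate_restricted_ll(h2, d, yr, Xr)[0]

    res = optimize.minimize_scalar(
        nll, bounds=(_H2_EPS, 1.0 - _H2_EPS), method="bounded",
        options={"xatol": 1e-8},
    )
    h2_hat = float(res.x)
    ll_hat = -float(res.fun)
    ll_zero = _univariate_restricted_ll(0.0, d, yr, Xr)[0]
    ll_one = _univariate_restricted_ll(1.0 - 1e-9, d, yr, Xr)[0]
    message = ""
    if ll_zero >= ll_hat:
        h2_hat, ll_hat = 0.0, ll_zero
        message = "boundary: h2 = 0"
    elif ll_one > ll_hat:
        h2_hat, ll_hat = 1.0 - 1e-9, ll_one
        message = "boundary: h2 = 1"
    if not identifiable:
        message = "A has no eigenvalue spread; h2 not identifiable"

    ll_fn = lambda h: _univariate_restricted_ll(h, d, yr, Xr)[0]  # noqa: E731
    step = 1e-4
    h0 = float(np.clip(h2_hat, step, 1.0 - _H2_EPS - step))
    curv = (ll_fn(h0 + step) - 2.0 * ll_fn(h0) + ll_fn(h0 - step)) / step**2
    se_h2 = float(1.0 / np.sqrt(-curv)) if curv < 0 else np.nan

    lrt = max(2.0 * (ll_hat - ll_zero), 0.0)
    p_value = 1.0 if lrt <= 0.0 else float(0.5 * stats.chi2.sf(lrt, df=1))

    _, sigma2, beta, cov_unit = _univariate_restricted_ll(h2_hat, d, yr, Xr)
    beta_se = np.sqrt(np.clip(np.diag(cov_unit), 0.0, None) * sigma2)
    return VarianceComponentsFit(
        sigma2_a=float(h2_hat * sigma2),
        sigma2_e=float((1.0 - h2_hat) * sigma2),
        h2=float(h2_hat),
        se_h2=se_h2,
        lrt_statistic=float(lrt),
        p_value=p_value,
        beta=dict(zip(names, map(float, beta))),
        beta_se=dict(zip(names, map(float, beta_se))),
        loglik=float(ll_hat),
        converged=bool(res.success) and identifiable,
        identifiable=identifiable,
        n=n,
        message=message,
    )


# ---------------------------------------------------------------------------
# bivariate


def _bivariate_nll(
    theta: np.ndarray,
    d: np.ndarray,
    y1r: np.ndarray,
    y2r: np.ndarray,
    Xr: np.ndarray,
    fix_rho_g: float | None,
) -> float:
    if fix_rho_g is None:
        la1, la2, zg, le1, le2, ze = theta
        rho_g = np.tanh(zg)
    else:
        la1, la2, le1, le2, ze = theta
        rho_g = fix_rho_g
    if np.any(np.abs(theta) > 40.0):
        return np.inf
    a1, a2, e1, e2 = np.exp((la1, la2, le1, le2))
    rho_e = np.tanh(ze)
    cg = rho_g * np.sqrt(a1 * a2)
    ce = rho_e * np.sqrt(e1 * e2)

    c11 = d * a1 + e1
    c22 = d * a2 + e2
    c12 = d * cg + ce
    det = c11 * c22 - c12 * c12
    if np.any(det <= 0.0) or np.any(c11 <= 0.0):
        return np.inf
    w11 = c22 / det
    w22 = c11 / det
    w12 = -c12 / det

    n, p = Xr.shape
    B11 = Xr.T @ (w11[:, None] * Xr)
    B22 = Xr.T @ (w22[:, None] * Xr)
    B12 = Xr.T @ (w12[:, None] * Xr)
    M = np.block([[B11, B12], [B12, B22]])
    t = np.concatenate([Xr.T @ (w11 * y1r + w12 * y2r), Xr.T @ (w12 * y1r + w22 * y2r)])
    try:
        beta = np.linalg.solve(M, t)
    except np.linalg.LinAlgError:
        return np.inf
    quad = float(np.sum(w11 * y1r**2 + 2.0 * w12 * y1r * y2r + w22 * y2r**2))
    yPy = quad - float(t @ beta)
    sign, logdet_m = np.linalg.slogdet(M)
    if sign <= 0:
        return np.inf
    ll = -0.5 * (
        float(np.sum(np.log(det))) + logdet_m + yPy + (2 * n - 2 * p) * _LOG2PI
    )
    return -ll


def reml_bivariate(
    y1: np.ndarray,
    y2: np.ndarray,
    X: np.ndarray,
    A: np.ndarray | None = None,
    eigen: tuple[np.ndarray, np.ndarray] | None = None,
    compute_se: bool = True,
) -> GeneticCorrelationFit:
    """Bivariate animal model: genetic and residual correlation by REML.

    The genetic covariance of traits 1 and 2 is
    ``rho_g * sigma_a1 * sigma_a2`` (scaled by ``A``); the residual
    covariance ``rho_e * sigma_e1 * sigma_e2``.  After rotation by the
    eigenvectors of ``A`` the likelihood factors into per-eigenvalue 2x2
    blocks, so each evaluation is O(n).  Optimization is Nelder-Mead on
    log-variances and atanh-correlations, started from the univariate
    fits; the ``rho_g = 0`` p-value is a 1-df LRT against the fit with
    the genetic covariance constrained to zero.
    """
    y1, X = _check_design(y1, X)
    y2, _ = _check_design(y2, X)
    if y1.var() == 0.0 or y2.var() == 0.0:
        raise ValueError("degenerate trait with zero variance")
    if eigen is None:
        if A is None:
            raise ValueError("provide A or its eigendecomposition")
        eigen = eigendecompose(A)
    d, U = eigen
    y1r, y2r, Xr = U.T @ y1, U.T @ y2, U.T @ X
    n = len(y1)

    starts = []
    for y in (y1, y2):
        fit = reml_univariate(y, X, eigen=eigen)
        h2 = min(max(fit.h2, 0.05), 0.95)
        tot = fit.sigma2_a + fit.sigma2_e
        starts.append((np.log(h2 * tot), np.log((1 - h2) * tot)))
    r_ph = float(np.clip(np.corrcoef(y1, y2)[0, 1], -0.95, 0.95))
    z0 = np.arctanh(r_ph)

    def fit_once(fix_rho_g: float | None) -> tuple[optimize.OptimizeResult, np.ndarray]:
        if fix_rho_g is None:
            x0 = np.array([starts[0][0], starts[1][0], z0, starts[0][1], starts[1][1], z0])
        else:
            x0 = np.array([starts[0][0], starts[1][0], starts[0][1], starts[1][1], z0])
        res = optimize.minimize(
            _bivariate_nll,
            x0,
            args=(d, y1r, y2r, Xr, fix_rho_g),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-7, "fatol": 1e-9},
        )
        return res, res.x

    res_full, theta = fit_once(None)
    res_null, _ = fit_once(0.0)
    ll_full = -float(res_full.fun)
    ll_null = -float(res_null.fun)
    la1, la2, zg, le1, le2, ze = theta
    a1, a2, e1, e2 = np.exp((la1, la2, le1, le2))
    rho_g = float(np.tanh(zg))
    rho_e = float(np.tanh(ze))
    lrt = max(2.0 * (ll_full - ll_null), 0.0)
    p_value = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0

    se_rho_g = np.nan
    if compute_se:
        se_rho_g = _rho_g_se(theta, d, y1r, y2r, Xr)

    return GeneticCorrelationFit(
        rho_g=rho_g,
        rho_e=rho_e,
        sigma2_a=(float(a1), float(a2)),
        sigma2_e=(float(e1), float(e2)),
        h2=(float(a1 / (a1 + e1)), float(a2 / (a2 + e2))),
        se_rho_g=float(se_rho_g),
        lrt_statistic=float(lrt),
        p_value=p_value,
        loglik=float(ll_full),
        converged=bool(res_full.success and res_null.success),
        n=n,
        message="" if res_full.success else res_full.message,
    )


def _rho_g_se(theta, d, y1r, y2r, Xr) -> float:
    """Delta-method SE of rho_g from the numerical Hessian at the optimum."""
    k = len(theta)
    h = 1e-4
    H = np.zeros((k, k))
    f0 = _bivariate_nll(theta, d, y1r, y2r, Xr, None)
    if not np.isfinite(f0):
        return np.nan
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            fpp = _bivariate_nll(theta + ei + ej, d, y1r, y2r, Xr, None)
            fpm = _bivariate_nll(theta + ei - ej, d, y1r, y2r, Xr, None)
            fmp = _bivariate_nll(theta - ei + ej, d, y1r, y2r, Xr, None)
            fmm = _bivariate_nll(theta - ei - ej, d, y1r, y2r, Xr, None)
            if not all(np.isfinite([fpp, fpm, fmp, fmm])):
                return np.nan
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.nan
    var_z = cov[2, 2]
    if var_z <= 0:
        return np.nan
    rho = np.tanh(theta[2])
    return float(np.sqrt(var_z) * (1.0 - rho**2))


# ---------------------------------------------------------------------------
# reporting


def heritability_report(
    fits: Mapping[str, VarianceComponentsFit],
    rho_fits: Mapping[tuple[str, str], GeneticCorrelationFit] | None = None,
) -> dict:
    """Assemble fitted heritabilities and the genetic-correlation matrix.

    Returns ``{"h2_table": DataFrame, "rho_g": DataFrame}``; traits whose
    fit did not converge are marked NaN with a note rather than silently
    reported.
    """
    rows = []
    for name, fit in fits.items():
        ok = fit.converged
        rows.append(
            {
                "trait": name,
                "h2": fit.h2 if ok else np.nan,
                "se_h2": fit.se_h2 if ok else np.nan,
                "p_value": fit.p_value if ok else np.nan,
                "converged": ok,
                "note": fit.message,
            }
        )
    h2_table = pd.DataFrame(rows).set_index("trait")

    traits = list(fits)
    rho = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    if rho_fits:
        for (t1, t2), fit in rho_fits.items():
            val = fit.rho_g if fit.converged else np.nan
            rho.loc[t1, t2] = val
            rho.loc[t2, t1] = val
    return {"h2_table": h2_table, "rho_g": rho}
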