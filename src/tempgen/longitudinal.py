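"""Later-life outcome statistics: treat refusal and its stability.

Adult animals offered a treat by an unfamiliar human either take it or
refuse; infant inhibited temperament is expected to predict refusal
years later.  This module fits the logistic regression of refusal on the
temperament indicator (plus sex/age covariates) by iteratively
reweighted least squares, tests test-retest stability of the dichotomous
refusal variable with a Pearson chi-squared test on the 2x2
cross-tabulation, and summarizes the all-or-nothing character of the
task (what fraction of first-trial refusers ever retrieve a treat).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

__all__ = [
    "LogisticFit",
    "ContingencyResult",
    "SeparationError",
    "fit_logistic",
    "stability_chi2",
    "refusal_summary",
]


class SeparationError(ValueError):
    """Complete separation: the MLE does not exist."""


@dataclasses.dataclass
class LogisticFit:
    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    loglik: float
    n_iter: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.z, "p": self.p_values},
            index=self.names,
        )

    def __getitem__(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return {
            "coef": float(self.coef[i]),
            "se": float(self.se[i]),
            "z": float(self.z[i]),
            "p": float(self.p_values[i]),
        }


@dataclasses.dataclass
class ContingencyResult:
    table: np.ndarray            # 2x2 observed counts
    chi2: float
    dof: int
    p_value: float
    n: int


def _check_separation(y: np.ndarray, X: np.ndarray, names: list[str]) -> None:
    """Raise if any single predictor perfectly separates the classes."""
    for j, name in enumerate(names):
        col = X[:, j]
        if np.all(col == col[0]):
            continue
        x1, x0 = col[y == 1], col[y == 0]
        if x1.min() > x0.max() or x1.max() < x0.min():
            raise SeparationError(
                f"predictor {name!r} completely separates the outcome"
            )


def fit_logistic(
    outcome: np.ndarray | pd.Series,
    predictors: pd.DataFrame | np.ndarray,
    names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Parameters
    ----------
    outcome
        Binary 0/1 vector; both classes must be present.
    predictors
        Design columns (a DataFrame supplies the coefficient names).
    add_intercept
        Prepend a constant column named ``"intercept"``.

    Wald z statistics and two-sided normal p-values come from the inverse
    Fisher information at the MLE.  Convergence is declared when the
    relative change in log-likelihood drops below ``tol``; complete
    separation by a single predictor raises :class:`SeparationError`
    naming it, and quasi-separation that drives the fit to infinite
    coefficients is reported via ``converged=False``.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome has a single class; model undefined")
    if isinstance(predictors, pd.DataFrame):
        names = names or list(predictors.columns)
        X = predictors.to_numpy(dtype=float)
    else:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = names or [f"x{j}" for j in range(X.shape[1])]
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept", *names]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design")
    _check_separation(y, X, names)

    beta = np.zeros(X.shape[1])
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = expit(eta)
        mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
        W = mu * (1.0 - mu)
        info = X.T @ (W[:, None] * X)
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
        if abs(ll - ll_old) < tol * (abs(ll_old) + 1e-12):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    mu = np.clip(expit(X @ beta), 1e-12, 1.0 - 1e-12)
    info = X.T @ ((mu * (1.0 - mu))[:, None] * X)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    ll = float(np.sum(y * np.log(mu) + (1.0 - y) * np.log(1.0 - mu)))
    return LogisticFit(
        names=names,
        coef=beta,
        se=se,
        z=z,
        p_values=np.clip(p, np.finfo(float).tiny, 1.0),
        loglik=ll,
        n_iter=it,
        converged=converged,
    )


def stability_chi2(
    assess_a: np.ndarray | pd.Series,
    assess_b: np.ndarray | pd.Series,
    yates: bool = False,
) -> ContingencyResult:
    """Pearson chi-squared test of association between two paired binaries.

    Cross-tabulates the two assessments into a 2x2 table and computes
    ``sum (O - E)^2 / E`` with 1 degree of freedom (optional Yates
    continuity correction, off by default).  A zero marginal makes the
    statistic undefined and raises.
    """
    a = np.asarray(assess_a, dtype=int).ravel()
    b = np.asarray(assess_b, dtype=int).ravel()
    if len(a) != len(b):
        raise ValueError("assessments must be paired (equal length)")
    if not (np.all(np.isin(a, (0, 1))) and np.all(np.isin(b, (0, 1)))):
        raise ValueError("assessments must be binary 0/1")
    table = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            table[i, j] = np.sum((a == i) & (b == j))
    n = int(table.sum())
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal in the 2x2 table; statistic undefined")
    expected = np.outer(rows, cols) / n
    diff = np.abs(table - expected)
    if yates:
        diff = np.clip(diff - 0.5, 0.0, None)
    chi2 = float(np.sum(diff**2 / expected))
    return ContingencyResult(
        table=table,
        chi2=chi2,
        dof=1,
        p_value=float(stats.chi2.sf(chi2, df=1)),
        n=n,
    )


def refusal_summary(records: pd.DataFrame) -> dict:
    """Descriptive summary of refusal behavior across assessments.

    Expects columns ``animal``, ``assessment``, ``refused``,
    ``first_trial_refused`` and optionally ``inhibited``.  Reports the
    refusal proportion (by temperament group when available), the
    percentage of first-trial refusers that ever retrieved a later
    treat, and the cross-assessment consistency percentage.
    """
    if records.empty:
        raise ValueError("no refusal records")
    out: dict = {}
    first = records[records["assessment"] == records["assessment"].min()]
    out["refusal_rate"] = float(first["refused"].mean())
    if "inhibited" in records.columns:
        out["refusal_rate_by_group"] = {
            ("inhibited" if k else "not_inhibited"): float(v)
            for k, v in first.groupby("inhibited")["refused"].mean().items()
        }
    refusers = records[records["first_trial_refused"].astype(bool)]
    if len(refusers):
        later_retrieved = ~refusers["refused"].astype(bool)
        out["n_first_trial_refusers"] = int(len(refusers))
        out["n_later_retrievers"] = int(later_retrieved.sum())
        out["pct_refusers_retrieving_later"] = float(100.0 * later_retrieved.mean())
    wide = records.pivot_table(
        index="animal", columns="assessment", values="refused", aggfunc="first"
    )
    if wide.shape[1] >= 2:
        pairs = []
        cols = list(wide.columns)
        for c1, c2 in zip(cols[:-1], cols[1:]):
            both = wide[[c1, c2]].dropna()
            if len(both):
                pairs.append(float((both[c1] == both[c2]).mean()))
        if pairs:
            out["pct_consistent_between_assessments"] = float(100.0 * np.mean(pairs))
    return out
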