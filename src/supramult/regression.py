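"""Logistic-regression engine for case-control association tests.

All tests in the package (the supra-multiplicativity threshold scan, the
single-marker, dominance and interaction comparators) reduce to fitting
binomial-logit models and comparing nested fits with likelihood-ratio or
Wald statistics.  The fitter is iteratively reweighted least squares
(Fisher scoring == Newton for the canonical link) with step halving, a
relative log-likelihood convergence criterion, collinearity diagnosis that
names the offending columns, and detection of complete/quasi separation.

Separation deserves care here: a threshold scan over a 500-SNP set fits
hundreds of models, and a single degenerate cut-off must not abort the
scan.  Callers therefore get a ``separation_flag`` instead of an exception
and decide themselves (the scan keeps the finite likelihood-ratio
statistic but marks the effect estimate non-estimable; Wald inference
refuses such fits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg
from scipy.linalg.blas import dsyrk
from scipy.special import expit, logit
from scipy.stats import chi2

__all__ = [
    "CollinearityError",
    "DegeneratePhenotypeError",
    "DesignMatrix",
    "FitResult",
    "TestResult",
    "fit_logistic",
    "likelihood_ratio_test",
    "wald_test",
]

#: fitted probabilities closer than this to 0/1 count as saturated
_PROB_EPS = 1e-6
#: coefficient magnitude that, together with saturation, signals separation
_DIVERGING_COEF = 10.0
#: relative tolerance used when deciding whether a column adds rank
_RANK_RTOL = 1e-8


class DegeneratePhenotypeError(ValueError):
    """Phenotype vector contains only cases or only controls."""


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the redundant column labels."""

    def __init__(self, columns: Sequence[str], prefix: str = ""):
        self.columns = tuple(columns)
        msg = "design matrix is rank deficient; collinear columns: " + ", ".join(
            self.columns
        )
        super().__init__(prefix + msg)


@dataclass(frozen=True)
class DesignMatrix:
    """Covariate matrix with an intercept as the mandatory first column.

    Parameters
    ----------
    values : ndarray of shape (n_individuals, n_columns)
        Finite real covariate values; the first column must be all ones.
    columns : sequence of str
        Unique labels, one per column (``"intercept"`` first by convention).
    """

    values: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "columns", tuple(str(c) for c in self.columns))
        if vals.ndim != 2:
            raise ValueError("design matrix must be two-dimensional")
        if vals.shape[1] != len(self.columns):
            raise ValueError("number of column labels does not match matrix width")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("column labels must be unique")
        if not np.isfinite(vals).all():
            raise ValueError("design matrix contains non-finite values")
        if vals.shape[1] == 0 or not np.all(vals[:, 0] == 1.0):
            raise ValueError("first column must be an all-ones intercept")

    @classmethod
    def from_columns(
        cls, n_obs: int, columns: Mapping[str, np.ndarray] | None = None
    ) -> "DesignMatrix":
        """Assemble intercept + named covariate columns."""
        columns = columns or {}
        mat = np.empty((n_obs, 1 + len(columns)), dtype=np.float64)
        mat[:, 0] = 1.0
        labels = ["intercept"]
        for j, (label, col) in enumerate(columns.items(), start=1):
            mat[:, j] = np.asarray(col, dtype=np.float64)
            labels.append(label)
        return cls(mat, tuple(labels))

    def with_column(self, label: str, values: np.ndarray) -> "DesignMatrix":
        col = np.asarray(values, dtype=np.float64).reshape(-1, 1)
        return DesignMatrix(np.hstack([self.values, col]), self.columns + (label,))

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_params(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood fit of a binomial-logit model."""

    coefficients: np.ndarray
    standard_errors: np.ndarray
    log_likelihood: float
    converged: bool
    separation_flag: bool
    columns: tuple[str, ...]
    n_obs: int

    def coefficient(self, label: str) -> float:
        return float(self.coefficients[self.columns.index(label)])

    def standard_error(self, label: str) -> float:
        return float(self.standard_errors[self.columns.index(label)])


@dataclass(frozen=True)
class TestResult:
    """A chi-square test: statistic, degrees of freedom, upper-tail p."""

    __test__ = False  # not a pytest class despite the name

    statistic: float
    df: int
    p_value: float
    effect_estimate: float | None = None
    effect_se: float | None = None
    odds_ratio: float | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("test statistic must be non-negative")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # sum_i [ y_i * eta_i - log(1 + exp(eta_i)) ], numerically stable
    return float(y @ eta - np.logaddexp(0.0, eta).sum())


def _irls(
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray,
    max_iter: int,
    tol: float,
):
    """Newton iterations with step halving.

    Returns ``(beta, loglik, chol, converged, singular)`` where ``chol`` is
    the Cholesky factor of the weighted information at the last Newton step
    (None when the information matrix was singular).
    """
    beta = np.array(beta0, dtype=np.float64)
    eta = X @ beta
    ll = _loglik(eta, y)
    converged = False
    chol = None
    for _ in range(max_iter):
        p = expit(eta)
        w = p * (1.0 - p)
        np.maximum(w, 1e-12, out=w)
        Xw = X * np.sqrt(w)[:, None]
        # X^T W X via a symmetric rank-k update; only the lower triangle is
        # referenced by the Cholesky below
        info = dsyrk(1.0, Xw, trans=1, lower=1)
        grad = X.T @ (y - p)
        try:
            chol = linalg.cho_factor(info, lower=True, check_finite=False)
        except linalg.LinAlgError:
            return beta, ll, None, converged, True
        step = linalg.cho_solve(chol, grad, check_finite=False)
        cand, eta_c, ll_c = beta, eta, ll
        for _half in range(40):
            cand = beta + step
            eta_c = X @ cand
            ll_c = _loglik(eta_c, y)
            if ll_c >= ll - 1e-13:
                break
            step = 0.5 * step
        beta, eta = cand, eta_c
        if abs(ll_c - ll) <= tol * (abs(ll_c) + 1.0):
            ll = ll_c
            converged = True
            break
        ll = ll_c
    return beta, ll, chol, converged, False


def _is_separated(X: np.ndarray, beta: np.ndarray) -> bool:
    p = expit(X @ beta)
    saturated = bool((p < _PROB_EPS).any() or (p > 1.0 - _PROB_EPS).any())
    return saturated and bool(np.abs(beta).max() > _DIVERGING_COEF)


def _collinear_columns(X: np.ndarray, labels: Sequence[str]) -> tuple[str, ...]:
    """Labels of columns that do not add rank, via pivoted QR."""
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    if diag.size == 0 or diag[0] == 0.0:
        return tuple(labels)
    rank = int((diag > _RANK_RTOL * diag[0]).sum())
    return tuple(labels[j] for j in sorted(piv[rank:]))


def _covariance(X: np.ndarray, beta: np.ndarray) -> np.ndarray | None:
    p = expit(X @ beta)
    w = np.maximum(p * (1.0 - p), 1e-12)
    Xw = X * np.sqrt(w)[:, None]
    info = Xw.T @ Xw
    try:
        c = linalg.cho_factor(info, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    return linalg.cho_solve(c, np.eye(X.shape[1]), check_finite=False)


def _validate_phenotype(y, n_obs: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64).ravel()
    if y.shape[0] != n_obs:
        raise ValueError("phenotype length does not match design matrix rows")
    uniq = np.unique(y)
    if not np.isin(uniq, (0.0, 1.0)).all():
        raise ValueError("phenotype must be coded 0/1")
    if uniq.size < 2:
        which = "cases" if uniq.size and uniq[0] == 1.0 else "controls"
        raise DegeneratePhenotypeError(
            f"degenerate phenotype: sample contains only {which}"
        )
    return y


def fit_logistic(
    X: DesignMatrix,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    start: np.ndarray | None = None,
) -> FitResult:
    """Fit a binomial-logit model by IRLS.

    Parameters
    ----------
    X : DesignMatrix
    y : array of 0/1 phenotypes, both classes present
    max_iter, tol : Newton iteration cap and relative log-likelihood tolerance
    start : optional warm-start coefficient vector

    Raises
    ------
    DegeneratePhenotypeError
        if the phenotype is all-case or all-control.
    CollinearityError
        if the design matrix is rank deficient (names the redundant columns).
    """
    yv = _validate_phenotype(y, X.n_obs)
    if start is not None:
        beta0 = np.asarray(start, dtype=np.float64)
        if beta0.shape != (X.n_params,):
            raise ValueError("start vector has wrong length")
    else:
        beta0 = np.zeros(X.n_params)
        beta0[0] = logit(yv.mean())
    beta, ll, _, converged, singular = _irls(X.values, yv, beta0, max_iter, tol)
    if singular:
        bad = _collinear_columns(X.values, X.columns)
        if bad:
            raise CollinearityError(bad)
    separated = _is_separated(X.values, beta)
    cov = _covariance(X.values, beta)
    if cov is None:
        se = np.full(X.n_params, np.inf)
    else:
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        se[se == 0.0] = np.inf
    return FitResult(
        coefficients=beta,
        standard_errors=se,
        log_likelihood=ll,
        converged=converged and not singular,
        separation_flag=separated,
        columns=X.columns,
        n_obs=X.n_obs,
    )


def likelihood_ratio_test(
    null_fit: FitResult, alt_fit: FitResult, df: int
) -> TestResult:
    """LRT of two nested fits: 2*(ll_alt - ll_null) ~ chi-square(df)."""
    if int(df) != df or df <= 0:
        raise ValueError("degrees of freedom must be a positive integer")
    if alt_fit.log_likelihood < null_fit.log_likelihood - 1e-8:
        raise ValueError(
            "models do not appear nested: alternative log-likelihood below null"
        )
    stat = max(0.0, 2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood))
    return TestResult(statistic=stat, df=int(df), p_value=float(chi2.sf(stat, df)))


def wald_test(fit: FitResult, column_label: str) -> TestResult:
    """One-parameter Wald test: (coef/se)^2 ~ chi-square(1)."""
    if fit.separation_flag:
        raise ValueError("unreliable Wald: fit shows separation")
    if not fit.converged:
        raise ValueError("unreliable Wald: fit did not converge")
    coef = fit.coefficient(column_label)
    se = fit.standard_error(column_label)
    if not math.isfinite(se) or se <= 0:
        raise ValueError("unreliable Wald: standard error not positive finite")
    stat = (coef / se) ** 2
    return TestResult(
        statistic=stat,
        df=1,
        p_value=float(chi2.sf(stat, 1)),
        effect_estimate=coef,
        effect_se=se,
    )
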