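"""Elementary statistics used throughout the package.

Pearson and partial correlation, pooled-variance t-test, and the
psycholinguistic OLS regression are implemented directly (the formulas
are part of the analysis contract and must be auditable); ``scipy`` is
used only for distribution tail probabilities.

Conventions
-----------
Behavioural validity correlations (e.g. checklist score vs. correct
information units) are two-tailed by default.  Tract-damage partial
correlations are directional by hypothesis (more damage, worse score)
and default to a one-tailed test in the negative direction; pass
``alternative`` explicitly to override.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _spdist

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "pearson",
    "partial_correlation",
    "pooled_t_test",
    "psycholinguistic_regression",
    "holm_bonferroni",
    "UndefinedStatisticError",
]


class UndefinedStatisticError(ValueError):
    """Raised when a statistic is undefined (constant input, zero variance)."""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    df: int
    p: float
    tails: str  # "two" or "one"
    controlled: tuple = ()

    @property
    def t(self) -> float:
        denom = max(1.0 - self.r**2, 1e-300)
        return self.r * np.sqrt(self.df / denom)


@dataclass(frozen=True)
class RegressionResult:
    coefficients: dict = field(default_factory=dict)  # name -> (est, se, t, p)
    r_squared: float = 0.0
    f_stat: float = np.nan
    f_p: float = np.nan
    n: int = 0


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size == 0:
        raise ValueError(f"{name} is empty")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def _p_from_t(t: float, df: int, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * _spdist.t.sf(abs(t), df))
    if alternative == "greater":
        return float(_spdist.t.sf(t, df))
    if alternative == "less":
        return float(_spdist.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


def pearson(x, y, alternative: str = "two-sided") -> CorrelationResult:
    """Product-moment correlation with a t-transform p-value.

    p is computed from t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of
    freedom; ``alternative`` is one of "two-sided", "less", "greater".
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0.0 or sy == 0.0:
        raise UndefinedStatisticError("correlation undefined for constant input")
    r = float(np.sum(xc * yc) / (sx * sy))
    r = min(1.0, max(-1.0, r))
    df = n - 2
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = _p_from_t(t, df, alternative)
    tails = "two" if alternative == "two-sided" else "one"
    return CorrelationResult(r=r, n=n, df=df, p=p, tails=tails)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_correlation(x, y, covariates=None, alternative: str = "two-sided",
                        names: tuple = ()) -> CorrelationResult:
    """Correlation between x and y after residualizing both on covariates.

    Residualization is least squares with an intercept; df = n - 2 - q for
    q covariate columns.  With no covariates this is exactly :func:`pearson`.
    """
    x = _as_vector(x, "x")
    y = _as_vector(y, "y")
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if covariates is None:
        Z = np.empty((n, 0))
    else:
        Z = np.asarray(covariates, dtype=float)
        if Z.ndim == 1:
            Z = Z[:, None]
        if Z.shape[0] != n:
            raise ValueError("covariate rows must align with x/y")
    q = Z.shape[1]
    if n <= 2 + q:
        raise ValueError("need n > 2 + number of covariates")
    design = np.column_stack([np.ones(n), Z])
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    if np.sum(rx**2) < 1e-12 * max(1.0, np.sum((x - x.mean()) ** 2)) or np.sum(rx**2) < 1e-24:
        raise UndefinedStatisticError("x is collinear with the covariates")
    if np.sum(ry**2) < 1e-12 * max(1.0, np.sum((y - y.mean()) ** 2)) or np.sum(ry**2) < 1e-24:
        raise UndefinedStatisticError("y is collinear with the covariates")
    r = float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    r = min(1.0, max(-1.0, r))
    df = n - 2 - q
    t = r * np.sqrt(df / max(1.0 - r**2, 1e-300))
    p = _p_from_t(t, df, alternative)
    tails = "two" if alternative == "two-sided" else "one"
    return CorrelationResult(r=r, n=n, df=df, p=p, tails=tails,
                             controlled=tuple(names) if names else tuple(f"z{i}" for i in range(q)))


def pooled_t_test(group_a, group_b):
    """Independent two-sample Student t-test with pooled variance.

    Returns (t, df, p) with df = n_a + n_b - 2 and a two-tailed p.  The
    pooled (not Welch) form is used so that the printed degrees of
    freedom equal n_a + n_b - 2.
    """
    a = _as_vector(group_a, "group_a")
    b = _as_vector(group_b, "group_b")
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    df = na + nb - 2
    ssa = np.sum((a - a.mean()) ** 2)
    ssb = np.sum((b - b.mean()) ** 2)
    sp2 = (ssa + ssb) / df
    if sp2 <= 0.0:
        raise UndefinedStatisticError("zero pooled variance")
    t = float((a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
    p = float(2.0 * _spdist.t.sf(abs(t), df))
    return t, df, p


def psycholinguistic_regression(item_totals, checklist) -> RegressionResult:
    """OLS of summed per-item production counts on psycholinguistic covariates.

    Predictors are word class (noun=0 / verb=1), length in phonemes,
    (log) frequency and imageability, taken from the checklist.  The
    system is solved by QR on the centered design, never by normal
    equations on the raw data.
    """
    y = _as_vector(item_totals, "item_totals")
    items = checklist.items
    if y.size != len(items):
        raise ValueError("item_totals must align with checklist items")
    if y.size < 6:
        raise ValueError("need at least 6 items for the regression")
    names = ["intercept", "word_class", "length_phonemes", "frequency", "imageability"]
    X = np.column_stack([
        np.ones(y.size),
        np.array([1.0 if it.word_class == "verb" else 0.0 for it in items]),
        np.array([float(it.length_phonemes) for it in items]),
        np.array([float(it.frequency) for it in items]),
        np.array([float(it.imageability) for it in items]),
    ])
    # rank check with named offenders
    ranks = np.linalg.matrix_rank(X)
    if ranks < X.shape[1]:
        bad = []
        for j in range(1, X.shape[1]):
            keep = [c for c in range(X.shape[1]) if c != j]
            if np.linalg.matrix_rank(X[:, keep]) == ranks:
                bad.append(names[j])
        raise np.linalg.LinAlgError(f"singular design; offending columns: {bad or names[1:]}")
    Q, R = np.linalg.qr(X)
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    dof = n - k
    rss = float(np.sum(resid**2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    sigma2 = rss / dof if dof > 0 else np.nan
    XtX_inv = np.linalg.inv(R) @ np.linalg.inv(R).T
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    coeffs = {}
    for j, name in enumerate(names):
        tj = beta[j] / se[j] if se[j] > 0 else np.nan
        pj = float(2.0 * _spdist.t.sf(abs(tj), dof)) if np.isfinite(tj) else np.nan
        coeffs[name] = (float(beta[j]), float(se[j]), float(tj), pj)
    p_pred = k - 1
    if rss > 0 and dof > 0 and tss > rss:
        f = (tss - rss) / p_pred / (rss / dof)
        fp = float(_spdist.f.sf(f, p_pred, dof))
    elif tss <= rss:
        f, fp = 0.0, 1.0
    else:  # perfect fit
        f, fp = np.inf, 0.0
    return RegressionResult(coefficients=coeffs, r_squared=float(r2),
                            f_stat=float(f), f_p=fp, n=n)


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (offered as an option; analyses
    report uncorrected p by default)."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
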