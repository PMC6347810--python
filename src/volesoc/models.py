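"""Linear mixed models with one random intercept, AICc selection, Spearman.

The analysis models are Gaussian linear mixed models with a single
grid-level random intercept, fitted by maximum likelihood (not REML — the
candidate models differ in fixed effects, and only ML log-likelihoods are
comparable across them). With one grouping factor the ML fit reduces to a
one-dimensional profile over the variance ratio lambda = sigma_b^2 /
sigma_e^2: given lambda, the GLS coefficients and the residual variance
have closed forms, so the optimiser only searches lambda >= 0. This keeps
boundary fits (lambda = 0, i.e. no group variance) exact rather than a
convergence failure.

Model degrees of freedom count the fixed-effect coefficients (incl.
intercept) plus the two variance components. AICc is
-2 logL + 2 df + 2 df (df+1) / (n - df - 1).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelFit",
    "fit_lmm",
    "aicc",
    "model_selection",
    "spearman",
    "OVERLAP_CANDIDATES",
    "GROWTH_CANDIDATES",
]

# candidate fixed-effect sets for the two analyses: overlap ~ cycle phase
# and/or season; growth ~ every subset of {phase, season, overlap index}
OVERLAP_CANDIDATES = [[], ["phase"], ["season"], ["phase", "season"]]
GROWTH_CANDIDATES = [
    [], ["phase"], ["season"], ["hro"],
    ["phase", "season"], ["phase", "hro"], ["hro", "season"],
    ["phase", "hro", "season"],
]


@dataclass
class ModelFit:
    label: str
    terms: list
    coefficients: pd.Series
    sigma2_group: float
    sigma2_resid: float
    loglik: float
    df: int
    n: int
    boundary: bool = False  # group variance estimated at the 0 boundary
    aicc: float = np.nan
    delta_aicc: float = np.nan
    weight: float = np.nan


def _design_matrix(fixed: list, data: pd.DataFrame):
    """Treatment-coded design matrix with intercept; alphabetical reference."""
    cols = {"Intercept": np.ones(len(data))}
    for term in fixed:
        s = data[term]
        if s.nunique() <= 1:
            raise ValueError(f"term {term!r} is constant in the data")
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(map(str, s.unique()))
            for lev in levels[1:]:
                cols[f"{term}[{lev}]"] = (s.astype(str) == lev).astype(float).to_numpy()
        else:
            cols[term] = s.to_numpy(dtype=float)
    X = np.column_stack(list(cols.values()))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"singular design for terms {fixed}")
    return X, list(cols)


def _profile_loglik(lam: float, X, y, group_idx, group_sizes):
    """ML profile log-likelihood at variance ratio lam, with GLS by-products.

    Uses (I + lam J)^-1 = I - lam/(1 + n lam) J per group, so everything is
    group sums — no matrix bigger than p x p is formed.
    """
    n = len(y)
    shrink = lam / (1.0 + group_sizes * lam)  # per group
    Xs = np.stack([np.bincount(group_idx, weights=X[:, j], minlength=len(group_sizes))
                   for j in range(X.shape[1])], axis=1)  # group sums of X
    ys = np.bincount(group_idx, weights=y, minlength=len(group_sizes))
    XtWX = X.T @ X - (Xs * shrink[:, None]).T @ Xs
    XtWy = X.T @ y - Xs.T @ (shrink * ys)
    beta = np.linalg.solve(XtWX, XtWy)
    r = y - X @ beta
    rs = np.bincount(group_idx, weights=r, minlength=len(group_sizes))
    rWr = r @ r - shrink @ rs ** 2
    sigma2 = rWr / n
    logdet = np.sum(np.log1p(group_sizes * lam))
    ll = -0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return ll, beta, sigma2, XtWX


def fit_lmm(response: str, fixed: list, group: str, data: pd.DataFrame,
            label: str | None = None) -> ModelFit:
    """ML fit of response ~ fixed effects + (1 | group)."""
    y = data[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    codes, groups = pd.factorize(data[group])
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to estimate a random intercept")
    sizes = np.bincount(codes).astype(float)
    X, names = _design_matrix(fixed, data)

    def neg(u):
        return -_profile_loglik(np.exp(u), X, y, codes, sizes)[0]

    ll0 = _profile_loglik(0.0, X, y, codes, sizes)
    res = minimize_scalar(neg, bounds=(-12.0, 12.0), method="bounded",
                          options={"xatol": 1e-10})
    if -res.fun > ll0[0] + 1e-10:
        lam = float(np.exp(res.x))
        boundary = False
    else:
        lam, boundary = 0.0, True
    ll, beta, sigma2, _ = _profile_loglik(lam, X, y, codes, sizes)
    p = X.shape[1]
    return ModelFit(
        label=label or _label(fixed),
        terms=list(fixed),
        coefficients=pd.Series(beta, index=names),
        sigma2_group=lam * sigma2,
        sigma2_resid=sigma2,
        loglik=float(ll),
        df=p + 2,
        n=len(y),
        boundary=boundary,
    )


def _label(fixed: list) -> str:
    if not fixed:
        return "Null"
    parts = [t.upper() if t.lower() == "hro" else t.capitalize() for t in fixed]
    return " + ".join([parts[0]] + [p.lower() if p != "HRO" else p for p in parts[1:]])


def aicc(loglik: float, df: int, n: int) -> float:
    """AICc = -2 logL + 2 df + 2 df (df + 1) / (n - df - 1)."""
    if n <= df + 1:
        raise ValueError(f"AICc undefined: n={n} <= df+1={df + 1}")
    return -2.0 * loglik + 2.0 * df + 2.0 * df * (df + 1) / (n - df - 1)


def model_selection(candidates: list, response: str, group: str,
                    data: pd.DataFrame) -> pd.DataFrame:
    """Fit every candidate on identical rows; rank by AICc with weights.

    Listwise deletion over the union of all candidate variables happens
    before any fit so every AICc shares the same n. Ties keep input order.
    """
    if not candidates:
        raise ValueError("need >= 1 candidate model")
    used = sorted({t for c in candidates for t in c})
    cols = [response, group] + used
    complete = data[cols].dropna()
    if complete.empty:
        raise ValueError("no complete rows after listwise deletion")
    fits = [fit_lmm(response, c, group, complete) for c in candidates]
    for f in fits:
        f.aicc = aicc(f.loglik, f.df, f.n)
    best = min(f.aicc for f in fits)
    deltas = np.array([f.aicc - best for f in fits])
    w = np.exp(-deltas / 2.0)
    w /= w.sum()
    for f, d, wi in zip(fits, deltas, w):
        f.delta_aicc, f.weight = float(d), float(wi)
    order = sorted(range(len(fits)), key=lambda i: (fits[i].aicc, i))
    table = pd.DataFrame([
        {
            "variables": fits[i].label,
            "aicc": fits[i].aicc,
            "delta_aicc": fits[i].delta_aicc,
            "weight": fits[i].weight,
            "df": fits[i].df,
            "loglik": fits[i].loglik,
        }
        for i in order
    ])
    table.attrs["fits"] = [fits[i] for i in order]
    return table


def spearman(x, y) -> float:
    """Spearman rank correlation with mid-ranks, pairwise-complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 complete pairs")
    rx = stats.rankdata(x[ok])
    ry = stats.rankdata(y[ok])
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance")
    return float(np.corrcoef(rx, ry)[0, 1])
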