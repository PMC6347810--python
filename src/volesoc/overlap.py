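"""Home-range-overlap index from the k = sigma * sqrt(D) parameterisation.

Under a circular bivariate-normal home range, constant overlap between
neighbours means the spatial scale shrinks as density grows: sigma =
k / sqrt(D), i.e. ln sigma = ln k - (1/2) ln D. Departures from that line —
the residuals of an inverse-variance-weighted regression of ln sigma on
ln D across grid-seasons — index sociality: a positive residual means more
home-range overlap than expected at that density, a negative one less.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .data import HECTARE_M2

__all__ = ["OverlapRegression", "compute_k", "fit_overlap_regression", "overlap_index"]


@dataclass
class OverlapRegression:
    """Weighted ln sigma ~ ln D fit across grid-seasons.

    slope is the coefficient of ln D, so the constant-overlap expectation
    is -1/2. residuals are in input order, NaN where an input was missing.
    """

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    residuals: np.ndarray
    weights: np.ndarray
    n_obs: int

    def slope_ci(self, z: float = 1.96) -> tuple:
        return (self.slope - z * self.se_slope, self.slope + z * self.se_slope)


def compute_k(sigma: float, D: float) -> float:
    """Dimensionless overlap index k = sigma * sqrt(D per m^2).

    D is supplied in animals/ha and converted to animals/m^2 so that k is
    unit-stable against the metre-based sigma.
    """
    if sigma < 0 or D < 0:
        raise ValueError("sigma and D must be >= 0")
    return float(sigma * np.sqrt(D / HECTARE_M2))


def fit_overlap_regression(records, log_scale_weights: bool = False) -> OverlapRegression:
    """Inverse-variance-weighted regression of ln sigma on ln D.

    `records` is an iterable of (grid, season, sigma, SE_sigma, D) tuples or
    an equivalently-columned DataFrame. Weights are 1/SE_sigma^2 on the
    natural sigma scale by default; `log_scale_weights=True` switches to the
    delta-method weights (sigma/SE_sigma)^2 appropriate for ln sigma.
    Rows with any missing value keep their position and get NaN residuals.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame(records, columns=["grid", "season", "sigma", "se_sigma", "D"])
    sig = df["sigma"].to_numpy(dtype=float)
    se = df["se_sigma"].to_numpy(dtype=float)
    D = df["D"].to_numpy(dtype=float)
    usable = np.isfinite(sig) & np.isfinite(se) & np.isfinite(D) & (sig > 0) & (se > 0) & (D > 0)
    n = int(usable.sum())
    if n < 3:
        raise ValueError(f"need >= 3 usable records, got {n}")
    x = np.log(D[usable])
    y = np.log(sig[usable])
    if np.ptp(x) == 0:
        raise ValueError("all densities identical: regressor has zero variance")
    w = (sig[usable] / se[usable]) ** 2 if log_scale_weights else 1.0 / se[usable] ** 2
    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=w).fit()
    resid = np.full(len(df), np.nan)
    resid[usable] = fit.resid
    weights = np.full(len(df), np.nan)
    weights[usable] = w
    return OverlapRegression(
        intercept=float(fit.params[0]),
        slope=float(fit.params[1]),
        se_intercept=float(fit.bse[0]),
        se_slope=float(fit.bse[1]),
        residuals=resid,
        weights=weights,
        n_obs=n,
    )


def overlap_index(panel: pd.DataFrame, group: str = "adult_females",
                  log_scale_weights: bool = False) -> pd.DataFrame:
    """Residual overlap index per grid-season from a panel of SECR fits.

    `panel` needs columns grid, season, year and, for the requested group,
    sigma / se_sigma / D columns — suffixed `_f` for the adult-female fits
    (the territorial part of the population, the default) or unsuffixed for
    the whole population. Sessions without estimates (too few captures)
    come back with NaN residuals rather than being dropped.
    """
    if group == "adult_females":
        cols = ("sigma_f", "se_sigma_f", "D_f")
    elif group == "all":
        cols = ("sigma", "se_sigma", "D")
    else:
        raise ValueError(f"unknown group {group!r}")
    missing = [c for c in cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks columns {missing}")
    recs = pd.DataFrame({
        "grid": panel["grid"],
        "season": panel["season"],
        "sigma": panel[cols[0]],
        "se_sigma": panel[cols[1]],
        "D": panel[cols[2]],
    })
    reg = fit_overlap_regression(recs, log_scale_weights=log_scale_weights)
    out = panel[["grid", "season", "year"]].copy() if "year" in panel.columns \
        else panel[["grid", "season"]].copy()
    out["residual_overlap"] = reg.residuals
    out.attrs["regression"] = reg
    return out
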