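"""Seasons, cycle phases, MNKA trajectories and seasonal growth rates.

Seasons follow the boreal field convention: summer June-August, fall
September-November, winter December-February, spring March-May. The cycle
is split into an increase phase up to and including a configurable peak
month (default August 2014) and a crash phase after it. MNKA (minimum
number known alive) counts animals caught in a month plus those bridged by
captures before and after; seasonal growth is the density ratio
r_t = D_t / D_{t-1}.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CaptureHistory

__all__ = [
    "SEASON_OF_MONTH",
    "assign_season",
    "assign_phase",
    "season_year",
    "season_sequence",
    "filter_adult_females",
    "mnka",
    "growth_rate",
]

SEASON_OF_MONTH = {
    6: "summer", 7: "summer", 8: "summer",
    9: "fall", 10: "fall", 11: "fall",
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
}

_SEASON_ORDER = ["winter", "spring", "summer", "fall"]


def assign_season(month: int) -> str:
    if month not in SEASON_OF_MONTH:
        raise ValueError(f"month must be 1..12, got {month}")
    return SEASON_OF_MONTH[month]


def assign_phase(
    year: int, month: int,
    boundary: tuple = (2014, 8),
    span: tuple = ((2013, 6), (2015, 8)),
) -> str:
    """Increase up to and including the boundary month, crash after it."""
    if not (span[0] <= (year, month) <= span[1]):
        raise ValueError(f"({year}, {month}) outside the study span {span}")
    return "increase" if (year, month) <= tuple(boundary) else "crash"


def season_year(year: int, month: int) -> int:
    """Label winters spanning the year boundary by their December year."""
    if assign_season(month) == "winter" and month in (1, 2):
        return year - 1
    return year


def season_sequence(calendar) -> list:
    """Ordered unique (season, season_year) labels of a (year, month) list."""
    seen = []
    for year, month in calendar:
        lab = (assign_season(month), season_year(year, month))
        if lab not in seen:
            seen.append(lab)
    return seen


def filter_adult_females(capthist: CaptureHistory) -> CaptureHistory:
    """Keep only records of mature females; idempotent, structure unchanged."""
    cov = capthist.covariates
    used = set(capthist.animal_ids)
    known = set(cov["animal_id"]) if len(cov) else set()
    missing = sorted(used - known)
    if missing:
        raise ValueError(f"covariates missing for animals {missing}")
    keep = set(
        cov.loc[(cov["sex"] == "F") & cov["mature"].astype(bool), "animal_id"]
    )
    rec = capthist.records[capthist.records["animal_id"].isin(keep)].reset_index(drop=True)
    cov = cov[cov["animal_id"].isin(set(rec["animal_id"]))].reset_index(drop=True)
    return CaptureHistory(
        session_id=capthist.session_id,
        n_occasions=capthist.n_occasions,
        records=rec,
        covariates=cov,
    )


def mnka(monthly_captures: dict, n_active_traps: dict) -> pd.DataFrame:
    """Minimum number known alive per month, and per active trap.

    monthly_captures maps an ordered month key (e.g. (year, month)) to the
    set of animal ids caught that month; n_active_traps maps the same keys
    to the number of traps operating (0 = untrapped). MNKA(t) counts the
    animals caught in t plus those caught both before and after t but not
    in t — an animal known alive because its captures bracket t. Untrapped
    months still receive an MNKA (bridging sees through them) but a missing
    per-trap value, since no trapping effort existed to observe absences.
    """
    months = list(monthly_captures)
    if months != sorted(months):
        raise ValueError("months must be in increasing order")
    if any(n_active_traps.get(m, 0) < 0 for m in months):
        raise ValueError("trap counts must be >= 0")
    first_last = {}
    for t, ids in monthly_captures.items():
        for a in ids:
            lo, hi = first_last.get(a, (t, t))
            first_last[a] = (min(lo, t), max(hi, t))
    rows = []
    for t in months:
        caught = set(monthly_captures[t])
        bridged = sum(
            1 for a, (lo, hi) in first_last.items()
            if a not in caught and lo < t < hi
        )
        total = len(caught) + bridged
        ntr = n_active_traps.get(t, 0)
        rows.append({
            "month": t,
            "mnka": total,
            "n_traps": ntr,
            "mnka_per_trap": total / ntr if ntr > 0 else np.nan,
        })
    return pd.DataFrame(rows)


def growth_rate(densities) -> list:
    """Seasonal growth rates r_t = D_t / D_{t-1} for one grid.

    `densities` is the ordered per-season density series; entries may be
    NaN (inestimable seasons). The first season has no rate; a rate is
    missing when either density is missing or the denominator is zero.
    """
    d = [float(x) if x is not None else np.nan for x in densities]
    rates = [np.nan]
    for prev, cur in zip(d, d[1:]):
        if not np.isfinite(prev) or not np.isfinite(cur) or prev == 0:
            rates.append(np.nan)
        else:
            rates.append(cur / prev)
    return rates
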