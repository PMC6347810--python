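"""Synthetic trap layouts, populations and multi-catch capture histories.

The generator realises exactly the model the estimator assumes: activity
centres are a homogeneous Poisson process on a rectangle around the traps,
detection is half-normal with multi-catch competing hazards, and the
population is closed within a session. Across a multi-season panel,
populations are redrawn each month and the spatial scale follows the
constant-overlap rule sigma = k / sqrt(D), so a configured home-range
overlap level k and a density trajectory jointly determine every session.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import HECTARE_M2, CaptureHistory, DetectionParams, TrapArray
from .demography import assign_phase, assign_season, season_sequence, season_year
from .secrfit import _hazards

__all__ = [
    "make_trap_array",
    "simulate_capture_history",
    "CyclePanelConfig",
    "simulate_cycle_panel",
    "default_cycle_config",
    "sigma_from_k",
]


def make_trap_array(shape: str, n_traps: int, spacing: float, grid_id: str = "grid") -> TrapArray:
    """Build a cross or linear trapping grid.

    cross: the 16-trap field layout — a plus of two 2-trap-wide bars on a
    5x5 lattice of pitch `spacing`, spanning a (4*spacing)^2 bounding box
    (60 m x 60 m at the standard 15 m spacing). linear: n_traps collinear
    traps at `spacing`; the field used 9-12 traps where terrain forced a
    line. Nearest-neighbour distance equals `spacing` in both layouts.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if shape == "cross":
        if n_traps != 16:
            raise ValueError("cross layout has exactly 16 traps")
        lattice = np.arange(5) * spacing
        bar = {1, 2}  # the two central lattice lines forming the bars
        coords = [
            (x, y)
            for i, x in enumerate(lattice)
            for j, y in enumerate(lattice)
            if i in bar or j in bar
        ]
        coords = np.array(coords, dtype=float)
    elif shape == "linear":
        if not (9 <= n_traps <= 12):
            raise ValueError("linear layout uses 9 to 12 traps")
        coords = np.column_stack([np.arange(n_traps) * spacing, np.zeros(n_traps)])
    else:
        raise ValueError(f"unknown shape {shape!r}")
    ids = tuple(f"{grid_id}_t{i + 1:02d}" for i in range(len(coords)))
    return TrapArray(grid_id=grid_id, trap_ids=ids, coords=coords, shape=shape)


def _region_around(traps: TrapArray, sigma: float, margin: float | None = None):
    """Simulation rectangle: trap bounding box + max(4 sigma, 50 m) margin.

    Beyond ~4 sigma half-normal detection is negligible, so the rectangle
    captures effectively every detectable animal while matching the 50 m
    buffer scale of the estimation mask.
    """
    m = max(4.0 * sigma, 50.0) if margin is None else margin
    xmin, ymin, xmax, ymax = traps.bounding_box()
    return xmin - m, ymin - m, xmax + m, ymax + m


def simulate_capture_history(
    params: DetectionParams,
    traps: TrapArray,
    n_occasions: int,
    seed,
    region: tuple | None = None,
    session_id: str | None = None,
    p_female: float = 0.5,
    p_mature: float = 0.7,
    month: int = 6,
) -> CaptureHistory:
    """Simulate one closed-population multi-catch session.

    N ~ Poisson(D * area) activity centres are placed uniformly on `region`
    (default: trap box + max(4 sigma, 50 m)); each occasion every animal
    independently enters one trap or none with the competing-hazard
    probabilities. Sex and maturity are independent Bernoulli draws; mass is
    a normal draw centred higher for matures. Reproducible given `seed`.
    """
    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    rng = np.random.default_rng(seed)
    region = _region_around(traps, params.sigma) if region is None else tuple(region)
    sid = session_id or f"{traps.grid_id}_sim"
    centres, cov = _draw_population(rng, params.D, region, traps, sid,
                                    p_female=p_female, p_mature=p_mature, month=month)
    rec = _capture_records(centres, traps, params.g0, params.sigma, n_occasions,
                           rng, cov["animal_id"].to_numpy(), occasion_offset=0)
    caught = set(rec["animal_id"])
    cov = cov[cov["animal_id"].isin(caught)].reset_index(drop=True)
    return CaptureHistory(session_id=sid, n_occasions=n_occasions, records=rec, covariates=cov)


def _draw_population(rng, D, region, traps, id_prefix,
                     p_female=0.5, p_mature=0.7, month=6):
    """Poisson number of uniform activity centres plus animal covariates."""
    xmin, ymin, xmax, ymax = region
    bx = traps.bounding_box()
    if not (xmin < bx[0] and ymin < bx[1] and xmax > bx[2] and ymax > bx[3]):
        raise ValueError("region must contain all traps with a positive margin")
    area_m2 = (xmax - xmin) * (ymax - ymin)
    n = rng.poisson(D / HECTARE_M2 * area_m2)
    centres = np.column_stack([
        rng.uniform(xmin, xmax, n),
        rng.uniform(ymin, ymax, n),
    ])
    ids = np.array([f"{id_prefix}_a{i + 1:03d}" for i in range(n)])
    female = rng.random(n) < p_female
    mature = rng.random(n) < p_mature
    mass = np.round(rng.normal(np.where(mature, 22.0, 14.0), 2.5), 1)
    cov = pd.DataFrame({
        "animal_id": ids,
        "sex": np.where(female, "F", "M"),
        "mature": mature,
        "mass_g": mass,
        "first_month": month,
    })
    return centres, cov


def _capture_records(centres, traps, g0, sigma, n_occasions, rng, ids,
                     occasion_offset=0):
    """Multi-catch capture draws for fixed activity centres.

    Each animal independently enters one trap or none per occasion with the
    competing-hazard probabilities; occasions are numbered from
    occasion_offset + 1.
    """
    records = []
    if len(centres) and g0 > 0:
        h = _hazards(centres, traps, g0, sigma)  # (N, K)
        H = h.sum(axis=1)
        p_none = np.exp(-H)
        for i in range(len(centres)):
            if H[i] == 0:
                continue
            probs = np.concatenate([(h[i] / H[i]) * (1.0 - p_none[i]), [p_none[i]]])
            draws = rng.choice(traps.n_traps + 1, size=n_occasions, p=probs)
            for occ, k in enumerate(draws, start=occasion_offset + 1):
                if k < traps.n_traps:
                    records.append((ids[i], occ, traps.trap_ids[k]))
    return pd.DataFrame(records, columns=["animal_id", "occasion", "trap_id"])


def sigma_from_k(k: float, D: float) -> float:
    """Invert the constant-overlap rule: sigma = k / sqrt(D per m^2)."""
    if k <= 0:
        raise ValueError("k must be > 0")
    if D <= 0:
        raise ValueError("sigma undefined at zero density")
    return float(k / np.sqrt(D / HECTARE_M2))


@dataclass
class CyclePanelConfig:
    """Scenario for a multi-grid, multi-month cycle panel.

    Densities (animals/ha) are looked up by (phase, season); the overlap
    level k by phase. Grid-to-grid heterogeneity multiplies density by a
    lognormal factor (sd `grid_density_sd` on the log scale) and k by an
    independent lognormal factor (sd `grid_k_sd`). `calendar` is an ordered
    list of (year, month, active); inactive months produce no session, and
    months with density 0 produce no animals.
    """

    grids: list  # list of TrapArray
    calendar: list  # [(year, month, active: bool), ...]
    density_levels: dict  # {(phase, season): D per ha}
    k_levels: dict  # {phase: k}
    g0: float = 0.2
    n_occasions: int = 6
    sigma_max: float = 30.0  # home-range ceiling: sigma = min(k/sqrt(D), sigma_max)
    seed: int = 0
    phase_boundary: tuple = (2014, 8)
    study_span: tuple = ((2013, 6), (2015, 8))
    grid_density_sd: float = 0.25
    grid_k_sd: float = 0.0
    p_female: float = 0.5
    p_mature: float = 0.7

    def __post_init__(self):
        ym = [(y, m) for y, m, _ in self.calendar]
        if any(b <= a for a, b in zip(ym, ym[1:])):
            raise ValueError("calendar must be strictly increasing")
        if any(d < 0 for d in self.density_levels.values()):
            raise ValueError("density levels must be >= 0")
        if any(k <= 0 for k in self.k_levels.values()):
            raise ValueError("k levels must be > 0")


def default_cycle_config(
    n_grids: int = 24,
    seed: int = 0,
    k_increase: float = 0.6,
    k_crash: float = 0.3,
) -> CyclePanelConfig:
    """Illustrative demo scenario shaped like the field study.

    24 grids by default (every 5th one linear with 9-12 traps, the rest
    16-trap crosses), monthly sessions June 2013 - August 2015 with
    September 2014 missing, a two-phase cycle (increase through August
    2014, crash after), summer densities above winter, and an
    increase-phase overlap level k above the crash-phase level. The
    numbers are package defaults for demonstrations, not estimates of any
    real population.
    """
    grids = []
    for i in range(n_grids):
        gid = f"g{i + 1:02d}"
        if (i + 1) % 5 == 0:
            grids.append(make_trap_array("linear", 9 + (i // 5) % 4, 15.0, grid_id=gid))
        else:
            grids.append(make_trap_array("cross", 16, 15.0, grid_id=gid))
    calendar = []
    y, m = 2013, 6
    while (y, m) <= (2015, 8):
        calendar.append((y, m, not (y == 2014 and m == 9)))
        m += 1
        if m > 12:
            y, m = y + 1, 1
    # cycle shape: density is still high in the first crash fall, then
    # collapses over winter to effective extinction by the last summer, so
    # late-crash sessions become inestimable just as the field data did
    density_levels = {
        ("increase", "summer"): 25.0,
        ("increase", "fall"): 18.0,
        ("increase", "winter"): 10.0,
        ("increase", "spring"): 14.0,
        ("crash", "fall"): 16.0,
        ("crash", "winter"): 4.0,
        ("crash", "spring"): 0.6,
        ("crash", "summer"): 0.3,
    }
    return CyclePanelConfig(
        grids=grids,
        calendar=calendar,
        density_levels=density_levels,
        k_levels={"increase": k_increase, "crash": k_crash},
        grid_k_sd=0.1,
        seed=seed,
    )


def _stream_seed(master_seed: int, grid_index: int, tag: int) -> int:
    """Independent, reproducible sub-stream keyed by the master seed.

    One stream per (grid, month) and per (grid, season) population draw, so
    panels are reproducible and single months re-simulable in isolation.
    """
    ss = np.random.SeedSequence([int(master_seed), int(grid_index), int(tag)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def simulate_cycle_panel(config: CyclePanelConfig) -> dict:
    """Simulate every (grid, year, month) session of a cycle scenario.

    Returns {(grid_id, year, month): CaptureHistory}, omitting inactive
    months. The population is closed within each 3-month season: activity
    centres (and animal covariates) are drawn once per grid-season from the
    season's density level and persist across the season's months, so
    pooling a season's monthly sessions yields genuine across-month
    recaptures. Populations are redrawn at season boundaries (demographic
    turnover). sigma follows the phase-level overlap rule
    sigma = k / sqrt(D); zero-density months yield an empty CaptureHistory.
    """
    rng = np.random.default_rng(config.seed)
    d_mult = np.exp(rng.normal(0.0, config.grid_density_sd, len(config.grids)))
    k_mult = np.exp(rng.normal(0.0, config.grid_k_sd, len(config.grids)))
    months_by_season = {}
    for year, month, active in config.calendar:
        lab = (assign_season(month), season_year(year, month))
        months_by_season.setdefault(lab, []).append((year, month, active))
    panel = {}
    for gi, traps in enumerate(config.grids):
        for si, lab in enumerate(season_sequence([(y, m) for y, m, _ in config.calendar])):
            season, syear = lab
            months = months_by_season[lab]
            y0, m0, _ = months[0]
            phase = assign_phase(y0, m0, boundary=config.phase_boundary,
                                 span=config.study_span)
            D = config.density_levels.get((phase, season), 0.0) * d_mult[gi]
            if D <= 0:
                for year, month, active in months:
                    if active:
                        panel[(traps.grid_id, year, month)] = CaptureHistory(
                            session_id=f"{traps.grid_id}_{year}_{month:02d}",
                            n_occasions=config.n_occasions,
                            records=pd.DataFrame(columns=["animal_id", "occasion", "trap_id"]),
                        )
                continue
            k = config.k_levels[phase] * k_mult[gi]
            # sigma follows constant overlap until the home-range ceiling:
            # space use cannot expand without bound as density collapses
            sigma = min(sigma_from_k(k, D), config.sigma_max)
            pop_rng = np.random.default_rng(
                _stream_seed(config.seed, gi, 10_000 + si))
            centres, cov = _draw_population(
                pop_rng, D, _region_around(traps, sigma), traps,
                f"{traps.grid_id}_{season}{syear}",
                p_female=config.p_female, p_mature=config.p_mature, month=m0)
            ids = cov["animal_id"].to_numpy()
            for year, month, active in months:
                if not active:
                    continue
                mrng = np.random.default_rng(
                    _stream_seed(config.seed, gi, year * 100 + month))
                rec = _capture_records(centres, traps, config.g0, sigma,
                                       config.n_occasions, mrng, ids)
                caught = set(rec["animal_id"])
                panel[(traps.grid_id, year, month)] = CaptureHistory(
                    session_id=f"{traps.grid_id}_{year}_{month:02d}",
                    n_occasions=config.n_occasions,
                    records=rec,
                    covariates=cov[cov["animal_id"].isin(caught)].reset_index(drop=True),
                )
    return panel
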