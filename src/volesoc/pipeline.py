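"""File I/O, configuration and the end-to-end analysis pipeline.

Chains simulation (or reading of trap/capture files), season-level SECR
fits, the residual home-range-overlap index, MNKA trajectories, seasonal
growth rates, AICc model selection and the overlap-growth correlation, and
writes every stage as CSV plus a JSON run manifest.

File dialects (all plain CSV with headers):
  traps:      trap_id,x,y              coordinates in metres
  captures:   session,animal_id,occasion,trap_id    occasions 1-based
  covariates: animal_id,sex,mature,mass_g,first_month
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import CaptureHistory, TrapArray
from .demography import (assign_phase, assign_season, filter_adult_females,
                         growth_rate, mnka, season_sequence, season_year)
from .models import GROWTH_CANDIDATES, OVERLAP_CANDIDATES, model_selection, spearman
from .overlap import overlap_index
from .secrfit import InestimableSessionError, build_mask, fit_secr
from .simulate import CyclePanelConfig, default_cycle_config, simulate_cycle_panel

log = logging.getLogger("volesoc")

__all__ = [
    "PipelineConfig",
    "read_trap_file",
    "write_trap_file",
    "read_capture_file",
    "write_capture_file",
    "pool_season_sessions",
    "fit_sessions",
    "run_pipeline",
]

FIT_COLUMNS = [
    "session", "grid", "season", "year", "group", "n_animals",
    "D", "SE_D", "g0", "SE_g0", "sigma", "SE_sigma",
    "loglik", "converged", "effective_area_ha",
]


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; defaults match the field protocol.

    Detection is half-normal with a 50 m habitat-mask buffer; sessions are
    pooled to season level; the overlap index is fitted on adult females.
    """

    output_dir: str = "volesoc_out"
    trap_files: list = field(default_factory=list)
    capture_file: str | None = None
    covariate_file: str | None = None
    buffer: float = 50.0
    mask_spacing: float = 5.0
    min_animals: int = 5  # SECR fits on fewer captured animals are unreliable
    group: str = "adult_females"
    phase_boundary: tuple = (2014, 8)
    study_span: tuple = ((2013, 6), (2015, 8))
    log_scale_weights: bool = False
    seed: int = 1
    scenario: CyclePanelConfig | None = None

    def __post_init__(self):
        if self.buffer <= 0 or self.mask_spacing <= 0:
            raise ValueError("buffer and mask_spacing must be > 0")


def read_trap_file(path) -> TrapArray:
    """Read one trap-layout CSV (trap_id,x,y) into a TrapArray."""
    path = Path(path)
    df = pd.read_csv(path, skipinitialspace=True)
    required = {"trap_id", "x", "y"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns trap_id,x,y")
    if df.empty:
        raise ValueError(f"{path}: no trap rows")
    dup = df["trap_id"].astype(str).duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ValueError(
            f"{path}: duplicate trap id {df['trap_id'].iloc[i]!r} at line {i + 2}"
        )
    try:
        coords = df[["x", "y"]].to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric coordinate ({e})") from None
    # "g01.traps.csv" and "g01.csv" both name grid g01
    return TrapArray(grid_id=path.stem.split(".")[0],
                     trap_ids=tuple(df["trap_id"].astype(str)), coords=coords)


def write_trap_file(traps: TrapArray, path) -> None:
    df = pd.DataFrame({
        "trap_id": traps.trap_ids,
        "x": traps.coords[:, 0],
        "y": traps.coords[:, 1],
    })
    df.to_csv(path, index=False)


def read_capture_file(path, covariate_path=None, traps_by_grid: dict | None = None,
                      n_occasions: int | None = None,
                      keep_first_on_conflict: bool = False) -> dict:
    """Read a capture CSV into {session_id: CaptureHistory}.

    A multi-catch violation (one animal, two traps, one occasion) is an
    error unless `keep_first_on_conflict`, which keeps the first record.
    If `traps_by_grid` maps grid ids (the session prefix before the first
    '_') to TrapArrays, trap references are validated against them.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    required = {"session", "animal_id", "occasion", "trap_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns session,animal_id,occasion,trap_id")
    cov = None
    if covariate_path is not None:
        cov = pd.read_csv(covariate_path, skipinitialspace=True)
    sessions = {}
    for sid, block in df.groupby("session", sort=True):
        rec = block[["animal_id", "occasion", "trap_id"]].copy()
        dup = rec.duplicated(subset=["animal_id", "occasion"])
        if dup.any():
            if keep_first_on_conflict:
                rec = rec[~dup]
            else:
                bad = rec.loc[dup].iloc[0]
                raise ValueError(
                    f"{path}: session {sid!r}: animal {bad['animal_id']!r} in two "
                    f"traps on occasion {bad['occasion']} (pass keep_first_on_conflict to repair)"
                )
        nocc = n_occasions or int(rec["occasion"].max())
        scov = None
        if cov is not None:
            scov = cov[cov["animal_id"].isin(set(rec["animal_id"]))]
        hist = CaptureHistory(session_id=str(sid), n_occasions=nocc, records=rec,
                              covariates=scov if scov is not None else pd.DataFrame(
                                  columns=["animal_id", "sex", "mature", "mass_g", "first_month"]))
        if traps_by_grid is not None:
            grid = str(sid).rsplit("_", 2)[0]  # "<grid>_<year>_<month>"
            if grid not in traps_by_grid:
                raise ValueError(f"{path}: session {sid!r} references unknown grid {grid!r}")
            hist.validate_traps(traps_by_grid[grid])
        sessions[str(sid)] = hist
    return sessions


def write_capture_file(histories, path, covariate_path=None) -> None:
    """Write CaptureHistory objects to the capture (and covariate) dialect."""
    recs, covs = [], []
    for h in histories:
        r = h.records.copy()
        r.insert(0, "session", h.session_id)
        recs.append(r)
        covs.append(h.covariates)
    pd.concat(recs, ignore_index=True).to_csv(path, index=False)
    if covariate_path is not None:
        cov = pd.concat(covs, ignore_index=True).drop_duplicates(subset="animal_id")
        cov.to_csv(covariate_path, index=False)


def pool_season_sessions(month_histories, session_id: str) -> CaptureHistory:
    """Pool one grid's monthly histories of a season into one closed session.

    Occasions are concatenated in calendar order (total S = sum of monthly
    occasions); animal identities carry across months, so across-month
    recaptures survive pooling.
    """
    parts, covs = [], []
    offset = 0
    for h in month_histories:
        r = h.records.copy()
        r["occasion"] = r["occasion"] + offset
        parts.append(r)
        covs.append(h.covariates)
        offset += h.n_occasions
    rec = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["animal_id", "occasion", "trap_id"])
    cov = pd.concat(covs, ignore_index=True).drop_duplicates(subset="animal_id") \
        if covs else pd.DataFrame(columns=["animal_id", "sex", "mature", "mass_g", "first_month"])
    return CaptureHistory(session_id=session_id, n_occasions=offset,
                          records=rec, covariates=cov)


def _fit_row(hist, traps, mask, session, grid, season, year, group,
             min_animals=5):
    base = {"session": session, "grid": grid, "season": season, "year": year,
            "group": group, "n_animals": hist.n_animals if hist is not None else 0}
    nan = dict(D=np.nan, SE_D=np.nan, g0=np.nan, SE_g0=np.nan,
               sigma=np.nan, SE_sigma=np.nan, loglik=np.nan,
               converged=False, effective_area_ha=np.nan)
    if hist is None or hist.n_animals < min_animals:
        log.info("session %s (%s): too few captures, recorded as inestimable",
                 session, group)
        return {**base, **nan}
    try:
        fit = fit_secr(hist, traps, mask)
    except InestimableSessionError:
        return {**base, **nan}
    if not fit.converged or fit.estimates is None:
        log.warning("session %s (%s): SECR fit did not converge", session, group)
        return {**base, **nan}
    e = fit.estimates
    return {**base, "D": e.D, "SE_D": fit.se[0], "g0": e.g0, "SE_g0": fit.se[1],
            "sigma": e.sigma, "SE_sigma": fit.se[2], "loglik": fit.loglik,
            "converged": True, "effective_area_ha": fit.effective_area_ha}


def fit_sessions(panel_hists: dict, traps_by_grid: dict, config: PipelineConfig):
    """Season-level SECR fits for every grid: whole population and adult females.

    panel_hists is the simulate_cycle_panel mapping {(grid, year, month):
    CaptureHistory}. Returns (fits DataFrame in FIT_COLUMNS, panel
    DataFrame with one row per grid-season). Inestimable or non-converged
    sessions keep their row with missing estimates — no silent drops.
    """
    months_by_gs = {}
    for (grid, year, month), hist in sorted(panel_hists.items()):
        lab = (assign_season(month), season_year(year, month))
        months_by_gs.setdefault((grid, lab), []).append((year, month, hist))
    masks = {g: build_mask(t, config.buffer, config.mask_spacing)
             for g, t in traps_by_grid.items()}
    fit_rows, panel_rows = [], []
    for (grid, (season, syear)), months in sorted(months_by_gs.items()):
        months.sort(key=lambda t: (t[0], t[1]))
        y0, m0, _ = months[0]
        phase = assign_phase(y0, m0, boundary=config.phase_boundary,
                             span=config.study_span)
        session = f"{grid}_{season}_{syear}"
        pooled = pool_season_sessions([h for _, _, h in months], session)
        traps = traps_by_grid[grid]
        row_all = _fit_row(pooled, traps, masks[grid], session, grid, season,
                           syear, "all", min_animals=config.min_animals)
        females = filter_adult_females(pooled)
        row_f = _fit_row(females, traps, masks[grid], session, grid, season,
                         syear, "adult_females", min_animals=config.min_animals)
        fit_rows += [row_all, row_f]
        panel_rows.append({
            "grid": grid, "season": season, "year": syear, "phase": phase,
            "n_animals": row_all["n_animals"], "D": row_all["D"],
            "SE_D": row_all["SE_D"], "sigma": row_all["sigma"],
            "SE_sigma": row_all["SE_sigma"],
            "n_females": row_f["n_animals"], "D_f": row_f["D"],
            "SE_D_f": row_f["SE_D"], "sigma_f": row_f["sigma"],
            "se_sigma_f": row_f["SE_sigma"],
        })
    fits = pd.DataFrame(fit_rows, columns=FIT_COLUMNS)
    panel = pd.DataFrame(panel_rows)
    return fits, panel


def _season_sort_key(calendar):
    order = {lab: i for i, lab in enumerate(season_sequence(calendar))}

    def key(row):
        return order.get((row["season"], row["year"]), len(order))

    return key


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write all output tables.

    Stages: simulate (or read) capture data; season-level SECR fits for the
    whole population and for adult females; residual overlap index; MNKA;
    seasonal growth rates; AICc selection tables for the overlap and growth
    models; Spearman correlation of seasonal mean overlap and growth.
    Deterministic given config.seed. Returns the result bundle as a dict of
    DataFrames / scalars; writes CSVs + manifest.json under output_dir.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.scenario is not None:
        scenario = config.scenario
    elif config.capture_file is None:
        scenario = default_cycle_config(seed=config.seed)
    else:
        scenario = None

    if scenario is not None:
        log.info("simulating cycle panel: %d grids, %d calendar months",
                 len(scenario.grids), len(scenario.calendar))
        panel_hists = simulate_cycle_panel(scenario)
        traps_by_grid = {t.grid_id: t for t in scenario.grids}
        calendar = [(y, m) for y, m, a in scenario.calendar]
        active = {(y, m): a for y, m, a in scenario.calendar}
    else:
        traps_by_grid = {}
        for tf in config.trap_files:
            t = read_trap_file(tf)
            traps_by_grid[t.grid_id] = t
        sessions = read_capture_file(config.capture_file, config.covariate_file,
                                     traps_by_grid=traps_by_grid)
        panel_hists = {}
        for sid, h in sessions.items():
            grid, year, month = sid.rsplit("_", 2)
            panel_hists[(grid, int(year), int(month))] = h
        months = sorted({(y, m) for _, y, m in panel_hists})
        calendar = months
        active = {ym: True for ym in months}

    # --- SECR fits and analysis panel -------------------------------------
    fits, panel = fit_sessions(panel_hists, traps_by_grid, config)

    # --- residual overlap index (adult females by default) ----------------
    ovl = overlap_index(panel, group=config.group,
                        log_scale_weights=config.log_scale_weights)
    panel["residual_overlap"] = ovl["residual_overlap"].to_numpy()
    reg = ovl.attrs["regression"]

    # --- MNKA -------------------------------------------------------------
    mnka_rows = []
    for grid, traps in sorted(traps_by_grid.items()):
        caps = {}
        ntraps = {}
        for (y, m) in calendar:
            hist = panel_hists.get((grid, y, m))
            caps[(y, m)] = set(hist.animal_ids) if hist is not None else set()
            ntraps[(y, m)] = traps.n_traps if active.get((y, m), False) else 0
        tab = mnka(caps, ntraps)
        tab.insert(0, "grid", grid)
        tab["year"] = [ym[0] for ym in tab["month"]]
        tab["month"] = [ym[1] for ym in tab["month"]]
        mnka_rows.append(tab[["grid", "year", "month", "mnka", "n_traps", "mnka_per_trap"]])
    mnka_table = pd.concat(mnka_rows, ignore_index=True)

    # --- seasonal growth rates (whole-population density) ------------------
    key = _season_sort_key(calendar)
    panel = panel.sort_values(["grid"], kind="stable")
    panel["_order"] = [key(r) for _, r in panel.iterrows()]
    panel = panel.sort_values(["grid", "_order"], kind="stable").drop(columns="_order")
    panel["growth_rate"] = np.nan
    for grid, block in panel.groupby("grid", sort=False):
        panel.loc[block.index, "growth_rate"] = growth_rate(block["D"].tolist())
    panel = panel.reset_index(drop=True)

    # --- model selection ---------------------------------------------------
    mdata = panel.rename(columns={"residual_overlap": "overlap", "growth_rate": "growth"})
    mdata["hro"] = mdata["overlap"]
    sel_overlap = model_selection(OVERLAP_CANDIDATES, "overlap", "grid", mdata)
    sel_growth = model_selection(GROWTH_CANDIDATES, "growth", "grid", mdata)

    # --- overlap vs growth correlation (seasonal means) --------------------
    seasonal = mdata.groupby(["season", "year"], as_index=False).agg(
        overlap=("overlap", "mean"), growth=("growth", "mean"))
    try:
        rho = spearman(seasonal["overlap"], seasonal["growth"])
    except ValueError:
        rho = np.nan

    # --- outputs ------------------------------------------------------------
    fits.to_csv(out / "fits.csv", index=False)
    ovl_out = panel[["grid", "season", "year", "phase", "n_females",
                     "sigma_f", "se_sigma_f", "D_f", "residual_overlap"]]
    ovl_out.to_csv(out / "overlap.csv", index=False)
    mnka_table.to_csv(out / "mnka.csv", index=False)
    panel.to_csv(out / "panel.csv", index=False)
    sel_overlap.to_csv(out / "selection_overlap.csv", index=False)
    sel_growth.to_csv(out / "selection_growth.csv", index=False)
    manifest = {
        "package": "volesoc",
        "version": __version__,
        "seed": int(config.seed),
        "buffer_m": config.buffer,
        "mask_spacing_m": config.mask_spacing,
        "group": config.group,
        "phase_boundary": list(config.phase_boundary),
        "overlap_regression": {
            "intercept": reg.intercept, "slope": reg.slope,
            "se_slope": reg.se_slope, "n_obs": reg.n_obs,
        },
        "spearman_overlap_growth": None if not np.isfinite(rho) else rho,
        "n_sessions": int(len(panel)),
        "simulated": scenario is not None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("pipeline complete: %d grid-seasons, slope %.3f, rho %s",
             len(panel), reg.slope, f"{rho:.2f}" if np.isfinite(rho) else "NA")
    return {
        "fits": fits,
        "panel": panel,
        "overlap": ovl_out,
        "overlap_regression": reg,
        "mnka": mnka_table,
        "selection_overlap": sel_overlap,
        "selection_growth": sel_growth,
        "spearman": rho,
        "manifest": manifest,
    }
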