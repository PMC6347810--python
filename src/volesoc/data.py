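"""Core data containers shared across the package.

Coordinates are planar metres (no geographic projection). Densities are
animals per hectare unless a name says otherwise; occasions are 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HECTARE_M2 = 10_000.0

CAPTURE_COLUMNS = ["animal_id", "occasion", "trap_id"]
COVARIATE_COLUMNS = ["animal_id", "sex", "mature", "mass_g", "first_month"]


@dataclass(frozen=True)
class TrapArray:
    """Geometry of one trapping grid: trap identifiers and planar coordinates.

    Parameters
    ----------
    grid_id : str
        Identifier of the trapping grid.
    trap_ids : tuple of str
        Unique trap identifiers, ordered.
    coords : ndarray of shape (n_traps, 2)
        Trap x/y coordinates in metres.
    shape : {"cross", "linear"}
        Layout family the grid belongs to.
    """

    grid_id: str
    trap_ids: tuple
    coords: np.ndarray
    shape: str = "cross"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "trap_ids", tuple(str(t) for t in self.trap_ids))
        if len(self.trap_ids) != len(set(self.trap_ids)):
            raise ValueError("trap ids must be unique")
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must have shape (n_traps, 2)")
        if coords.shape[0] != len(self.trap_ids):
            raise ValueError("coords and trap_ids length mismatch")
        if coords.shape[0] < 2:
            raise ValueError("a trap array needs at least 2 traps")
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if np.any(d <= 0):
            raise ValueError("all pairwise trap distances must be > 0")

    @property
    def n_traps(self) -> int:
        return len(self.trap_ids)

    def index_of(self, trap_id: str) -> int:
        try:
            return self.trap_ids.index(str(trap_id))
        except ValueError:
            raise KeyError(f"unknown trap id {trap_id!r} on grid {self.grid_id!r}")

    def bounding_box(self):
        """(xmin, ymin, xmax, ymax) of the trap coordinates."""
        return (
            float(self.coords[:, 0].min()),
            float(self.coords[:, 1].min()),
            float(self.coords[:, 0].max()),
            float(self.coords[:, 1].max()),
        )


@dataclass(frozen=True)
class DetectionParams:
    """Half-normal detection parameters plus density.

    D : animals per hectare (>= 0)
    g0 : per-occasion capture probability at distance zero, in [0, 1)
    sigma : spatial scale of detection, metres (> 0)
    """

    D: float
    g0: float
    sigma: float

    def __post_init__(self):
        if self.D < 0:
            raise ValueError("density D must be >= 0")
        if not (0 <= self.g0 < 1):
            raise ValueError("g0 must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def density_per_m2(self) -> float:
        return self.D / HECTARE_M2


@dataclass
class CaptureHistory:
    """Multi-catch capture records for one session (grid x season or month).

    records has columns animal_id, occasion (1-based), trap_id; covariates
    has one row per animal with sex ('F'/'M'), mature (bool), mass_g and
    first_month. An animal occupies at most one trap per occasion.
    """

    session_id: str
    n_occasions: int
    records: pd.DataFrame
    covariates: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=COVARIATE_COLUMNS))

    def __post_init__(self):
        if self.n_occasions < 1:
            raise ValueError("n_occasions must be >= 1")
        rec = pd.DataFrame(self.records, columns=CAPTURE_COLUMNS).reset_index(drop=True)
        rec["occasion"] = rec["occasion"].astype(int)
        self.records = rec
        if len(rec):
            if rec["occasion"].min() < 1 or rec["occasion"].max() > self.n_occasions:
                raise ValueError("occasion outside 1..n_occasions")
            dup = rec.duplicated(subset=["animal_id", "occasion"])
            if dup.any():
                bad = rec.loc[dup, "animal_id"].unique()
                raise ValueError(
                    f"multi-catch violation: animals {list(bad)} recorded twice in one occasion"
                )
        self.covariates = pd.DataFrame(self.covariates).reset_index(drop=True)

    @property
    def animal_ids(self) -> list:
        return list(pd.unique(self.records["animal_id"]))

    @property
    def n_animals(self) -> int:
        return self.records["animal_id"].nunique()

    def validate_traps(self, traps: TrapArray) -> None:
        known = set(traps.trap_ids)
        unknown = set(map(str, self.records["trap_id"])) - known
        if unknown:
            raise ValueError(f"records reference unknown traps {sorted(unknown)}")

    def capture_counts(self, traps: TrapArray):
        """Per-animal capture counts by trap.

        Returns (animal_ids, counts) where counts[i, k] is how many occasions
        animal i was caught in trap k. Occasions are exchangeable under the
        closed-population model, so these counts are sufficient for the
        likelihood.
        """
        self.validate_traps(traps)
        ids = self.animal_ids
        idx = {a: i for i, a in enumerate(ids)}
        counts = np.zeros((len(ids), traps.n_traps), dtype=int)
        for a, t in zip(self.records["animal_id"], self.records["trap_id"]):
            counts[idx[a], traps.index_of(t)] += 1
        return ids, counts
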