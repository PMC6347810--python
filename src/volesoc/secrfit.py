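"""Spatially explicit capture-recapture (SECR) engine.

Implements the closed-population multi-catch SECR model with a half-normal
detection function and a Poisson prior on the number of activity centres.
Density D (animals/ha), baseline detection g0 and the spatial scale sigma
(m) are estimated by maximising the full likelihood over a habitat mask,
with standard errors from the observed information on the transformed
(ln D, logit g0, ln sigma) scale.

The half-normal detection function is g(d) = g0 * exp(-d^2 / (2 sigma^2)).
With multi-catch traps the animal, not the trap, is the competing unit:
per occasion an animal with per-trap hazards h_k = -ln(1 - g(d_k)) enters
trap k with probability (h_k / H) (1 - e^-H), H = sum h_k, or no trap with
probability e^-H.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .data import HECTARE_M2, CaptureHistory, DetectionParams, TrapArray

__all__ = [
    "HabitatMask",
    "SECRFit",
    "build_mask",
    "halfnormal",
    "occasion_capture_probs",
    "history_prob",
    "effective_area",
    "neg_log_likelihood",
    "fit_secr",
]


class InestimableSessionError(ValueError):
    """Raised when a session carries no capture information.

    The conditional part of the likelihood is undefined with zero captured
    animals; callers should record the session as missing rather than fit it.
    """


@dataclass(frozen=True)
class HabitatMask:
    """Lattice of candidate activity-centre locations around the traps.

    points : (M, 2) array of lattice coordinates, metres
    spacing : lattice pitch, metres; each point represents spacing^2 m^2
    buffer : the maximum distance of a mask point to its nearest trap
    """

    points: np.ndarray
    spacing: float
    buffer: float

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, dtype=float))
        if self.points.ndim != 2 or self.points.shape[1] != 2 or not len(self.points):
            raise ValueError("mask needs >= 1 point with x,y columns")
        if self.spacing <= 0:
            raise ValueError("mask spacing must be > 0")

    @property
    def cell_area(self) -> float:
        """Area represented by one mask point, m^2."""
        return self.spacing ** 2

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def area_ha(self) -> float:
        return self.n_points * self.cell_area / HECTARE_M2


@dataclass
class SECRFit:
    """Maximum-likelihood SECR estimates for one session."""

    estimates: DetectionParams | None
    se: tuple  # (SE_D, SE_g0, SE_sigma) on the natural scale
    loglik: float
    converged: bool
    n_animals: int
    effective_area_ha: float
    message: str = ""


def build_mask(traps: TrapArray, buffer: float = 50.0, spacing: float = 5.0) -> HabitatMask:
    """Construct the habitat mask: a square lattice clipped to the buffer.

    The lattice has pitch `spacing`, is aligned to the trap bounding-box
    origin, and retains every point whose distance to the nearest trap is
    at most `buffer`. Deterministic: no randomness, stable point order.
    """
    if buffer <= 0:
        raise ValueError("buffer must be > 0")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    xmin, ymin, xmax, ymax = traps.bounding_box()
    xs = np.arange(xmin - buffer, xmax + buffer + spacing / 2, spacing)
    ys = np.arange(ymin - buffer, ymax + buffer + spacing / 2, spacing)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    d2 = ((pts[:, None, :] - traps.coords[None, :, :]) ** 2).sum(axis=-1)
    keep = d2.min(axis=1) <= buffer ** 2 + 1e-9
    return HabitatMask(points=pts[keep], spacing=float(spacing), buffer=float(buffer))


def halfnormal(d, g0: float, sigma: float):
    """Half-normal detection: g(d) = g0 exp(-d^2 / (2 sigma^2))."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    if not (0 <= g0 < 1):
        raise ValueError("g0 must lie in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    out = g0 * np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    return out if out.shape else float(out)


def _hazards(centres: np.ndarray, traps: TrapArray, g0: float, sigma: float) -> np.ndarray:
    """Per-trap capture hazards h_k = -ln(1 - g(d_k)) for each centre.

    centres: (M, 2); returns (M, K).
    """
    d2 = ((centres[:, None, :] - traps.coords[None, :, :]) ** 2).sum(axis=-1)
    g = g0 * np.exp(-d2 / (2.0 * sigma ** 2))
    if np.any(g >= 1.0):
        raise ValueError("capture probability reached 1; invalid g0")
    return -np.log1p(-g)


def occasion_capture_probs(centre, traps: TrapArray, g0: float, sigma: float):
    """Single-occasion multi-catch probabilities for one activity centre.

    Returns (p, p_none) with p the per-trap capture probabilities
    p_k = (h_k / H) (1 - e^-H) and p_none = e^-H; they sum to 1 exactly.
    """
    if not (0 <= g0 < 1):
        raise ValueError("g0 must lie in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    centre = np.asarray(centre, dtype=float).reshape(1, 2)
    h = _hazards(centre, traps, g0, sigma)[0]
    H = h.sum()
    if H == 0.0:
        return np.zeros_like(h), 1.0
    p_none = float(np.exp(-H))
    p = (h / H) * (1.0 - p_none)
    return p, p_none


def history_prob(history, centre, traps: TrapArray, g0: float, sigma: float) -> float:
    """Probability of one animal's capture history given its activity centre.

    `history` is a sequence over occasions whose entries are a trap_id or
    None (not caught). Occasions are independent, so the probability is the
    product of the per-occasion terms.
    """
    p, p_none = occasion_capture_probs(centre, traps, g0, sigma)
    prob = 1.0
    for entry in history:
        if entry is None:
            prob *= p_none
        else:
            prob *= p[traps.index_of(entry)]
    return float(prob)


def effective_area(
    g0: float, sigma: float, traps: TrapArray, mask: HabitatMask, n_occasions: int
) -> float:
    """Effective sampling area a(theta) in hectares.

    The mask Riemann sum of the probability of being caught at least once
    over n_occasions: a = sum_m (1 - exp(-S * H(X_m))) * cell_area / 1e4.
    Converts the expected count of detected animals into a density.
    """
    if mask.n_points == 0:
        raise ValueError("empty mask")
    H = _hazards(mask.points, traps, g0, sigma).sum(axis=1)
    p_seen = -np.expm1(-n_occasions * H)
    return float(p_seen.sum() * mask.cell_area / HECTARE_M2)


def _hazards_from_d2(d2: np.ndarray, g0: float, sigma: float) -> np.ndarray:
    g = g0 * np.exp(-d2 / (2.0 * sigma ** 2))
    if np.any(g >= 1.0):
        raise ValueError("capture probability reached 1; invalid g0")
    return -np.log1p(-g)


def _nll_core(D, g0, sigma, counts, n_occasions, d2, cell_area):
    """Negative full log-likelihood from precomputed sufficient statistics.

    counts[i, k]: occasions animal i was caught in trap k; d2: squared
    mask-to-trap distances (M, K); cell_area in m^2. Shared by the public
    neg_log_likelihood and the optimiser loop in fit_secr (which hoists
    counts and d2 out of the objective).
    """
    h = _hazards_from_d2(d2, g0, sigma)
    H = h.sum(axis=1)
    logp = _log_conditional_from_hazards(counts, n_occasions, h, H)
    Dm = D / HECTARE_M2
    mmax = logp.max(axis=1)
    log_integral = mmax + np.log(np.exp(logp - mmax[:, None]).sum(axis=1)) \
        + np.log(cell_area)
    a_m2 = float((-np.expm1(-n_occasions * H)).sum() * cell_area)
    loglik = np.sum(np.log(Dm) + log_integral) - Dm * a_m2
    return float(-loglik)


def _log_conditional_from_hazards(counts, n_occasions, h, H):
    """log P(omega_i | centre X_m) for every animal i and mask point m."""
    with np.errstate(divide="ignore", invalid="ignore"):
        # -1e30 stands in for log 0 where h == 0: a capture there is
        # impossible and scores (essentially) -inf without poisoning 0 * log 0
        log_pk = np.where(
            h > 0,
            np.log(np.where(h > 0, h, 1.0)) - np.log(H[:, None])
            + np.log(-np.expm1(-H))[:, None],
            -1e30,
        )
    n_caught = counts.sum(axis=1)  # per animal
    logp = counts @ log_pk.T  # (n_animals, M)
    logp += np.outer(n_occasions - n_caught, -H)
    return logp


def _squared_distances(mask: HabitatMask, traps: TrapArray) -> np.ndarray:
    return ((mask.points[:, None, :] - traps.coords[None, :, :]) ** 2).sum(axis=-1)


def neg_log_likelihood(
    params: DetectionParams,
    capthist: CaptureHistory,
    traps: TrapArray,
    mask: HabitatMask,
) -> float:
    """Negative log of the full (Poisson-N) SECR likelihood.

    With density per m^2 Dm, mask cell area c and a(theta) in m^2:
        -[ sum_i ln( Dm * sum_m P(omega_i | X_m) * c ) - Dm * a(theta) ]
    The additive -ln(n!) constant is omitted (parameter-free).
    """
    if capthist.n_animals == 0:
        raise InestimableSessionError(
            f"session {capthist.session_id!r} has no captured animals; skip it"
        )
    _, counts = capthist.capture_counts(traps)
    return _nll_core(params.D, params.g0, params.sigma, counts,
                     capthist.n_occasions, _squared_distances(mask, traps),
                     mask.cell_area)


def _auto_start(capthist: CaptureHistory, traps: TrapArray, mask: HabitatMask) -> DetectionParams:
    """Data-driven start values: strictly interior and scale-free."""
    ids, counts = capthist.capture_counts(traps)
    # mean displacement among distinct traps per recaptured animal
    disps = []
    for row in counts:
        k = np.flatnonzero(row)
        if len(k) > 1:
            d = np.linalg.norm(
                traps.coords[k][:, None, :] - traps.coords[k][None, :, :], axis=-1
            )
            disps.append(d[np.triu_indices(len(k), 1)].mean())
    sigma0 = 0.5 * (np.mean(disps) if disps else mask.spacing) + mask.spacing
    D0 = max(len(ids) / mask.area_ha, 1e-3)
    return DetectionParams(D=D0, g0=0.1, sigma=float(sigma0))


def _transform(p: DetectionParams) -> np.ndarray:
    return np.array([np.log(p.D), logit(p.g0), np.log(p.sigma)])


def _untransform(x: np.ndarray) -> DetectionParams:
    return DetectionParams(D=float(np.exp(x[0])), g0=float(expit(x[1])), sigma=float(np.exp(x[2])))


def _hessian_central(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = step
            ej = np.zeros(n); ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step ** 2)
    return H


def fit_secr(
    capthist: CaptureHistory,
    traps: TrapArray,
    mask: HabitatMask,
    start: DetectionParams | None = None,
) -> SECRFit:
    """Fit the half-normal multi-catch SECR model by maximum likelihood.

    Optimisation is on the transformed scale (ln D, logit g0, ln sigma);
    standard errors come from the inverse observed information there and are
    delta-method back-transformed. Non-convergence or a non-positive-definite
    Hessian is reported via `converged=False`, never silently.
    """
    if capthist.n_animals == 0:
        raise InestimableSessionError(
            f"session {capthist.session_id!r} has no captured animals"
        )
    if capthist.n_occasions < 2:
        warnings.warn("fewer than 2 occasions: parameters weakly identified")
    _, counts = capthist.capture_counts(traps)
    # single animal always caught in one trap gives a flat sigma direction
    if capthist.n_animals == 1 and (counts[0] > 0).sum() <= 1:
        return SECRFit(
            estimates=None, se=(np.nan,) * 3, loglik=np.nan, converged=False,
            n_animals=1, effective_area_ha=np.nan,
            message="inestimable: one animal, one trap",
        )
    if start is None:
        start = _auto_start(capthist, traps, mask)
    d2 = _squared_distances(mask, traps)
    S = capthist.n_occasions
    cell = mask.cell_area

    def nll_t(x):
        if np.any(np.abs(x) > 50):
            return 1e12
        try:
            p = _untransform(x)
            return _nll_core(p.D, p.g0, p.sigma, counts, S, d2, cell)
        except (ValueError, FloatingPointError):
            return 1e12

    x0 = _transform(start)
    res = minimize(nll_t, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000})
    res2 = minimize(nll_t, res.x, method="BFGS",
                    options={"gtol": 1e-8, "maxiter": 200})
    if res2.fun <= res.fun:
        res = res2
    xhat = res.x
    est = _untransform(xhat)
    H = _hessian_central(nll_t, xhat)
    se = (np.nan, np.nan, np.nan)
    hess_ok = False
    try:
        eigvals = np.linalg.eigvalsh(H)
        if np.all(eigvals > 0):
            cov = np.linalg.inv(H)
            sd = np.sqrt(np.diag(cov))
            se = (
                est.D * sd[0],                      # d D / d lnD = D
                est.g0 * (1 - est.g0) * sd[1],      # d g0 / d logit = g0(1-g0)
                est.sigma * sd[2],
            )
            hess_ok = True
    except np.linalg.LinAlgError:
        pass
    converged = bool(res.fun < 1e11) and hess_ok
    a_ha = effective_area(est.g0, est.sigma, traps, mask, capthist.n_occasions)
    return SECRFit(
        estimates=est,
        se=se,
        loglik=float(-res.fun),
        converged=converged,
        n_animals=capthist.n_animals,
        effective_area_ha=a_ha,
        message="" if converged else "optimizer or Hessian failure",
    )
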