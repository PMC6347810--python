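"""SECR engine: mask, detection model, likelihood and fitting."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from volesoc import DetectionParams, build_mask, make_trap_array
from volesoc.data import CaptureHistory, TrapArray
from volesoc.secrfit import (InestimableSessionError, effective_area, fit_secr,
                             halfnormal, history_prob, neg_log_likelihood,
                             occasion_capture_probs)

# independent fine-lattice (1 m) quadrature of a(theta) for the cross grid at
# g0=0.2, sigma=15 m, 18 occasions, 50 m buffer — frozen before the engine
# was used, see the quadrature in test_effective_area_fine_lattice_golden
A_THETA_GOLDEN_HA = 1.179820


def _nll_oracle(params, caught_trap_idx, traps, mask_pts, cell, n_occasions=1):
    """Term-by-term pure-Python evaluation of the toy likelihood."""
    Dm = params.D / 1e4
    tot = 0.0
    a_m2 = 0.0
    for mx, my in mask_pts:
        hs = []
        for tx, ty in traps.coords:
            d = math.hypot(mx - tx, my - ty)
            g = params.g0 * math.exp(-d * d / (2 * params.sigma ** 2))
            hs.append(-math.log(1 - g))
        H = sum(hs)
        p = hs[caught_trap_idx] / H * (1 - math.exp(-H))
        tot += p * math.exp(-(n_occasions - 1) * H)
        a_m2 += (1 - math.exp(-n_occasions * H)) * cell
    return -(math.log(Dm * tot * cell) - Dm * a_m2)


class TestMask:
    def test_single_trap_matches_brute_force(self):
        traps = TrapArray("one", ("t1", "t2"),
                         np.array([[0.0, 0.0], [0.0, 1e-6]]))
        # effectively a single trap at the origin; brute-force count of
        # 50 m-pitch lattice points within 50 m of it
        mask = build_mask(traps, buffer=50.0, spacing=50.0)
        xs = np.arange(-50.0, 101.0, 50.0)
        brute = sum(
            1 for x in xs for y in xs if math.hypot(x - 0, y - 0) <= 50 + 1e-9
        )
        assert mask.n_points == brute

    def test_all_points_within_buffer(self, cross_traps):
        mask = build_mask(cross_traps, buffer=50.0, spacing=7.0)
        d = np.linalg.norm(
            mask.points[:, None, :] - cross_traps.coords[None], axis=-1
        ).min(axis=1)
        assert d.max() <= 50.0 + 1e-6

    def test_finer_mask_changes_likelihood_little(self, toy_fixture):
        params, hist, traps, _ = toy_fixture
        coarse = build_mask(traps, buffer=50.0, spacing=10.0)
        fine = build_mask(traps, buffer=50.0, spacing=5.0)
        v1 = neg_log_likelihood(params, hist, traps, coarse)
        v2 = neg_log_likelihood(params, hist, traps, fine)
        assert abs(v1 - v2) < 0.5

    @pytest.mark.parametrize("buffer,spacing", [(0.0, 5.0), (-1.0, 5.0), (50.0, 0.0)])
    def test_invalid_geometry_rejected(self, cross_traps, buffer, spacing):
        with pytest.raises(ValueError):
            build_mask(cross_traps, buffer=buffer, spacing=spacing)


class TestDetection:
    def test_halfnormal_closed_forms(self):
        assert halfnormal(0.0, 0.2, 15.0) == pytest.approx(0.2)
        assert halfnormal(15.0, 0.2, 15.0) == pytest.approx(0.2 * math.exp(-0.5))
        assert halfnormal(150.0, 0.2, 15.0) < 1e-21 * 0.2

    def test_halfnormal_strictly_decreasing(self):
        d = np.linspace(0, 100, 200)
        g = halfnormal(d, 0.3, 12.0)
        assert np.all(np.diff(g) < 0)

    @pytest.mark.parametrize("d,g0,sigma", [(-1, 0.2, 15), (1, 1.0, 15), (1, 0.2, 0)])
    def test_halfnormal_domain_errors(self, d, g0, sigma):
        with pytest.raises(ValueError):
            halfnormal(d, g0, sigma)

    def test_single_trap_collapses_to_halfnormal(self):
        traps = TrapArray("t", ("t1", "far"),
                         np.array([[0.0, 0.0], [1e6, 1e6]]))
        p, p_none = occasion_capture_probs((20.0, 0.0), traps, 0.2, 15.0)
        assert p[0] == pytest.approx(halfnormal(20.0, 0.2, 15.0), rel=1e-12)

    def test_equidistant_two_traps_symmetry(self):
        traps = TrapArray("t", ("a", "b"), np.array([[0.0, 0.0], [30.0, 0.0]]))
        p, p_none = occasion_capture_probs((15.0, 0.0), traps, 0.2, 15.0)
        # hand evaluation: d = 15 to both traps
        g = 0.2 * math.exp(-0.5)
        h = -math.log(1 - g)
        H = 2 * h
        expected = 0.5 * (1 - math.exp(-H))
        assert p[0] == pytest.approx(p[1], rel=1e-14)
        assert p[0] == pytest.approx(expected, rel=1e-12)
        assert p_none + p.sum() == pytest.approx(1.0, abs=1e-14)

    def test_g0_zero_means_no_capture(self, cross_traps):
        p, p_none = occasion_capture_probs((30.0, 30.0), cross_traps, 0.0, 15.0)
        assert p_none == 1.0 and np.all(p == 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        x=st.floats(-100, 160), y=st.floats(-100, 160),
        g0=st.floats(0.001, 0.95), sigma=st.floats(1.0, 60.0),
    )
    def test_normalization_property(self, cross_traps, x, y, g0, sigma):
        p, p_none = occasion_capture_probs((x, y), cross_traps, g0, sigma)
        assert p_none + p.sum() == pytest.approx(1.0, abs=1e-12)


class TestHistoryProb:
    def test_all_empty_history(self, cross_traps):
        centre = (30.0, 30.0)
        p, p_none = occasion_capture_probs(centre, cross_traps, 0.2, 15.0)
        S = 5
        assert history_prob([None] * S, centre, cross_traps, 0.2, 15.0) == \
            pytest.approx(p_none ** S, rel=1e-12)

    def test_caught_then_missed_is_product(self, cross_traps):
        centre = (10.0, 25.0)
        tid = cross_traps.trap_ids[3]
        p, p_none = occasion_capture_probs(centre, cross_traps, 0.2, 15.0)
        got = history_prob([tid, None], centre, cross_traps, 0.2, 15.0)
        assert got == pytest.approx(p[3] * p_none, rel=1e-12)

    def test_unknown_trap_rejected(self, cross_traps):
        with pytest.raises(KeyError):
            history_prob(["nope"], (0, 0), cross_traps, 0.2, 15.0)


class TestEffectiveArea:
    def test_zero_detection_zero_area(self, cross_traps, cross_mask):
        assert effective_area(0.0, 15.0, cross_traps, cross_mask, 18) == 0.0

    def test_saturates_at_mask_area(self, cross_traps, cross_mask):
        a = effective_area(0.5, 30.0, cross_traps, cross_mask, 10_000)
        assert a == pytest.approx(cross_mask.area_ha, rel=1e-6)

    def test_fine_lattice_golden(self, cross_traps, cross_mask):
        a = effective_area(0.2, 15.0, cross_traps, cross_mask, 18)
        # 5 m mask Riemann sum vs the frozen 1 m quadrature: agree to 0.1%
        assert a == pytest.approx(A_THETA_GOLDEN_HA, rel=1e-3)

    def test_monotone_in_each_argument(self, cross_traps, cross_mask):
        base = effective_area(0.2, 15.0, cross_traps, cross_mask, 6)
        assert effective_area(0.3, 15.0, cross_traps, cross_mask, 6) >= base
        assert effective_area(0.2, 20.0, cross_traps, cross_mask, 6) >= base
        assert effective_area(0.2, 15.0, cross_traps, cross_mask, 12) >= base
        bigger = build_mask(cross_traps, buffer=90.0, spacing=5.0)
        assert effective_area(0.2, 15.0, cross_traps, bigger, 6) >= base


class TestLikelihood:
    def test_toy_fixture_term_by_term(self, toy_fixture):
        params, hist, traps, mask = toy_fixture
        got = neg_log_likelihood(params, hist, traps, mask)
        want = _nll_oracle(params, 0, traps, mask.points, mask.cell_area)
        assert got == pytest.approx(want, abs=1e-10)
        assert got == pytest.approx(3.189363847382, abs=1e-9)

    def test_permutation_invariance(self, toy_fixture):
        params, hist, traps, mask = toy_fixture
        v = neg_log_likelihood(params, hist, traps, mask)
        from volesoc.secrfit import HabitatMask
        perm = HabitatMask(points=mask.points[::-1], spacing=mask.spacing,
                           buffer=mask.buffer)
        assert neg_log_likelihood(params, hist, traps, perm) == \
            pytest.approx(v, abs=1e-10)

    def test_animal_order_invariance(self, cross_traps, coarse_mask, std_params):
        from volesoc import simulate_capture_history
        hist = simulate_capture_history(std_params, cross_traps, 6, seed=7)
        rev = CaptureHistory(hist.session_id, hist.n_occasions,
                             hist.records.iloc[::-1], hist.covariates)
        v1 = neg_log_likelihood(std_params, hist, cross_traps, coarse_mask)
        v2 = neg_log_likelihood(std_params, rev, cross_traps, coarse_mask)
        assert v1 == pytest.approx(v2, abs=1e-10)

    def test_buffer_truncation_negligible(self, toy_fixture):
        params, hist, traps, _ = toy_fixture
        m50 = build_mask(traps, buffer=50.0, spacing=5.0)
        m100 = build_mask(traps, buffer=100.0, spacing=5.0)
        v1 = neg_log_likelihood(params, hist, traps, m50)
        v2 = neg_log_likelihood(params, hist, traps, m100)
        # the entire change is the exp(-d^2/2 sigma^2) tail beyond 50 m
        # (~3.3 sigma), of order D/1e4 * ~1 m^2 here
        assert abs(v1 - v2) < 2e-3

    def test_zero_captures_is_explicit_error(self, cross_traps, cross_mask, std_params):
        empty = CaptureHistory("e", 6, pd.DataFrame(
            columns=["animal_id", "occasion", "trap_id"]))
        with pytest.raises(InestimableSessionError):
            neg_log_likelihood(std_params, empty, cross_traps, cross_mask)


class TestFit:
    def test_profile_density_closed_form(self, cross_traps, coarse_mask, std_params):
        """With g0, sigma fixed at truth the Poisson factor is maximised
        analytically at D = n / a(theta)."""
        from scipy.optimize import minimize_scalar
        from volesoc import simulate_capture_history
        hist = simulate_capture_history(std_params, cross_traps, 18, seed=11)
        a = effective_area(std_params.g0, std_params.sigma, cross_traps,
                           coarse_mask, 18)
        res = minimize_scalar(
            lambda lnD: neg_log_likelihood(
                DetectionParams(np.exp(lnD), std_params.g0, std_params.sigma),
                hist, cross_traps, coarse_mask),
            bounds=(-3, 6), method="bounded", options={"xatol": 1e-10},
        )
        assert np.exp(res.x) == pytest.approx(hist.n_animals / a, rel=1e-5)

    def test_optimum_beats_coarse_grid_and_is_local_max(
            self, cross_traps, coarse_mask, std_params):
        from volesoc import simulate_capture_history
        hist = simulate_capture_history(std_params, cross_traps, 18, seed=5)
        fit = fit_secr(hist, cross_traps, coarse_mask)
        assert fit.converged
        # independent coarse grid search over the 3-D parameter lattice
        best = np.inf
        for D in (2.0, 5.0, 10.0, 20.0, 40.0):
            for g0 in (0.05, 0.1, 0.2, 0.4):
                for sigma in (7.5, 15.0, 30.0):
                    v = neg_log_likelihood(DetectionParams(D, g0, sigma),
                                           hist, cross_traps, coarse_mask)
                    best = min(best, v)
        assert -fit.loglik <= best + 1e-8
        # small perturbations around the optimum never improve the fit
        e = fit.estimates
        for f in (0.97, 1.03):
            for which in range(3):
                vals = [e.D, e.g0, e.sigma]
                vals[which] *= f
                v = neg_log_likelihood(DetectionParams(*vals), hist,
                                       cross_traps, coarse_mask)
                assert v >= -fit.loglik - 1e-6

    def test_loglik_matches_nll_at_estimates(self, cross_traps, coarse_mask, std_params):
        from volesoc import simulate_capture_history
        hist = simulate_capture_history(std_params, cross_traps, 18, seed=5)
        fit = fit_secr(hist, cross_traps, coarse_mask)
        v = neg_log_likelihood(fit.estimates, hist, cross_traps, coarse_mask)
        assert fit.loglik == pytest.approx(-v, abs=1e-8)

    def test_buffer_sufficiency(self, cross_traps, std_params):
        """50 m vs 90 m buffer at sigma = 15 m changes density by < 1%."""
        from volesoc import simulate_capture_history
        hist = simulate_capture_history(std_params, cross_traps, 18, seed=42)
        assert hist.n_animals >= 10  # enough data for sigma-hat near truth
        f50 = fit_secr(hist, cross_traps, build_mask(cross_traps, 50.0, 10.0))
        f90 = fit_secr(hist, cross_traps, build_mask(cross_traps, 90.0, 10.0))
        assert abs(f50.estimates.sigma - 15.0) < 3.0
        assert f50.estimates.D == pytest.approx(f90.estimates.D, rel=0.01)

    def test_single_animal_single_trap_inestimable(self, cross_traps, cross_mask):
        hist = CaptureHistory("s", 6, pd.DataFrame(
            {"animal_id": ["a"] * 3, "occasion": [1, 2, 3],
             "trap_id": [cross_traps.trap_ids[0]] * 3}))
        fit = fit_secr(hist, cross_traps, cross_mask)
        assert not fit.converged and fit.estimates is None
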