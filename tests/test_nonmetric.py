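"""Monotone disparities, stress-1, penalized stress, distance smoothing."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from minkmds.metrics import Configuration
from minkmds.nonmetric import (
    DegenerateConfigurationError,
    isotonic_fit_vector,
    monotone_disparities,
    penalized_stress,
    smooth_abs,
    smooth_abs_grad,
    smoothed_pair_distances,
    stress1,
    StressValue,
)


def brute_force_isotonic(y):
    """Least-squares monotone fit by exhaustive search over consecutive-block
    partitions (each candidate is blockwise means; monotone ones compete)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    best, best_sse = None, np.inf
    for cuts in itertools.product([0, 1], repeat=n - 1):
        bounds = [0] + [i + 1 for i, c in enumerate(cuts) if c] + [n]
        fit = np.concatenate(
            [np.full(b - a, y[a:b].mean()) for a, b in zip(bounds, bounds[1:])]
        )
        if np.all(np.diff(fit) >= -1e-12):
            sse = float(np.sum((fit - y) ** 2))
            if sse < best_sse - 1e-12:
                best, best_sse = fit, sse
    return best


def _to_matrix(vec, n):
    m = np.zeros((n, n))
    m[np.triu_indices(n, 1)] = vec
    return m + m.T


class TestMonotoneDisparities:
    def test_pava_hand_example(self):
        # order (1,2,3) with distances (3,1,2): pool (3,1) -> (2,2), monotone
        out, _, deg = isotonic_fit_vector(np.array([1.0, 2.0, 3.0]), np.array([3.0, 1.0, 2.0]))
        assert out == pytest.approx([2.0, 2.0, 2.0])
        assert deg  # constant fitted disparities trip the collapsed-solution guard

    def test_already_monotone_unchanged(self):
        out, _, _ = isotonic_fit_vector(np.array([1.0, 2.0, 3.0]), np.array([0.5, 1.0, 4.0]))
        assert out == pytest.approx([0.5, 1.0, 4.0])

    def test_constant_distances_constant_fit(self):
        out, _, _ = isotonic_fit_vector(np.array([1.0, 2.0, 3.0]), np.array([2.0, 2.0, 2.0]))
        assert out == pytest.approx([2.0, 2.0, 2.0])

    def test_all_tied_dissimilarities_flagged_degenerate(self):
        out, _, deg = isotonic_fit_vector(np.array([5.0, 5.0, 5.0]), np.array([1.0, 2.0, 9.0]))
        assert deg
        assert out == pytest.approx([4.0, 4.0, 4.0])

    @given(st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=6))
    def test_matches_brute_force_enumeration(self, dist):
        dist = np.array(dist)
        dissim = np.arange(1.0, dist.size + 1)  # strictly increasing, no ties
        out, _, _ = isotonic_fit_vector(dissim, dist)
        assert out == pytest.approx(brute_force_isotonic(dist), abs=1e-8)

    def test_weak_monotonicity_with_ties_both_policies(self):
        rng = np.random.default_rng(5)
        n = 6
        dissim = _to_matrix(rng.integers(1, 5, size=15).astype(float), n)
        dist = _to_matrix(rng.uniform(0, 3, size=15), n)
        for ties in ("primary", "secondary"):
            disp = monotone_disparities(dissim, dist, ties=ties)
            iu = np.triu_indices(n, 1)
            dvec, ovec = dissim[iu], disp.values[iu]
            for i in range(len(dvec)):
                for j in range(len(dvec)):
                    if dvec[i] < dvec[j]:
                        assert ovec[i] <= ovec[j] + 1e-9
            if ties == "secondary":
                for i in range(len(dvec)):
                    for j in range(len(dvec)):
                        if dvec[i] == dvec[j]:
                            assert ovec[i] == pytest.approx(ovec[j])


class TestStress1:
    def test_perfect_fit_zero(self):
        m = _to_matrix(np.array([1.0, 2.0, 3.0]), 3)
        assert stress1(m, m) == 0.0

    def test_hand_value_sqrt_two_fifths(self):
        n = 3
        # only two informative pairs; the third is zero in both matrices
        disp = _to_matrix(np.array([1.0, 2.0, 0.0]), n)
        dist = _to_matrix(np.array([2.0, 1.0, 0.0]), n)
        assert stress1(disp, dist) == pytest.approx(math.sqrt(2.0 / 5.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        disp = _to_matrix(rng.uniform(0, 2, 10), 5)
        dist = _to_matrix(rng.uniform(0.1, 2, 10), 5)
        s = stress1(disp, dist)
        assert stress1(3.7 * disp, 3.7 * dist) == pytest.approx(s)

    def test_all_zero_distances_degenerate(self):
        z = np.zeros((4, 4))
        with pytest.raises(DegenerateConfigurationError):
            stress1(z, z)


class TestPenalizedStress:
    @staticmethod
    def _setup():
        rng = np.random.default_rng(2)
        coords = rng.uniform(-1, 1, (6, 2))
        cfg = Configuration([f"p{i}" for i in range(6)], coords, metric_p=1.0)
        e = _to_matrix(rng.uniform(0.5, 3, 15), 6)
        r = _to_matrix(rng.uniform(0.5, 3, 15), 6)
        return cfg, e, r

    def test_lambda_zero_is_unconstrained_squared_stress(self):
        cfg, e, r = self._setup()
        base = penalized_stress(cfg, e, r, 0.0)
        alt = penalized_stress(cfg, e, 5 * r + 0 * r, 0.0)  # constraint irrelevant
        assert base.value == pytest.approx(alt.value)

    def test_composition_base_plus_lambda_penalty(self):
        cfg, e, r = self._setup()
        s0 = penalized_stress(cfg, e, r, 0.0).value
        sr = penalized_stress(cfg, r, r, 0.0).value  # squared stress against R alone
        total = penalized_stress(cfg, e, r, 100.0).value
        assert total == pytest.approx(s0 + 100.0 * sr, rel=1e-9)

    def test_perfect_monotone_reproduction_gives_zero(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(-1, 1, (6, 2))
        cfg = Configuration([f"p{i}" for i in range(6)], coords, metric_p=2.0)
        d = cfg.pairwise()
        assert penalized_stress(cfg, d, d, 100.0).value == pytest.approx(0.0, abs=1e-16)

    def test_penalized_at_least_unpenalized(self):
        cfg, e, r = self._setup()
        for lam in (0.0, 1.0, 100.0):
            assert penalized_stress(cfg, e, r, lam).value >= penalized_stress(cfg, e, r, 0.0).value - 1e-12

    def test_stress_value_invariants(self):
        with pytest.raises(ValueError):
            StressValue(-0.1)
        with pytest.raises(ValueError):
            StressValue(0.5, kind="penalized", lambda_weight=None)


class TestSmoothAbs:
    def test_outside_window_exact(self):
        assert smooth_abs(5.0, 1.0) == 5.0
        assert smooth_abs(-5.0, 1.0) == 5.0

    def test_at_zero_positive_value_zero_slope(self):
        for tau in (0.5, 1.0, 2.0):
            assert smooth_abs(0.0, tau) == pytest.approx(tau / 2.0)
            assert smooth_abs_grad(np.array([0.0]), tau)[0] == 0.0

    def test_matches_abs_in_value_and_slope_at_tau(self):
        tau = 0.8
        assert smooth_abs(tau, tau) == pytest.approx(tau)
        assert smooth_abs_grad(np.array([tau]), tau)[0] == pytest.approx(1.0)

    def test_tau_zero_is_abs(self):
        t = np.linspace(-2, 2, 41)
        assert np.array_equal(smooth_abs(t, 0.0), np.abs(t))

    def test_uniform_convergence_as_tau_shrinks(self):
        t = np.linspace(-3, 3, 601)
        sups = [np.max(np.abs(smooth_abs(t, tau) - np.abs(t))) for tau in (1.0, 0.3, 0.1, 0.01)]
        assert all(a > b for a, b in zip(sups, sups[1:]))
        assert sups[-1] < 0.01

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            smooth_abs(1.0, -0.1)

    def test_smoothed_distances_converge_to_exact(self):
        rng = np.random.default_rng(6)
        diffs = rng.normal(size=(20, 2))
        exact = smoothed_pair_distances(diffs, 1.0, 0.0)
        for tau in (0.5, 0.05, 0.005):
            err = np.max(np.abs(smoothed_pair_distances(diffs, 1.0, tau) - exact))
            assert err <= tau  # h(t) - |t| <= tau/2 per coordinate
        assert np.allclose(exact, np.abs(diffs).sum(axis=1))
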