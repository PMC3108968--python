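"""Nonmetric machinery: monotone disparities, stress-1, the weakly
constrained penalized stress, and the smoothed-distance surrogate.

Only the rank order of the dissimilarities is treated as informative.  The
disparities are the isotonic least-squares fit of the configuration distances
against that rank order (pool-adjacent-violators); badness of fit is
Kruskal's stress-1, sqrt(sum (dhat - d)^2 / sum d^2) over the upper-triangle
pairs.  The weakly constrained loss adds, with weight lambda, the squared
stress-1 of the same distances against disparities fit to an external
constraint matrix (here the country-average dissimilarities), penalizing —
without forbidding — configurations that stray from the shared structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression

from .metrics import Configuration, pairwise_distances

#: Relative spread below which a fitted disparity vector counts as collapsed.
DEGENERATE_SPREAD = 1e-6

TIE_POLICIES = ("primary", "secondary")


class DegenerateConfigurationError(ValueError):
    """All configuration distances are zero; stress is undefined."""


def _upper(mat: np.ndarray) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    mat = np.asarray(mat, dtype=float)
    n = mat.shape[0]
    iu = np.triu_indices(n, 1)
    return mat[iu], iu


def _check_conformable(a: np.ndarray, b: np.ndarray) -> None:
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"matrices must be square and conformable, got {a.shape} vs {b.shape}")


def isotonic_fit_vector(
    dissim_vec: np.ndarray, dist_vec: np.ndarray, ties: str = "primary"
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Isotonic LS fit of ``dist_vec`` against the rank order of ``dissim_vec``.

    Returns (disparity vector aligned with the input pairs, fit order,
    degenerate flag).  Under the primary tie policy, tied dissimilarities
    impose no order constraint on their disparities; under the secondary
    policy they are forced equal.
    """
    if ties not in TIE_POLICIES:
        raise ValueError(f"ties must be one of {TIE_POLICIES}")
    dissim_vec = np.asarray(dissim_vec, dtype=float)
    dist_vec = np.asarray(dist_vec, dtype=float)
    if np.ptp(dissim_vec) == 0.0:
        # All input dissimilarities identical: the only information-free fit
        # is the constant mean; flagged degenerate rather than raised.
        order = np.arange(dissim_vec.size)
        return np.full_like(dist_vec, dist_vec.mean()), order, True
    if ties == "primary":
        # Sorting secondarily by the current distances means within-tie blocks
        # are already ascending, so PAVA leaves them unconstrained.
        order = np.lexsort((dist_vec, dissim_vec))
        fitted = isotonic_regression(dist_vec[order]).x
        out = np.empty_like(dist_vec)
        out[order] = fitted
    else:
        order = np.argsort(dissim_vec, kind="stable")
        sorted_d = dissim_vec[order]
        block_ids = np.concatenate(([0], np.cumsum(np.diff(sorted_d) > 0)))
        n_blocks = block_ids[-1] + 1
        weights = np.bincount(block_ids, minlength=n_blocks).astype(float)
        sums = np.bincount(block_ids, weights=dist_vec[order], minlength=n_blocks)
        block_fit = isotonic_regression(sums / weights, weights=weights).x
        out = np.empty_like(dist_vec)
        out[order] = block_fit[block_ids]
    spread = np.ptp(out)
    scale = max(abs(out).max(), 1e-300)
    return out, order, bool(spread < DEGENERATE_SPREAD * scale)


@dataclass
class Disparities:
    """Target disparity matrix from a monotone (isotonic) regression."""

    values: np.ndarray = field(repr=False)
    source_order: np.ndarray = field(repr=False)
    degenerate: bool = False


def monotone_disparities(
    dissim: np.ndarray, distances: np.ndarray, ties: str = "primary"
) -> Disparities:
    """Pool-adjacent-violators disparities for a full distance matrix."""
    _check_conformable(dissim, distances)
    dvec, iu = _upper(np.asarray(dissim, dtype=float))
    xvec = np.asarray(distances, dtype=float)[iu]
    out, order, degenerate = isotonic_fit_vector(dvec, xvec, ties=ties)
    n = dissim.shape[0]
    values = np.zeros((n, n))
    values[iu] = out
    values += values.T
    return Disparities(values=values, source_order=order, degenerate=degenerate)


def stress1_vectors(disp_vec: np.ndarray, dist_vec: np.ndarray) -> float:
    """Kruskal's stress-1 on upper-triangle pair vectors."""
    denom = float(np.sum(dist_vec**2))
    if denom == 0.0:
        raise DegenerateConfigurationError("all configuration distances are zero")
    return float(np.sqrt(np.sum((disp_vec - dist_vec) ** 2) / denom))


def stress1(disparities: np.ndarray, distances: np.ndarray) -> float:
    """Kruskal's stress-1: sqrt(sum_{i<j}(dhat - d)^2 / sum_{i<j} d^2)."""
    _check_conformable(disparities, distances)
    disp_vec, _ = _upper(disparities)
    dist_vec, _ = _upper(distances)
    return stress1_vectors(disp_vec, dist_vec)


@dataclass
class StressValue:
    """A stress value: either plain stress-1 or the penalized composite."""

    value: float
    kind: str = "stress1"  # "stress1" | "penalized"
    lambda_weight: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stress1", "penalized"):
            raise ValueError("kind must be 'stress1' or 'penalized'")
        if self.value < 0:
            raise ValueError("stress cannot be negative")
        if self.kind == "penalized" and (self.lambda_weight is None or self.lambda_weight < 0):
            raise ValueError("penalized stress requires lambda_weight >= 0")


def penalized_stress(
    config: Configuration,
    expert_dissim: np.ndarray,
    constraint: np.ndarray,
    lambda_weight: float,
    ties: str = "primary",
) -> StressValue:
    """Weakly constrained loss S(X) = s_E(X)^2 + lambda * s_R(X)^2.

    s_E is stress-1 of the configuration distances against disparities fit to
    the expert's dissimilarities; s_R is stress-1 of the same distances
    against disparities fit to the constraint matrix R.  With lambda = 0 this
    is the unconstrained squared stress-1.
    """
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")
    _check_conformable(expert_dissim, constraint)
    distances = pairwise_distances(config)
    dist_vec, iu = _upper(distances)
    e_vec = np.asarray(expert_dissim, dtype=float)[iu]
    r_vec = np.asarray(constraint, dtype=float)[iu]
    e_hat, _, _ = isotonic_fit_vector(e_vec, dist_vec, ties=ties)
    s_e = stress1_vectors(e_hat, dist_vec)
    if lambda_weight == 0.0:
        total = s_e**2
    else:
        r_hat, _, _ = isotonic_fit_vector(r_vec, dist_vec, ties=ties)
        s_r = stress1_vectors(r_hat, dist_vec)
        total = s_e**2 + lambda_weight * s_r**2
    return StressValue(value=total, kind="penalized", lambda_weight=lambda_weight)


def smooth_abs(t: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Once-differentiable surrogate for ``|t|`` (Huber-style quadratic cap).

    Equals |t| for |t| >= tau; for |t| < tau returns t^2/(2 tau) + tau/2,
    which matches |t| in value and slope at |t| = tau and has zero slope at
    t = 0.  ``smooth_abs(t, 0) == |t|``.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if tau == 0.0:
        out = np.abs(t_arr)
    else:
        out = np.where(np.abs(t_arr) >= tau, np.abs(t_arr), t_arr**2 / (2.0 * tau) + tau / 2.0)
    if np.isscalar(t):
        return float(out)
    return out


def smooth_abs_grad(t: np.ndarray, tau: float) -> np.ndarray:
    """Derivative of :func:`smooth_abs` (sign(t) at tau = 0)."""
    t = np.asarray(t, dtype=float)
    if tau == 0.0:
        return np.sign(t)
    return np.where(np.abs(t) >= tau, np.sign(t), t / tau)


def smoothed_pair_distances(diffs: np.ndarray, p: float, tau: float) -> np.ndarray:
    """Smoothed Minkowski distances from per-pair coordinate differences.

    ``diffs`` has shape (n_pairs, q); returns (n_pairs,) distances computed
    as (sum_m smooth_abs(diff_m, tau)^p)^(1/p).  At tau = 0 these are the
    exact distances.
    """
    h = smooth_abs(diffs, tau)
    return np.sum(np.asarray(h) ** p, axis=1) ** (1.0 / p)
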