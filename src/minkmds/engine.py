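"""Majorization engine for weakly constrained nonmetric Minkowski MDS.

For each expert the penalized loss

    S(X) = s_E(X)^2 + lambda * s_R(X)^2
         = [ sum (dhat_E - d)^2 + lambda * sum (dhat_R - d)^2 ] / sum d^2

is minimized over configurations X, where d are the (smoothed) Minkowski-p
distances of X, dhat_E are monotone disparities fit to the expert's
dissimilarities and dhat_R to the country-average constraint matrix R.

Optimization alternates isotonic disparity updates with configuration
updates.  A configuration update decreases the ratio S through the standard
device for normalized loss functions: at the current value S0, any decrease
of G(X) = numerator(X) - S0 * denominator(X) (which is zero at the current
point) strictly decreases S.  G is a quadratic-plus-linear function of the
pair distances and is majorized, per coordinate difference, by a quadratic —
the tangent minorization of the convex distance for the linear term and a
Hoelder-type bound (valid for 1 <= p <= 2) plus a curvature cap on the
smoothed component function for the quadratic term.  Each majorizer is
minimized exactly by solving one small Laplacian system per dimension, giving
the monotone-descent guarantee of majorization.

Distance smoothing (Huber surrogate, annealed to zero over a geometric tau
ladder) flattens the spikes of the city-block distance surface so that the
descent escapes the local minima that plague p close to 1; the final tau = 0
level runs on exact distances.  Seeded uniform random starts plus two
deterministic starts — classical scaling and the expert's own unconstrained
solution — guard against the remaining minima; all (expert x start) rows of
a three-way fit descend together in one vectorized batch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .metrics import Configuration
from .nonmetric import (
    DegenerateConfigurationError,
    StressValue,
    isotonic_fit_vector,
    smooth_abs,
    smooth_abs_grad,
    stress1_vectors,
)
from .results import ExpertFit, MDSResults, StartRecord


class EngineError(RuntimeError):
    pass


class MajorizationError(EngineError):
    """An exact majorization step increased the loss: internal inconsistency."""


@dataclass(frozen=True)
class EngineSettings:
    """Tunable optimizer constants.

    n_tau_levels geometric smoothing levels run from
    tau0 = tau0_factor * (median off-diagonal dissimilarity) down by
    tau_ratio per level, with the final level exact (tau = 0).  Within a
    level, majorization iterates until the relative loss decrease falls
    below inner_tol or the iteration budget runs out (max_inner at the
    exact level, max_inner_anneal during warm-up levels).
    """

    n_tau_levels: int = 16
    tau_ratio: float = 0.7
    tau0_factor: float = 1.0
    inner_tol: float = 1e-6
    max_inner: int = 500
    max_inner_anneal: int = 100
    ties: str = "primary"
    use_classical_start: bool = True
    use_unconstrained_start: bool = True
    max_halvings: int = 20


@dataclass
class FitTrace:
    """Loss trajectory of one fit: per tau level, the accepted loss values."""

    taus: list[float] = field(default_factory=list)
    phases: list[np.ndarray] = field(default_factory=list)
    final_loss: float = float("nan")
    degenerate: bool = False

    def append_phase(self, tau: float, values: Sequence[float]) -> None:
        self.taus.append(float(tau))
        self.phases.append(np.asarray(values, dtype=float))

    @property
    def n_iterations(self) -> int:
        return int(sum(len(ph) for ph in self.phases))


def tau_schedule(median_offdiag: float, settings: EngineSettings | None = None) -> np.ndarray:
    """Geometric smoothing ladder ending exactly at zero."""
    settings = settings or EngineSettings()
    tau0 = settings.tau0_factor * float(median_offdiag)
    if tau0 <= 0:
        return np.array([0.0])
    levels = [tau0 * settings.tau_ratio**k for k in range(settings.n_tau_levels - 1)]
    return np.array(levels + [0.0])


def _validate_schedule(schedule: np.ndarray) -> np.ndarray:
    schedule = np.asarray(schedule, dtype=float)
    if schedule.ndim != 1 or schedule.size < 1:
        raise ValueError("tau_schedule must be a non-empty 1-d sequence")
    if schedule[-1] != 0.0:
        raise ValueError("tau_schedule must end at exactly 0 (final level exact)")
    if np.any(np.diff(schedule) >= 0):
        raise ValueError("tau_schedule must be strictly decreasing to 0")
    return schedule


def classical_scaling_start(dissim: np.ndarray, q: int) -> np.ndarray:
    """Torgerson double-centering start (top-q eigenvectors of -J D^2 J / 2)."""
    d2 = np.asarray(dissim, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:q]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0.0, None))
    if coords.shape[1] < q:  # pragma: no cover - eigh always returns n columns
        coords = np.pad(coords, ((0, 0), (0, q - coords.shape[1])))
    return coords


def _pair_diffs(x: np.ndarray, i0: np.ndarray, i1: np.ndarray) -> np.ndarray:
    return x[i0] - x[i1]


def _loss(
    diffs: np.ndarray,
    p: float,
    tau: float,
    hat_e: np.ndarray,
    hat_r: np.ndarray,
    lam: float,
) -> tuple[float, np.ndarray]:
    h = smooth_abs(diffs, tau)
    d = np.sum(np.asarray(h) ** p, axis=1) ** (1.0 / p)
    denom = float(np.sum(d**2))
    if denom <= 0.0:
        raise DegenerateConfigurationError("configuration collapsed to a single point")
    num = float(np.sum((hat_e - d) ** 2) + lam * np.sum((hat_r - d) ** 2))
    return num / denom, d


_EPS_H = 1e-9  # floor on |coordinate difference| in negative powers at tau = 0
_EPS_D = 1e-12


def _majorize_candidate(
    x: np.ndarray,
    i0: np.ndarray,
    i1: np.ndarray,
    p: float,
    tau: float,
    hat_e: np.ndarray,
    hat_r: np.ndarray,
    lam: float,
    s0: float,
) -> tuple[np.ndarray, bool]:
    """One exact minimization of the quadratic majorizer of G at x.

    Returns (candidate configuration, clean) where ``clean`` is True when no
    numerical floor was active, i.e. the majorization inequality holds
    exactly and the true loss is guaranteed not to increase.
    """
    n, q = x.shape
    diffs = _pair_diffs(x, i0, i1)
    h = np.asarray(smooth_abs(diffs, tau))
    hp = smooth_abs_grad(diffs, tau)
    d = np.sum(h**p, axis=1) ** (1.0 / p)

    clean = True
    a = (1.0 + lam) - s0
    a_floor = 1e-3 * (1.0 + lam)
    if a < a_floor:
        a = a_floor
        clean = False

    h_safe = h
    if tau == 0.0 and p < 2.0:
        scale = max(float(np.median(d)), _EPS_H)
        h_safe = np.maximum(h, _EPS_H * scale)
        if np.any(h < _EPS_H * scale):
            clean = False
    d_safe = np.maximum(d, _EPS_D)
    if np.any(d <= _EPS_D):
        clean = False

    b = hat_e + lam * hat_r  # (P,)
    wt = h_safe ** (p - 2.0) * d_safe[:, None] ** (2.0 - p)  # Hoelder weights
    g = h_safe ** (p - 1.0) * hp / d_safe[:, None] ** (p - 1.0)  # subgradient of d

    if tau == 0.0:
        # h(e)^2 = e^2 exactly: quadratic term a * wt * e^2, linear -2 b g e.
        quad = a * wt
        lin = -2.0 * b[:, None] * g
    else:
        # h(e)^2 <= h(f)^2 + 2 h(f) h'(f) (e - f) + 2 (e - f)^2 (curvature cap).
        quad = 2.0 * a * wt
        lin = a * wt * (2.0 * h * hp - 4.0 * diffs) - 2.0 * b[:, None] * g

    x_new = np.empty_like(x)
    ones = np.ones((n, n)) / n
    for m in range(q):
        amat = np.zeros((n, n))
        amat[i0, i1] = quad[:, m]
        amat += amat.T
        lap = 2.0 * (np.diag(amat.sum(axis=1)) - amat)
        bmat = np.zeros((n, n))
        bmat[i0, i1] = lin[:, m]
        bmat -= bmat.T
        rhs = -bmat.sum(axis=1)
        try:
            x_new[:, m] = np.linalg.solve(lap + ones, rhs)
        except np.linalg.LinAlgError:  # pragma: no cover - disconnected weights
            x_new[:, m] = np.linalg.lstsq(lap, rhs, rcond=None)[0]
    x_new -= x_new.mean(axis=0)
    return x_new, clean


def _iso_rows(target_rows: np.ndarray, dists: np.ndarray, ties: str) -> np.ndarray:
    """Row-wise isotonic fits of distances against per-row dissimilarity orders."""
    out = np.empty_like(dists)
    for s in range(dists.shape[0]):
        out[s], _, _ = isotonic_fit_vector(target_rows[s], dists[s], ties=ties)
    return out


def _exact_d(x: np.ndarray, i0: np.ndarray, i1: np.ndarray, p: float) -> np.ndarray:
    diffs = x[..., i0, :] - x[..., i1, :]
    return np.sum(np.abs(diffs) ** p, axis=-1) ** (1.0 / p)


def _loss_rows(
    x: np.ndarray,
    i0: np.ndarray,
    i1: np.ndarray,
    p: float,
    tau: float,
    hat_e: np.ndarray,
    hat_r: np.ndarray,
    lam: float,
) -> np.ndarray:
    """Smoothed penalized loss per start row; collapsed rows map to +inf."""
    diffs = x[:, i0, :] - x[:, i1, :]
    h = np.asarray(smooth_abs(diffs, tau))
    d = np.sum(h**p, axis=-1) ** (1.0 / p)
    denom = np.sum(d**2, axis=-1)
    num = np.sum((hat_e - d) ** 2, axis=-1) + lam * np.sum((hat_r - d) ** 2, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom > 0.0, num / np.where(denom > 0.0, denom, 1.0), np.inf)
    return out


def _majorize_candidates(
    x: np.ndarray,
    i0: np.ndarray,
    i1: np.ndarray,
    p: float,
    tau: float,
    hat_e: np.ndarray,
    hat_r: np.ndarray,
    lam: float,
    s0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Batched exact minimization of the quadratic majorizer of G, per row.

    ``x`` has shape (S, n, q); ``hat_e``/``hat_r``/``s0`` carry a leading
    start axis.  Rows are mutually independent: each candidate is exactly
    what :func:`fit_single`'s scalar majorizer step would produce.  Returns
    (candidates, clean-per-row).
    """
    S, n, q = x.shape
    diffs = x[:, i0, :] - x[:, i1, :]  # (S, P, q)
    h = np.asarray(smooth_abs(diffs, tau))
    hp = smooth_abs_grad(diffs, tau)
    d = np.sum(h**p, axis=-1) ** (1.0 / p)  # (S, P)

    clean = np.ones(S, dtype=bool)
    a = (1.0 + lam) - s0
    a_floor = 1e-3 * (1.0 + lam)
    low = a < a_floor
    a = np.where(low, a_floor, a)
    clean &= ~low

    h_safe = h
    if tau == 0.0 and p < 2.0:
        scale = np.maximum(np.median(d, axis=-1), _EPS_H)  # (S,)
        floor = (_EPS_H * scale)[:, None, None]
        floored = h < floor
        h_safe = np.maximum(h, floor)
        clean &= ~np.any(floored, axis=(1, 2))
    d_safe = np.maximum(d, _EPS_D)
    clean &= ~np.any(d <= _EPS_D, axis=-1)

    b = hat_e + lam * hat_r  # (S, P)
    wt = h_safe ** (p - 2.0) * d_safe[..., None] ** (2.0 - p)
    g = h_safe ** (p - 1.0) * hp / d_safe[..., None] ** (p - 1.0)

    if tau == 0.0:
        quad = a[:, None, None] * wt
        lin = -2.0 * b[..., None] * g
    else:
        quad = 2.0 * a[:, None, None] * wt
        lin = a[:, None, None] * wt * (2.0 * h * hp - 4.0 * diffs) - 2.0 * b[..., None] * g

    amat = np.zeros((S, q, n, n))
    amat[:, :, i0, i1] = quad.transpose(0, 2, 1)
    amat += amat.transpose(0, 1, 3, 2)
    lap = -2.0 * amat
    deg = 2.0 * amat.sum(axis=-1)
    lap[:, :, np.arange(n), np.arange(n)] += deg
    bmat = np.zeros((S, q, n, n))
    bmat[:, :, i0, i1] = lin.transpose(0, 2, 1)
    bmat -= bmat.transpose(0, 1, 3, 2)
    rhs = -bmat.sum(axis=-1)  # (S, q, n)
    ones = np.ones((n, n)) / n
    try:
        sol = np.linalg.solve(lap + ones, rhs[..., None])[..., 0]  # (S, q, n)
    except np.linalg.LinAlgError:  # pragma: no cover - disconnected weights
        flat_l = (lap + ones).reshape(-1, n, n)
        flat_r = rhs.reshape(-1, n)
        sol = np.stack(
            [np.linalg.lstsq(flat_l[i], flat_r[i], rcond=None)[0] for i in range(flat_l.shape[0])]
        ).reshape(S, q, n)
    x_new = sol.transpose(0, 2, 1)
    x_new = x_new - x_new.mean(axis=1, keepdims=True)
    return x_new, clean


def _fit_batch_rows(
    e_rows: np.ndarray,
    r_rows: np.ndarray,
    p: float,
    q: int,
    lambda_weight: float,
    tau_schedule: np.ndarray,
    starts: np.ndarray,
    settings: EngineSettings,
) -> list[tuple[np.ndarray, float, float, FitTrace]]:
    """Batched annealed-majorization descent with per-row dissimilarity targets.

    Row s descends the penalized loss for expert data ``e_rows[s]`` and
    constraint ``r_rows[s]`` from ``starts[s]``; rows are mutually
    independent, so one vectorized sweep replaces S sequential fits.
    Returns per row (coords, exact stress-1, final penalized loss, trace).
    """
    schedule = _validate_schedule(tau_schedule)
    if not (1.0 <= p <= 2.0):
        raise ValueError("the majorization engine supports Minkowski orders 1 <= p <= 2")
    if q < 1:
        raise ValueError("q must be >= 1")
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")

    x = np.array(starts, dtype=float)
    if x.ndim != 3 or x.shape[2] != q:
        raise ValueError(f"starts must have shape (S, n, {q}), got {x.shape}")
    S, n, _ = x.shape
    i0, i1 = np.triu_indices(n, 1)
    e_rows = np.asarray(e_rows, dtype=float)
    r_rows = np.asarray(r_rows, dtype=float)
    if e_rows.shape != (S, i0.size) or r_rows.shape != (S, i0.size):
        raise ValueError("e_rows/r_rows must have shape (S, n_pairs)")
    x = x - x.mean(axis=1, keepdims=True)

    lam = lambda_weight
    ties = settings.ties
    phase_lists: list[list[list[float]]] = [[] for _ in range(S)]

    for tau in schedule:
        d_exact = _exact_d(x, i0, i1, p)
        hat_e = _iso_rows(e_rows, d_exact, ties)
        hat_r = _iso_rows(r_rows, d_exact, ties)
        s_cur = _loss_rows(x, i0, i1, p, tau, hat_e, hat_r, lam)
        phases = [[float(v)] for v in s_cur]
        active = np.ones(S, dtype=bool)
        budget = settings.max_inner if tau == 0.0 else min(settings.max_inner, settings.max_inner_anneal)
        for _ in range(budget):
            x_cand, clean = _majorize_candidates(x, i0, i1, p, tau, hat_e, hat_r, lam, s_cur)
            s_cand = _loss_rows(x_cand, i0, i1, p, tau, hat_e, hat_r, lam)
            ok = s_cand <= s_cur * (1.0 + 1e-12) + 1e-15
            bad_clean = active & clean & ~ok & (tau > 0.0) & (s_cand > s_cur * (1.0 + 1e-8))
            if np.any(bad_clean):
                idx = int(np.argmax(bad_clean))
                raise MajorizationError(
                    f"majorization step increased the loss at tau={tau:g} "
                    f"({s_cur[idx]:.3e} -> {s_cand[idx]:.3e})"
                )
            pending = active & ~ok
            for _h in range(settings.max_halvings):
                if not np.any(pending):
                    break
                x_cand[pending] = 0.5 * (x_cand[pending] + x[pending])
                s_sub = _loss_rows(x_cand[pending], i0, i1, p, tau,
                                   hat_e[pending], hat_r[pending], lam)
                s_cand[pending] = s_sub
                newly_ok = np.zeros(S, dtype=bool)
                newly_ok[pending] = s_sub <= s_cur[pending] * (1.0 + 1e-12) + 1e-15
                ok |= newly_ok
                pending = active & ~ok
            # starts whose step cannot be rescued have converged
            active &= ok
            if not np.any(active):
                break
            upd = active
            s_prev = s_cur.copy()
            x[upd] = x_cand[upd]
            s_cur[upd] = np.minimum(s_cand[upd], s_cur[upd])
            if tau == 0.0:
                d_exact = _exact_d(x[upd], i0, i1, p)
                hat_e[upd] = _iso_rows(e_rows[upd], d_exact, ties)
                hat_r[upd] = _iso_rows(r_rows[upd], d_exact, ties)
                s_new = _loss_rows(x[upd], i0, i1, p, tau, hat_e[upd], hat_r[upd], lam)
                s_cur[upd] = np.minimum(s_new, s_cur[upd])
            for s_idx in np.flatnonzero(upd):
                phases[s_idx].append(float(s_cur[s_idx]))
            converged = upd & ((s_prev - s_cur) < settings.inner_tol * np.maximum(s_prev, 1e-12))
            active &= ~converged
            if not np.any(active):
                break
        for s_idx in range(S):
            phase_lists[s_idx].append(phases[s_idx])

    results = []
    for s_idx in range(S):
        diffs = x[s_idx][i0] - x[s_idx][i1]
        d_fin = np.sum(np.abs(diffs) ** p, axis=1) ** (1.0 / p)
        hat_e_f, _, degenerate = isotonic_fit_vector(e_rows[s_idx], d_fin, ties=ties)
        hat_r_f, _, _ = isotonic_fit_vector(r_rows[s_idx], d_fin, ties=ties)
        s_e = stress1_vectors(hat_e_f, d_fin)
        s_r = stress1_vectors(hat_r_f, d_fin)
        trace = FitTrace(
            taus=[float(t) for t in schedule],
            phases=[np.asarray(ph) for ph in phase_lists[s_idx]],
            final_loss=s_e**2 + lam * s_r**2,
            degenerate=degenerate,
        )
        results.append((x[s_idx].copy(), s_e, s_e**2 + lam * s_r**2, trace))
    return results


def fit_batch(
    expert_dissim: np.ndarray,
    constraint: np.ndarray,
    p: float,
    q: int,
    lambda_weight: float,
    tau_schedule: np.ndarray,
    starts: np.ndarray,
    settings: EngineSettings | None = None,
    labels: Sequence[str] | None = None,
) -> list[tuple[Configuration, StressValue, FitTrace]]:
    """Run :func:`fit_single`'s algorithm from many starts simultaneously.

    ``starts`` has shape (S, n, q); all starts share one expert/constraint
    matrix pair.  Every start follows the identical annealed majorization
    schedule with its own safeguarded step acceptance and convergence test.
    """
    settings = settings or EngineSettings()
    expert_dissim = np.asarray(expert_dissim, dtype=float)
    constraint = np.asarray(constraint, dtype=float)
    n = expert_dissim.shape[0]
    i0, i1 = np.triu_indices(n, 1)
    starts = np.asarray(starts, dtype=float)
    S = starts.shape[0]
    e_rows = np.tile(expert_dissim[i0, i1], (S, 1))
    r_rows = np.tile(constraint[i0, i1], (S, 1))
    rows = _fit_batch_rows(
        e_rows, r_rows, p, q, lambda_weight, tau_schedule, starts, settings
    )
    labels = list(labels) if labels is not None else [f"obj_{i + 1}" for i in range(n)]
    return [
        (
            Configuration(labels=labels, coords=coords, metric_p=p),
            StressValue(value=s_e, kind="stress1"),
            trace,
        )
        for coords, s_e, _, trace in rows
    ]


def fit_single(
    expert_dissim: np.ndarray,
    constraint: np.ndarray,
    p: float,
    q: int,
    lambda_weight: float,
    tau_schedule: np.ndarray,
    start: np.ndarray,
    settings: EngineSettings | None = None,
    labels: Sequence[str] | None = None,
) -> tuple[Configuration, StressValue, FitTrace]:
    """Minimize the smoothed penalized loss from one start.

    Anneals tau down ``tau_schedule``; at each positive tau, disparities are
    refreshed once (isotonic fit against the exact distances) and the
    configuration then descends the fixed-disparity smoothed loss by
    majorization (provably monotone).  At the final tau = 0 level the full
    alternation runs and every step decreases the exact penalized loss.
    Returns the configuration, its exact (unsmoothed, unpenalized) stress-1
    against the expert data, and the loss trace.
    """
    settings = settings or EngineSettings()
    schedule = _validate_schedule(tau_schedule)
    if not (1.0 <= p <= 2.0):
        raise ValueError("the majorization engine supports Minkowski orders 1 <= p <= 2")
    if q < 1:
        raise ValueError("q must be >= 1")
    if lambda_weight < 0:
        raise ValueError("lambda_weight must be >= 0")

    expert_dissim = np.asarray(expert_dissim, dtype=float)
    constraint = np.asarray(constraint, dtype=float)
    n = expert_dissim.shape[0]
    i0, i1 = np.triu_indices(n, 1)
    e_vec = expert_dissim[i0, i1]
    r_vec = constraint[i0, i1]

    x = np.array(start, dtype=float)
    if x.shape != (n, q):
        raise ValueError(f"start must have shape {(n, q)}, got {x.shape}")
    x = x - x.mean(axis=0)

    trace = FitTrace()
    lam = lambda_weight
    ties = settings.ties

    for tau in schedule:
        diffs = _pair_diffs(x, i0, i1)
        d_exact = np.sum(np.abs(diffs) ** p, axis=1) ** (1.0 / p)
        hat_e, _, _ = isotonic_fit_vector(e_vec, d_exact, ties=ties)
        hat_r, _, _ = isotonic_fit_vector(r_vec, d_exact, ties=ties)
        s, _ = _loss(diffs, p, tau, hat_e, hat_r, lam)
        phase = [s]
        # Annealing levels are warm-up: a capped budget there loses nothing
        # the exact final level cannot recover.
        budget = settings.max_inner if tau == 0.0 else min(settings.max_inner, settings.max_inner_anneal)
        for _ in range(budget):
            x_cand, clean = _majorize_candidate(x, i0, i1, p, tau, hat_e, hat_r, lam, s)
            diffs_cand = _pair_diffs(x_cand, i0, i1)
            s_cand, _ = _loss(diffs_cand, p, tau, hat_e, hat_r, lam)
            if s_cand > s * (1.0 + 1e-12) + 1e-15:
                if clean and tau > 0.0 and s_cand > s * (1.0 + 1e-8):
                    raise MajorizationError(
                        f"majorization step increased the loss at tau={tau:g} "
                        f"({s:.3e} -> {s_cand:.3e})"
                    )
                accepted = False
                for _h in range(settings.max_halvings):
                    x_cand = 0.5 * (x_cand + x)
                    diffs_cand = _pair_diffs(x_cand, i0, i1)
                    s_cand, _ = _loss(diffs_cand, p, tau, hat_e, hat_r, lam)
                    if s_cand <= s * (1.0 + 1e-12) + 1e-15:
                        accepted = True
                        break
                if not accepted:
                    break
            s_prev = s
            x, s = x_cand, min(s_cand, s)
            if tau == 0.0:
                # Full alternation at the exact level: refitting disparities
                # against the (exact) distances can only lower the numerator.
                diffs = _pair_diffs(x, i0, i1)
                d_exact = np.sum(np.abs(diffs) ** p, axis=1) ** (1.0 / p)
                hat_e, _, _ = isotonic_fit_vector(e_vec, d_exact, ties=ties)
                hat_r, _, _ = isotonic_fit_vector(r_vec, d_exact, ties=ties)
                s, _ = _loss(diffs, p, tau, hat_e, hat_r, lam)
                s = min(s, s_prev)
            phase.append(s)
            if (s_prev - s) < settings.inner_tol * max(s_prev, 1e-12):
                break
        trace.append_phase(tau, phase)

    diffs = _pair_diffs(x, i0, i1)
    d_exact = np.sum(np.abs(diffs) ** p, axis=1) ** (1.0 / p)
    hat_e, _, degenerate = isotonic_fit_vector(e_vec, d_exact, ties=ties)
    hat_r, _, _ = isotonic_fit_vector(r_vec, d_exact, ties=ties)
    s_e = stress1_vectors(hat_e, d_exact)
    s_r = stress1_vectors(hat_r, d_exact)
    trace.final_loss = s_e**2 + lam * s_r**2
    trace.degenerate = degenerate

    labels = list(labels) if labels is not None else [f"obj_{i + 1}" for i in range(n)]
    config = Configuration(labels=labels, coords=x, metric_p=p)
    return config, StressValue(value=s_e, kind="stress1"), trace


def _median_offdiag(mat: np.ndarray) -> float:
    iu = np.triu_indices(mat.shape[0], 1)
    med = float(np.median(mat[iu]))
    return med


def random_start(n: int, q: int, seed: int | None, expert_index: int, start_index: int) -> np.ndarray:
    """Seeded i.i.d. uniform [-1, 1] start; nested in (expert, start) index."""
    ss = np.random.SeedSequence(entropy=0 if seed is None else int(seed), spawn_key=(expert_index, start_index))
    rng = np.random.default_rng(ss)
    return rng.uniform(-1.0, 1.0, size=(n, q))


def fit_three_way(
    data,
    p: float,
    q: int,
    lambda_weight: float = 100.0,
    n_starts: int = 50,
    seed: int | None = None,
    settings: EngineSettings | None = None,
    candidate_configs: Sequence[Sequence[np.ndarray]] | None = None,
) -> MDSResults:
    """Fit one weakly constrained configuration per expert by multistart.

    For each expert, ``n_starts`` starts are run against the shared
    constraint matrix: one deterministic classical-scaling start (unless
    disabled), one warm start from the expert's own unconstrained solution
    (unless disabled; it enters the penalized descent like any other start),
    and seeded uniform random starts.  All rows (experts x starts) descend
    in one vectorized batch.  Optional ``candidate_configs[k]`` (e.g. the
    padded best solution from one fewer dimension) are both evaluated
    directly as candidates and refined with a tau = 0 descent, so a
    dimensionality scan is non-increasing in q by construction.  The
    reported fit per expert is the candidate with the lowest exact stress-1
    (ties broken by penalized loss, then order).

    ``data`` is a :class:`~minkmds.survey.ThreeWayDissimilarities`.
    """
    settings = settings or EngineSettings()
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    n = data.n_parties
    n_experts = data.n_experts
    i0, i1 = np.triu_indices(n, 1)

    # Rank order (all the nonmetric fit uses) is scale-free; normalizing each
    # expert by its median off-diagonal entry puts the dissimilarities, the
    # uniform starts and the tau ladder on one common scale, which also lets
    # every expert share one annealing schedule.
    e_pairs = np.empty((n_experts, i0.size))
    r_pairs = np.empty((n_experts, i0.size))
    classical = np.empty((n_experts, n, q))
    for k in range(n_experts):
        mat = np.asarray(data.matrices[k], dtype=float)
        med = _median_offdiag(mat)
        if med <= 0:
            med = float(mat.max()) or 1.0
        e_pairs[k] = mat[i0, i1] / med
        r_pairs[k] = np.asarray(data.constraint, dtype=float)[i0, i1] / med
        classical[k] = classical_scaling_start(mat / med, q)
    schedule = tau_schedule(
        float(np.median(np.median(e_pairs, axis=1))), settings
    )
    exact_only = np.array([0.0])

    roster: list[str] = []
    n_slots = n_starts
    use_warm = settings.use_unconstrained_start and lambda_weight > 0
    if settings.use_classical_start and n_slots > 0:
        roster.append("classical")
        n_slots -= 1
    if use_warm and n_slots > 0:
        roster.append("unconstrained_warm")
        n_slots -= 1
    roster += [f"random_{s}" for s in range(max(n_slots, 0))]

    def _rows(names_starts, e_rows, r_rows, lam, sched):
        return _fit_batch_rows(
            e_rows, r_rows, p, q, lam, sched, names_starts, settings
        )

    try:
        warm_coords = None
        if "unconstrained_warm" in roster:
            # Warm pre-fits: each expert's own unconstrained solution, which
            # the tau = 0 penalized descent then pulls toward the constraint.
            pre = _rows(classical, e_pairs, e_pairs, 0.0, schedule)
            warm_coords = np.stack([coords for coords, _, _, _ in pre])

        batch_names: list[tuple[int, str]] = []
        batch_starts = []
        batch_e, batch_r = [], []
        exact_names: list[tuple[int, str]] = []
        exact_starts = []
        exact_e, exact_r = [], []
        for k in range(n_experts):
            for name in roster:
                if name == "classical":
                    batch_names.append((k, name))
                    batch_starts.append(classical[k])
                elif name == "unconstrained_warm":
                    exact_names.append((k, name))
                    exact_starts.append(warm_coords[k])
                    exact_e.append(e_pairs[k])
                    exact_r.append(r_pairs[k])
                    continue
                else:
                    s_idx = int(name.split("_")[1])
                    batch_names.append((k, name))
                    batch_starts.append(random_start(n, q, seed, k, s_idx))
                if name != "unconstrained_warm":
                    batch_e.append(e_pairs[k])
                    batch_r.append(r_pairs[k])
        if candidate_configs is not None:
            for k in range(n_experts):
                for c_idx, cand in enumerate(candidate_configs[k]):
                    exact_names.append((k, f"candidate_{c_idx}_refined"))
                    exact_starts.append(np.asarray(cand, dtype=float))
                    exact_e.append(e_pairs[k])
                    exact_r.append(r_pairs[k])

        records_by_expert: list[list[StartRecord]] = [[] for _ in range(n_experts)]

        def _record(k, name, coords, s_e, loss, trace):
            records_by_expert[k].append(
                StartRecord(
                    name=name,
                    stress=s_e,
                    loss=loss,
                    config=Configuration(
                        labels=list(data.parties), coords=coords, metric_p=p
                    ),
                    trace=trace,
                    degenerate=trace.degenerate,
                )
            )

        if batch_starts:
            outs = _rows(
                np.stack(batch_starts), np.stack(batch_e), np.stack(batch_r),
                lambda_weight, schedule,
            )
            for (k, name), (coords, s_e, loss, trace) in zip(batch_names, outs):
                _record(k, name, coords, s_e, loss, trace)
        if exact_starts:
            outs = _rows(
                np.stack(exact_starts), np.stack(exact_e), np.stack(exact_r),
                lambda_weight, exact_only,
            )
            for (k, name), (coords, s_e, loss, trace) in zip(exact_names, outs):
                _record(k, name, coords, s_e, loss, trace)
        if candidate_configs is not None:
            # Direct evaluations keep each previous solution's stress as a
            # reachable candidate (the exact non-increase guarantee).
            for k in range(n_experts):
                for c_idx, cand in enumerate(candidate_configs[k]):
                    cand = np.asarray(cand, dtype=float)
                    cand = cand - cand.mean(axis=0)
                    d_fin = _exact_d(cand, i0, i1, p)
                    hat_e, _, degenerate = isotonic_fit_vector(
                        e_pairs[k], d_fin, ties=settings.ties
                    )
                    hat_r, _, _ = isotonic_fit_vector(
                        r_pairs[k], d_fin, ties=settings.ties
                    )
                    s_e = stress1_vectors(hat_e, d_fin)
                    loss = s_e**2 + lambda_weight * stress1_vectors(hat_r, d_fin) ** 2
                    trace = FitTrace(
                        taus=[0.0], phases=[np.array([loss])],
                        final_loss=loss, degenerate=degenerate,
                    )
                    _record(k, f"candidate_{c_idx}", cand, s_e, loss, trace)
    except DegenerateConfigurationError as err:  # pragma: no cover
        raise EngineError(f"start collapsed: {err}") from err

    name_rank = {name: i for i, name in enumerate(roster)}
    expert_fits: list[ExpertFit] = []
    for k in range(n_experts):
        records = sorted(
            records_by_expert[k], key=lambda r: name_rank.get(r.name, len(name_rank))
        )
        best = min(
            range(len(records)), key=lambda i: (records[i].stress, records[i].loss, i)
        )
        expert_fits.append(
            ExpertFit(
                expert=data.experts[k],
                config=records[best].config,
                stress=records[best].stress,
                loss=records[best].loss,
                best_start=records[best].name,
                starts=records,
                degenerate=records[best].degenerate,
            )
        )

    return MDSResults(
        expert_fits=expert_fits,
        metric_p=p,
        n_dims=q,
        lambda_weight=lambda_weight,
        n_starts=n_starts,
        seed=seed,
        settings=settings,
        parties=list(data.parties),
    )
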