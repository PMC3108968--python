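"""Kendall-tau correlation of fitted city-block dimensions with ideology.

The meaning of MDS dimensions is probed externally: for every expert, each
dimension's party coordinates are rank-correlated (Kendall tau-b, two-sided)
with that expert's left-right ideology ratings.  Only city-block (p = 1)
solutions are admitted — a Euclidean solution can be rotated without changing
stress, so its dimension-wise correlations are not identified.

Tau-b is used because 1-20 integer ideology scales produce frequent ties.
p-values come from exact enumeration of the permutation null for n <= 8 and
from the tie-adjusted normal approximation otherwise.  Per the reporting
convention replicated here, no multiple-testing correction is applied across
experts or dimensions (a caveat, not an oversight).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .results import MDSResults

ALPHA = 0.05
EXACT_MAX_N = 8


class UndefinedTauError(ValueError):
    """Kendall tau is undefined (a constant vector zeroes the denominator)."""


class RotationalIndeterminacyError(ValueError):
    """Dimension-wise correlation refused for rotatable (p != 1) solutions."""


def _pair_signs(v: np.ndarray) -> np.ndarray:
    return np.sign(v[:, None] - v[None, :])


def kendall_tau(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall tau-b (tie-corrected) between two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-d vectors of identical length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedTauError("tau undefined for a constant vector")
    sx = _pair_signs(x)
    sy = _pair_signs(y)
    iu = np.triu_indices(x.size, 1)
    num = float(np.sum(sx[iu] * sy[iu]))
    n_pairs = iu[0].size
    tx = n_pairs - float(np.sum(sx[iu] != 0))
    ty = n_pairs - float(np.sum(sy[iu] != 0))
    denom = np.sqrt((n_pairs - tx) * (n_pairs - ty))
    return num / denom


def _exact_permutation_p(x: np.ndarray, y: np.ndarray, tau_obs: float) -> float:
    """Two-sided p by full enumeration of permutations of y (n <= 8)."""
    n = x.size
    sx = _pair_signs(x)
    sy = _pair_signs(y)
    iu, ju = np.triu_indices(n, 1)
    n_pairs = iu.size
    tx = n_pairs - float(np.sum(sx[iu, ju] != 0))
    ty = n_pairs - float(np.sum(sy[iu, ju] != 0))
    denom = np.sqrt((n_pairs - tx) * (n_pairs - ty))
    perms = np.array(list(permutations(range(n))))
    nums = np.zeros(perms.shape[0])
    for i, j in zip(iu, ju):
        nums += sx[i, j] * sy[perms[:, i], perms[:, j]]
    taus = nums / denom
    return float(np.mean(np.abs(taus) >= abs(tau_obs) - 1e-12))


@dataclass
class TauResult:
    expert: str
    dimension_index: int  # 1-based
    tau: float
    p_value: float
    significant: bool


def tau_significance(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Kendall tau-b and a two-sided p-value.

    Exact permutation-null enumeration for n <= 8; tie-adjusted normal
    approximation for larger n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    tau = kendall_tau(x, y)
    if x.size <= EXACT_MAX_N:
        p = _exact_permutation_p(x, y, tau)
    else:
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
        p = float(res.pvalue)
    return tau, min(max(p, 0.0), 1.0)


def dimension_ideology_tests(
    fit: MDSResults, ideology: np.ndarray
) -> tuple[list[TauResult], dict[str, float]]:
    """Per-(expert, dimension) tau tests plus configuration-level counts.

    ``ideology`` has shape (n_experts, n_parties), rows aligned with the
    fit's experts and columns with its parties.  Returns the list of
    :class:`TauResult` and summary counts: how many experts have at least one
    (and both of the first two) dimensions significant at p < 0.05.
    """
    if fit.metric_p != 1.0:
        raise RotationalIndeterminacyError(
            "dimension-ideology correlation is only meaningful for the city-block "
            "(p=1) solution; rotational indeterminacy remains at other orders"
        )
    ideology = np.asarray(ideology, dtype=float)
    if ideology.shape != (fit.n_experts, len(fit.parties)):
        raise ValueError(
            f"ideology must have shape {(fit.n_experts, len(fit.parties))}, "
            f"got {ideology.shape}"
        )
    results: list[TauResult] = []
    for e_idx, ef in enumerate(fit.expert_fits):
        for m in range(ef.config.n_dims):
            try:
                tau, p = tau_significance(ef.config.coords[:, m], ideology[e_idx])
                significant = bool(p < ALPHA)
            except UndefinedTauError:
                # a collapsed axis (constant coordinates) carries no order
                # information: undefined tau, never significant
                tau, p, significant = float("nan"), float("nan"), False
            results.append(
                TauResult(
                    expert=ef.expert,
                    dimension_index=m + 1,
                    tau=tau,
                    p_value=p,
                    significant=significant,
                )
            )
    n_dims = fit.n_dims
    any_sig = 0
    both_sig = 0
    for e_idx in range(fit.n_experts):
        flags = [r.significant for r in results[e_idx * n_dims : (e_idx + 1) * n_dims]]
        if any(flags):
            any_sig += 1
        if len(flags) >= 2 and flags[0] and flags[1]:
            both_sig += 1
    summary = {
        "n_experts": float(fit.n_experts),
        "n_any_significant": float(any_sig),
        "n_both_significant": float(both_sig),
        "prop_any_significant": any_sig / fit.n_experts,
        "prop_both_significant": both_sig / fit.n_experts,
    }
    return results, summary


def tau_results_frame(results: list[TauResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "expert": [r.expert for r in results],
            "dimension": [r.dimension_index for r in results],
            "tau": [r.tau for r in results],
            "p_value": [r.p_value for r in results],
            "significant": [r.significant for r in results],
        }
    )
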