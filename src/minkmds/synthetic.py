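"""Synthetic expert-survey generator with known latent ground truth.

Emulates the data-generating situation the three-way analysis assumes:
parties occupy a low-dimensional latent space under a chosen Minkowski
metric; each expert observes a jittered copy of that space through many
policy scales (near-axis-aligned loadings, so separable city-block structure
survives the mapping); ratings are affinely mapped onto the integer 1-20
grid with pre-discretization noise; an ideology score is a noisy monotone
function of latent dimension 1.  The truth carrier makes every pipeline
stage testable for recovery without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .metrics import is_dominance
from .survey import (
    RATING_MAX,
    RATING_MIN,
    ExpertSurveyData,
    ThreeWayDissimilarities,
    average_dissimilarity,
)

# Inclusion minima of the study design the generator emulates.
MIN_PARTIES = 5
MIN_POLICIES = 7
MIN_EXPERTS = 7


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a generated expert survey.

    expert_jitter_sd is the per-expert coordinate noise as a fraction of
    party_scale; rating_noise_sd is pre-discretization noise in units of
    1-20 grid steps; ideology_alignment in [0, 1] weights latent dimension 1
    in the ideology score (0 gives a null, ideology-independent score).
    """

    n_parties: int = 10
    n_policies: int = 8
    n_experts: int = 7
    latent_dims: int = 2
    latent_metric_p: float = 1.0
    party_scale: float = 1.0
    expert_jitter_sd: float = 0.1
    rating_noise_sd: float = 0.5
    ideology_alignment: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_parties < MIN_PARTIES or self.n_policies < MIN_POLICIES or self.n_experts < MIN_EXPERTS:
            raise ValueError(
                "inclusion rule violated: need at least "
                f"{MIN_PARTIES} parties, {MIN_POLICIES} policies and "
                f"{MIN_EXPERTS} experts (got {self.n_parties}, "
                f"{self.n_policies}, {self.n_experts})"
            )
        if self.latent_dims < 1:
            raise ValueError("latent_dims must be >= 1")
        if not (is_dominance(self.latent_metric_p) or self.latent_metric_p >= 1.0):
            raise ValueError("latent_metric_p must be >= 1 or DOMINANCE")
        if not (0.0 <= self.ideology_alignment <= 1.0):
            raise ValueError("ideology_alignment must lie in [0, 1]")
        if self.party_scale <= 0:
            raise ValueError("party_scale must be positive")

    @property
    def raw_dimensionality(self) -> int:
        """Raw rating dimensionality n_parties * n_policies * n_experts."""
        return self.n_parties * self.n_policies * self.n_experts


@dataclass
class SyntheticTruth:
    """Everything needed to recompute expected (pre-noise) ratings."""

    latent: np.ndarray = field(repr=False)  # (E, N, latent_dims) jittered configs
    loadings: np.ndarray = field(repr=False)  # (n_policies, latent_dims)
    latent_metric_p: float = 1.0
    ideology_alignment: float = 0.8
    policy_affine: np.ndarray = field(repr=False, default=None)  # (n_policies, 2) scale, offset
    ideology_affine: tuple[float, float] = (1.0, 0.0)


@dataclass
class SyntheticDataset:
    survey: ExpertSurveyData
    truth: SyntheticTruth
    spec: SyntheticSpec


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _to_grid(x: np.ndarray) -> np.ndarray:
    return np.clip(_round_half_away(x), RATING_MIN, RATING_MAX).astype(np.int64)


def _affine_to_scale(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Affine map of an array onto [1, 20] (degenerate spread maps to midpoint)."""
    lo, hi = float(values.min()), float(values.max())
    if hi - lo < 1e-12:
        mid = (RATING_MIN + RATING_MAX) / 2.0
        return np.full_like(values, mid), 0.0, mid
    scale = (RATING_MAX - RATING_MIN) / (hi - lo)
    offset = RATING_MIN - lo * scale
    return values * scale + offset, scale, offset


def _make_loadings(n_policies: int, latent_dims: int) -> np.ndarray:
    """Near-axis-aligned loadings: 80% weight on one latent dimension each.

    Policies are assigned to main dimensions round-robin; signs alternate so
    that 'left' poles vary across scales.
    """
    loadings = np.zeros((n_policies, latent_dims))
    for j in range(n_policies):
        main = j % latent_dims
        row = np.full(latent_dims, 0.2 / max(latent_dims - 1, 1))
        row[main] = 0.8
        sign = 1.0 if (j // latent_dims) % 2 == 0 else -1.0
        loadings[j] = sign * row
    return loadings


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a fully seed-deterministic synthetic survey with ground truth."""
    rng = np.random.default_rng(spec.seed)
    n_e, n_p, n_k, d = spec.n_experts, spec.n_parties, spec.n_policies, spec.latent_dims

    base = rng.normal(0.0, spec.party_scale, size=(n_p, d))
    jitter = rng.normal(0.0, spec.expert_jitter_sd * spec.party_scale, size=(n_e, n_p, d))
    latent = base[None, :, :] + jitter

    loadings = _make_loadings(n_k, d)
    raw = np.einsum("epd,kd->epk", latent, loadings)  # (E, N, K)

    scaled = np.empty_like(raw)
    policy_affine = np.zeros((n_k, 2))
    for k in range(n_k):
        scaled[:, :, k], policy_affine[k, 0], policy_affine[k, 1] = _affine_to_scale(raw[:, :, k])
    noisy = scaled + rng.normal(0.0, spec.rating_noise_sd, size=scaled.shape)
    ratings = _to_grid(noisy)

    noise = rng.normal(0.0, spec.party_scale, size=(n_e, n_p))
    ideo_latent = spec.ideology_alignment * latent[:, :, 0] + (1.0 - spec.ideology_alignment) * noise
    ideo_scaled, ideo_scale, ideo_offset = _affine_to_scale(ideo_latent)
    ideology = _to_grid(ideo_scaled)

    survey = ExpertSurveyData(
        country_label="synthetic",
        experts=[f"E{i + 1}" for i in range(n_e)],
        parties=[f"P{i + 1:02d}" for i in range(n_p)],
        policies=[f"Policy{j + 1}" for j in range(n_k)],
        ratings=ratings,
        ideology=ideology,
    )
    truth = SyntheticTruth(
        latent=latent,
        loadings=loadings,
        latent_metric_p=spec.latent_metric_p,
        ideology_alignment=spec.ideology_alignment,
        policy_affine=policy_affine,
        ideology_affine=(ideo_scale, ideo_offset),
    )
    return SyntheticDataset(survey=survey, truth=truth, spec=spec)


def latent_dissimilarities(dataset: SyntheticDataset) -> ThreeWayDissimilarities:
    """Exact Minkowski distances between the true jittered latent coordinates.

    The oracle input for recovery tests: what the fitted configurations
    should reproduce up to a monotone transform.
    """
    p = dataset.truth.latent_metric_p
    mats = []
    for k in range(dataset.survey.n_experts):
        coords = dataset.truth.latent[k]
        if is_dominance(p):
            vec = pdist(coords, metric="chebyshev")
        else:
            vec = pdist(coords, metric="minkowski", p=p)
        mats.append(squareform(vec))
    stacked = np.asarray(mats)
    return ThreeWayDissimilarities(
        parties=dataset.survey.parties,
        matrices=stacked,
        constraint=average_dissimilarity(list(stacked)),
        profile_metric_p=p,
        experts=dataset.survey.experts,
    )


def judgment_dissimilarities(dataset: SyntheticDataset) -> ThreeWayDissimilarities:
    """Dissimilarities as the emulated experts would report them.

    The generating metric is the metric the emulated experts use to combine
    policy differences into one dissimilarity judgment: Minkowski profile
    distances over the observed integer ratings at p = latent_metric_p.
    This is the end-to-end (ratings-level) counterpart of
    :func:`latent_dissimilarities`, which returns the noise-free latent
    oracle distances instead.
    """
    from .survey import profile_dissimilarities

    return profile_dissimilarities(dataset.survey, p_in=dataset.truth.latent_metric_p)


def write_truth(dataset: SyntheticDataset, path: str | Path) -> Path:
    """JSON sidecar with the generating spec and ground truth."""
    path = Path(path)
    payload = {
        "spec": asdict(dataset.spec),
        "latent": dataset.truth.latent.tolist(),
        "loadings": dataset.truth.loadings.tolist(),
        "latent_metric_p": dataset.truth.latent_metric_p,
        "ideology_alignment": dataset.truth.ideology_alignment,
        "policy_affine": dataset.truth.policy_affine.tolist(),
        "ideology_affine": list(dataset.truth.ideology_affine),
    }
    path.write_text(json.dumps(payload, indent=2))
    return path
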