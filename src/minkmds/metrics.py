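"""Minkowski distance kernels and the planar city-block/dominance isometry.

The Minkowski family d_p(a, b) = (sum_m |a_m - b_m|^p)^(1/p) interpolates
between the city-block metric (p = 1, separable stimulus dimensions), the
Euclidean metric (p = 2, integral dimensions) and the dominance metric
(p = infinity, a single maximally discriminating dimension).  In two
dimensions the city-block and dominance metrics are isometric: a 45-degree
rotation maps one family of isosimilarity contours onto the other up to a
factor sqrt(2), which :func:`rotate45_scale` exposes as a testable identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

#: Sentinel for the dominance (maximum-component, p = infinity) metric.
DOMINANCE: float = math.inf

_SQRT2 = math.sqrt(2.0)


def is_dominance(p: float) -> bool:
    """True if ``p`` denotes the dominance (max-component) metric."""
    return p == DOMINANCE


def _check_p(p: float) -> None:
    if is_dominance(p):
        return
    if not (np.isfinite(p) and p >= 1.0):
        raise ValueError(
            f"Minkowski order must be >= 1 or DOMINANCE, got {p!r}; "
            "p < 1 is not a metric in this family"
        )


def minkowski_distance(a: Sequence[float], b: Sequence[float], p: float) -> float:
    """Minkowski distance of order ``p`` between two equal-length vectors.

    ``p = 1`` gives city-block, ``p = 2`` Euclidean, ``p = DOMINANCE`` the
    dominance (maximum component) distance.
    """
    _check_p(p)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("a and b must be 1-d vectors of identical length >= 1")
    diff = np.abs(a - b)
    if is_dominance(p):
        return float(diff.max())
    return float(np.sum(diff**p) ** (1.0 / p))


@dataclass
class Configuration:
    """Coordinates of ``n`` labelled points in a q-dimensional Minkowski space.

    Parameters
    ----------
    labels : ordered object (party) labels, length n.
    coords : real array of shape (n, q), all finite.
    metric_p : Minkowski order attached to the configuration (>= 1 or
        :data:`DOMINANCE`).
    """

    labels: list[str]
    coords: np.ndarray = field(repr=False)
    metric_p: float = 2.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] < 1:
            raise ValueError("coords must be a 2-d array with q >= 1 columns")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("all coordinates must be finite")
        if len(self.labels) != self.coords.shape[0]:
            raise ValueError("labels length must match number of coordinate rows")
        _check_p(self.metric_p)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]

    def pairwise(self) -> np.ndarray:
        """Symmetric zero-diagonal matrix of pairwise distances."""
        return pairwise_distances(self)


def pairwise_distances(config: Configuration) -> np.ndarray:
    """All pairwise Minkowski distances of a configuration (n x n matrix)."""
    coords = config.coords
    if coords.shape[0] == 1:
        return np.zeros((1, 1))
    if is_dominance(config.metric_p):
        vec = pdist(coords, metric="chebyshev")
    else:
        vec = pdist(coords, metric="minkowski", p=config.metric_p)
    return squareform(vec)


def rotate45_scale(coords: np.ndarray) -> np.ndarray:
    """Rotate every row of an (n, 2) coordinate array by 45 degrees.

    The rotation R satisfies, for any planar x, y::

        d_1(x, y) = sqrt(2) * d_inf(R x, R y)

    i.e. city-block distances equal sqrt(2) times dominance distances of the
    rotated points — the two-dimensional special case of the city-block /
    dominance isometry.  No scaling is applied to the coordinates themselves;
    the sqrt(2) factor belongs to the identity.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("rotate45_scale requires exactly 2 columns (the tested isometry is planar)")
    c = 1.0 / _SQRT2
    rot = np.array([[c, -c], [c, c]])
    return coords @ rot.T
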