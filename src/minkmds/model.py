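"""Model front-end: weakly constrained three-way nonmetric MDS.

Follows the familiar model/results split: build a
:class:`WeaklyConstrainedMDS` from data, call :meth:`~WeaklyConstrainedMDS.fit`,
inspect the returned :class:`~minkmds.results.MDSResults`.

Example
-------
>>> from minkmds.datasets import load_germany_example
>>> from minkmds.model import WeaklyConstrainedMDS
>>> model = WeaklyConstrainedMDS.from_survey(load_germany_example(), metric_p=1, n_dims=2)
>>> res = model.fit(n_starts=50, seed=1)
>>> res.mean_stress < 0.1
True
"""

from __future__ import annotations

from .engine import EngineSettings, fit_three_way
from .results import MDSResults
from .survey import ExpertSurveyData, ThreeWayDissimilarities, profile_dissimilarities


class WeaklyConstrainedMDS:
    """Three-way nonmetric MDS with a weak country-average constraint.

    One configuration is fitted per expert; the penalty
    ``lambda_weight * stress^2(distances, constraint disparities)`` pulls all
    of an expert panel's configurations toward the structure of the average
    dissimilarity matrix without hard-restricting any of them.

    Parameters
    ----------
    dissimilarities : ThreeWayDissimilarities
        Per-expert party dissimilarity matrices plus their average.
    metric_p : Minkowski order of the fitted space; 1 (city-block) and
        2 (Euclidean) are the supported comparisons.
    n_dims : dimensionality q of the fitted configurations.
    lambda_weight : weight of the constraint penalty (default 100).
    settings : optional :class:`~minkmds.engine.EngineSettings`.
    """

    def __init__(
        self,
        dissimilarities: ThreeWayDissimilarities,
        metric_p: float = 1.0,
        n_dims: int = 2,
        lambda_weight: float = 100.0,
        settings: EngineSettings | None = None,
    ) -> None:
        self.dissimilarities = dissimilarities
        self.metric_p = float(metric_p)
        self.n_dims = int(n_dims)
        self.lambda_weight = float(lambda_weight)
        self.settings = settings or EngineSettings()

    @classmethod
    def from_survey(
        cls,
        survey: ExpertSurveyData,
        metric_p: float = 1.0,
        n_dims: int = 2,
        lambda_weight: float = 100.0,
        profile_p: float = 2.0,
        settings: EngineSettings | None = None,
    ) -> "WeaklyConstrainedMDS":
        """Build the model straight from a ratings survey.

        ``profile_p`` is the Minkowski order used to turn policy-rating
        profiles into party dissimilarities (ideology excluded).
        """
        data = profile_dissimilarities(survey, p_in=profile_p)
        return cls(
            data,
            metric_p=metric_p,
            n_dims=n_dims,
            lambda_weight=lambda_weight,
            settings=settings,
        )

    def fit(
        self,
        n_starts: int = 50,
        seed: int | None = None,
        candidate_configs=None,
    ) -> MDSResults:
        """Run the multistart majorization fit and return the results."""
        return fit_three_way(
            self.dissimilarities,
            p=self.metric_p,
            q=self.n_dims,
            lambda_weight=self.lambda_weight,
            n_starts=n_starts,
            seed=seed,
            settings=self.settings,
            candidate_configs=candidate_configs,
        )
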