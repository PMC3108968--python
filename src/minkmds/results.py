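"""Results containers for three-way weakly constrained MDS fits."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .metrics import Configuration

if TYPE_CHECKING:  # pragma: no cover
    from .engine import EngineSettings, FitTrace


@dataclass
class StartRecord:
    """Outcome of one optimizer start for one expert."""

    name: str
    stress: float
    loss: float
    config: Configuration
    trace: "FitTrace"
    degenerate: bool = False


@dataclass
class ExpertFit:
    """Best configuration and diagnostics for a single expert."""

    expert: str
    config: Configuration
    stress: float
    loss: float
    best_start: str
    starts: list[StartRecord] = field(repr=False, default_factory=list)
    degenerate: bool = False


@dataclass
class MDSResults:
    """Fitted per-expert configurations with stress diagnostics.

    ``stress_per_expert`` holds exact Kruskal stress-1 values (the optimizer
    minimized the penalized smoothed loss, but stress is what is reported);
    ``mean_stress``/``stress_se`` summarize them at the country level.  No
    post-hoc rotation is applied to the configurations.
    """

    expert_fits: list[ExpertFit]
    metric_p: float
    n_dims: int
    lambda_weight: float
    n_starts: int
    seed: int | None
    settings: "EngineSettings"
    parties: list[str]

    @property
    def experts(self) -> list[str]:
        return [f.expert for f in self.expert_fits]

    @property
    def configurations(self) -> list[Configuration]:
        return [f.config for f in self.expert_fits]

    @property
    def per_expert_configs(self) -> list[Configuration]:
        return self.configurations

    @property
    def stress_per_expert(self) -> np.ndarray:
        return np.array([f.stress for f in self.expert_fits])

    @property
    def loss_per_expert(self) -> np.ndarray:
        return np.array([f.loss for f in self.expert_fits])

    @property
    def mean_stress(self) -> float:
        return float(self.stress_per_expert.mean())

    @property
    def stress_se(self) -> float:
        """Standard error over experts: sample SD / sqrt(n_experts)."""
        s = self.stress_per_expert
        if s.size < 2:
            return float("nan")
        return float(s.std(ddof=1) / np.sqrt(s.size))

    @property
    def n_experts(self) -> int:
        return len(self.expert_fits)

    @property
    def loss_trace(self) -> list["FitTrace"]:
        """Trace of the winning start per expert."""
        out = []
        for f in self.expert_fits:
            rec = next(r for r in f.starts if r.name == f.best_start)
            out.append(rec.trace)
        return out

    def stress_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "expert": self.experts,
                "metric_p": self.metric_p,
                "n_dims": self.n_dims,
                "stress": self.stress_per_expert,
                "loss": self.loss_per_expert,
                "best_start": [f.best_start for f in self.expert_fits],
                "degenerate": [f.degenerate for f in self.expert_fits],
            }
        )

    def coordinates_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.expert_fits:
            for i, party in enumerate(f.config.labels):
                row = {"expert": f.expert, "party": party}
                for m in range(f.config.n_dims):
                    row[f"dim{m + 1}"] = f.config.coords[i, m]
                rows.append(row)
        return pd.DataFrame(rows)

    def ideology_correlations(self, ideology: np.ndarray):
        """Per-expert Kendall tau of each dimension against ideology scores.

        Delegates to :func:`minkmds.ideology.dimension_ideology_tests`;
        requires a city-block (p = 1) fit.
        """
        from .ideology import dimension_ideology_tests

        return dimension_ideology_tests(self, ideology)

    def summary(self) -> SimpleTable:
        metric_name = {1.0: "city-block", 2.0: "Euclidean"}.get(self.metric_p, f"p={self.metric_p}")
        header = ["expert", "stress-1", "penalized loss", "best start", "degenerate"]
        rows = [
            [f.expert, f"{f.stress:.4f}", f"{f.loss:.4f}", f.best_start, str(f.degenerate)]
            for f in self.expert_fits
        ]
        rows.append(
            ["mean +/- SE", f"{self.mean_stress:.4f} +/- {self.stress_se:.4f}", "", "", ""]
        )
        title = (
            f"Weakly constrained nonmetric MDS ({metric_name}, q={self.n_dims}, "
            f"lambda={self.lambda_weight:g}, starts={self.n_starts})"
        )
        return SimpleTable(rows, headers=header, title=title)

    def __str__(self) -> str:
        return str(self.summary())
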