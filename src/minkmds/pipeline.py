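"""Analysis pipeline: dimensionality scan, metric comparison, full reports.

Orchestrates the three headline analyses on one country's three-way data:
(1) stress versus dimensionality q = 1..4 per Minkowski metric, with the
conventional mean-stress < 0.1 good-fit flag; (2) city-block versus Euclidean
mean (+/- SE) stress at q = 2; (3) per-expert Kendall-tau correlation of the
city-block dimensions with the ideology scale.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .engine import EngineSettings, fit_three_way
from .ideology import dimension_ideology_tests, tau_results_frame
from .results import MDSResults
from .survey import ThreeWayDissimilarities, profile_dissimilarities, read_survey_long

GOOD_FIT_THRESHOLD = 0.1


@dataclass
class ScanResult:
    """Stress indexed by (metric p, dimensionality q, expert).

    ``stress_table`` is long-format; ``country_summary`` carries the
    across-expert mean, standard error and the mean-stress < 0.1 good-fit
    flag per (p, q).  ``fits`` keeps the underlying :class:`MDSResults`.
    """

    stress_table: pd.DataFrame
    country_summary: pd.DataFrame
    fits: dict[tuple[float, int], MDSResults] = field(repr=False, default_factory=dict)

    @staticmethod
    def summarize(stress_table: pd.DataFrame) -> pd.DataFrame:
        rows = []
        for (p, q), grp in stress_table.groupby(["metric_p", "n_dims"], sort=True):
            s = grp["stress"].to_numpy()
            se = float(s.std(ddof=1) / np.sqrt(s.size)) if s.size > 1 else float("nan")
            rows.append(
                {
                    "metric_p": p,
                    "n_dims": q,
                    "mean_stress": float(s.mean()),
                    "se_stress": se,
                    "good_fit": bool(s.mean() < GOOD_FIT_THRESHOLD),
                }
            )
        return pd.DataFrame(rows)

    def merge(self, other: "ScanResult") -> "ScanResult":
        table = pd.concat([self.stress_table, other.stress_table], ignore_index=True)
        fits = {**self.fits, **other.fits}
        return ScanResult(table, ScanResult.summarize(table), fits)


def _pad_configs(fit: MDSResults) -> list[list[np.ndarray]]:
    """Best q-dim configs padded with one zero column (distance-preserving)."""
    return [[np.hstack([ef.config.coords, np.zeros((ef.config.coords.shape[0], 1))])]
            for ef in fit.expert_fits]


def dimension_scan(
    data: ThreeWayDissimilarities,
    p: float,
    q_range: Sequence[int],
    lambda_weight: float = 100.0,
    n_starts: int = 50,
    seed: int | None = None,
    settings: EngineSettings | None = None,
) -> ScanResult:
    """Fit at every q in ascending ``q_range`` and tabulate stress.

    Consecutive dimensionalities share starts: the best (q-1)-solution padded
    with a zero column joins the candidate set at q, so per-expert best
    stress is non-increasing in q by construction.
    """
    q_range = list(q_range)
    if not q_range:
        raise ValueError("q_range must be non-empty")
    if any(b <= a for a, b in zip(q_range, q_range[1:])):
        raise ValueError("q_range must be strictly ascending")
    rows = []
    fits: dict[tuple[float, int], MDSResults] = {}
    prev_fit: MDSResults | None = None
    for q in q_range:
        candidates = None
        if prev_fit is not None and q == prev_fit.n_dims + 1:
            candidates = _pad_configs(prev_fit)
        fit = fit_three_way(
            data,
            p=p,
            q=q,
            lambda_weight=lambda_weight,
            n_starts=n_starts,
            seed=seed,
            settings=settings,
            candidate_configs=candidates,
        )
        fits[(p, q)] = fit
        for ef in fit.expert_fits:
            rows.append(
                {"metric_p": p, "n_dims": q, "expert": ef.expert, "stress": ef.stress}
            )
        prev_fit = fit
    table = pd.DataFrame(rows)
    return ScanResult(table, ScanResult.summarize(table), fits)


@dataclass
class MetricComparison:
    """Mean +/- SE stress per metric at fixed q, and the sign of p1 - p2."""

    n_dims: int
    per_expert: pd.DataFrame
    summary: pd.DataFrame
    difference_sign: int  # sign(mean stress p=1 minus mean stress p=2)

    def frame(self) -> pd.DataFrame:
        return self.summary


def metric_comparison(
    data: ThreeWayDissimilarities,
    q: int = 2,
    metrics: Sequence[float] = (1.0, 2.0),
    lambda_weight: float = 100.0,
    n_starts: int = 50,
    seed: int | None = None,
    settings: EngineSettings | None = None,
    fits: dict[tuple[float, int], MDSResults] | None = None,
) -> MetricComparison:
    """Compare mean (+/- SE) stress across Minkowski metrics at one q.

    ``fits`` may supply already-computed :class:`MDSResults` (e.g. from a
    dimension scan) keyed by (p, q); missing ones are fitted here.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    rows = []
    summary_rows = []
    means = {}
    for p in metrics:
        fit = (fits or {}).get((p, q))
        if fit is None:
            fit = fit_three_way(
                data, p=p, q=q, lambda_weight=lambda_weight,
                n_starts=n_starts, seed=seed, settings=settings,
            )
        for ef in fit.expert_fits:
            rows.append({"metric_p": p, "expert": ef.expert, "stress": ef.stress})
        means[p] = fit.mean_stress
        summary_rows.append(
            {"metric_p": p, "n_dims": q, "mean_stress": fit.mean_stress, "se_stress": fit.stress_se}
        )
    diff = 0
    if 1.0 in means and 2.0 in means:
        diff = int(np.sign(means[1.0] - means[2.0]))
    return MetricComparison(
        n_dims=q,
        per_expert=pd.DataFrame(rows),
        summary=pd.DataFrame(summary_rows),
        difference_sign=diff,
    )


@dataclass
class PipelineConfig:
    """Everything needed to run one country end to end."""

    policies: list[str]
    ideology_column: str
    country_label: str | None = None
    profile_p: float = 2.0
    metrics: tuple[float, ...] = (1.0, 2.0)
    q_range: tuple[int, ...] = (1, 2, 3, 4)
    lambda_weight: float = 100.0
    n_starts: int = 50
    seed: int = 0
    engine: EngineSettings = field(default_factory=EngineSettings)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        engine = EngineSettings(**raw.pop("engine", {}))
        raw["metrics"] = tuple(float(m) for m in raw.get("metrics", (1.0, 2.0)))
        raw["q_range"] = tuple(int(q) for q in raw.get("q_range", (1, 2, 3, 4)))
        return cls(engine=engine, **raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["metrics"] = list(self.metrics)
        out["q_range"] = list(self.q_range)
        return out


def run_country(survey_path: str | Path, config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Read -> dissimilarities -> scans -> comparison -> ideology -> report.

    Writes machine-readable CSV/JSON results plus a plain-text log; every
    setting and the seed are recorded so a rerun is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    stage = "read"
    try:
        survey = read_survey_long(
            survey_path, config.policies, config.ideology_column,
            country_label=config.country_label,
        )
        log(f"read survey: {survey.n_experts} experts, {survey.n_parties} parties, "
            f"{survey.n_policies} policies ({survey.country_label})")

        stage = "dissimilarities"
        data = profile_dissimilarities(survey, p_in=config.profile_p)
        log(f"profile dissimilarities at p_in={config.profile_p}")

        stage = "dimension_scan"
        scan: ScanResult | None = None
        for p in config.metrics:
            part = dimension_scan(
                data, p=p, q_range=config.q_range,
                lambda_weight=config.lambda_weight, n_starts=config.n_starts,
                seed=config.seed, settings=config.engine,
            )
            scan = part if scan is None else scan.merge(part)
            log(f"dimension scan at p={p}: q in {list(config.q_range)}")

        stage = "metric_comparison"
        comparison_q = 2 if 2 in config.q_range else config.q_range[0]
        comparison = metric_comparison(
            data, q=comparison_q, metrics=config.metrics,
            lambda_weight=config.lambda_weight, n_starts=config.n_starts,
            seed=config.seed, settings=config.engine, fits=scan.fits,
        )
        log(f"metric comparison at q={comparison_q}: "
            f"sign(mean p=1 - mean p=2) = {comparison.difference_sign}")

        stage = "ideology_correlation"
        tau_frame = pd.DataFrame()
        tau_summary: dict[str, float] = {}
        cb_fit = scan.fits.get((1.0, comparison_q))
        if cb_fit is not None:
            tau_results, tau_summary = dimension_ideology_tests(cb_fit, survey.ideology)
            tau_frame = tau_results_frame(tau_results)
            log(f"ideology correlation: {tau_summary['n_any_significant']:.0f}/"
                f"{tau_summary['n_experts']:.0f} experts with >=1 significant dimension")

        stage = "report"
        country = survey.country_label
        stress_table = scan.stress_table.copy()
        stress_table.insert(0, "country", country)
        summary = scan.country_summary.copy()
        summary.insert(0, "country", country)

        paths = {
            "stress": out_dir / "stress_long.csv",
            "summary": out_dir / "stress_summary.csv",
            "comparison": out_dir / "metric_comparison.csv",
            "tau": out_dir / "ideology_tau.csv",
            "metadata": out_dir / "run_metadata.json",
            "log": out_dir / "run.log",
        }
        stress_table.to_csv(paths["stress"], index=False)
        summary.to_csv(paths["summary"], index=False)
        comparison.summary.to_csv(paths["comparison"], index=False)
        tau_frame.to_csv(paths["tau"], index=False)
        metadata = {
            "country": country,
            "config": config.to_dict(),
            "tau_summary": tau_summary,
            "minkmds_version": __version__,
            "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        }
        paths["metadata"].write_text(json.dumps(metadata, indent=2, sort_keys=True))
        paths["log"].write_text("\n".join(log_lines) + "\n")
        return paths
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {err}") from err
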