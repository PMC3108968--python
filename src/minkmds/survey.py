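"""Three-way expert survey data and party-by-party dissimilarity construction.

The data model mirrors the expert-survey design: each expert rates every
party on K policy scales (integers 1-20) plus one left-right ideology scale,
yielding a complete (experts x parties x policies) ratings tensor.  Per-expert
dissimilarity matrices between parties are derived as Minkowski distances
between policy-rating profiles; their across-expert average serves as the weak
constraint matrix of the three-way MDS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .metrics import DOMINANCE, is_dominance

RATING_MIN = 1
RATING_MAX = 20


class SurveyValidationError(ValueError):
    """Base class for survey ingestion/validation failures."""


class DuplicateRowError(SurveyValidationError):
    pass


class MissingCellError(SurveyValidationError):
    pass


class NonIntegerRatingError(SurveyValidationError):
    pass


class RatingRangeError(SurveyValidationError):
    pass


class InconsistentPartySetError(SurveyValidationError):
    pass


@dataclass
class ExpertSurveyData:
    """Complete three-way ratings tensor plus per-(expert, party) ideology.

    ratings has shape (n_experts, n_parties, n_policies); ideology has shape
    (n_experts, n_parties).  All entries are integers in [1, 20]; party and
    policy orderings are shared by every expert.
    """

    country_label: str
    experts: list[str]
    parties: list[str]
    policies: list[str]
    ratings: np.ndarray = field(repr=False)
    ideology: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.experts = [str(e) for e in self.experts]
        self.parties = [str(p) for p in self.parties]
        self.policies = [str(p) for p in self.policies]
        self.ratings = np.asarray(self.ratings)
        self.ideology = np.asarray(self.ideology)
        if len(self.policies) < 1:
            raise SurveyValidationError("at least one policy scale is required")
        shape = (len(self.experts), len(self.parties), len(self.policies))
        if self.ratings.shape != shape:
            raise SurveyValidationError(
                f"ratings shape {self.ratings.shape} does not match "
                f"(experts, parties, policies) = {shape}"
            )
        if self.ideology.shape != shape[:2]:
            raise SurveyValidationError(
                f"ideology shape {self.ideology.shape} does not match "
                f"(experts, parties) = {shape[:2]}"
            )
        for name, arr in (("rating", self.ratings), ("ideology", self.ideology)):
            if not np.issubdtype(arr.dtype, np.integer):
                as_float = np.asarray(arr, dtype=float)
                if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                    raise NonIntegerRatingError(f"{name} values must all be integers")
                arr = as_float.astype(np.int64)
            if arr.min() < RATING_MIN or arr.max() > RATING_MAX:
                raise RatingRangeError(
                    f"{name} values must lie in [{RATING_MIN}, {RATING_MAX}]"
                )
            if name == "rating":
                self.ratings = arr.astype(np.int64)
            else:
                self.ideology = arr.astype(np.int64)

    @property
    def n_experts(self) -> int:
        return len(self.experts)

    @property
    def n_parties(self) -> int:
        return len(self.parties)

    @property
    def n_policies(self) -> int:
        return len(self.policies)

    def to_frame(self, ideology_column: str = "Ideology") -> pd.DataFrame:
        """Long-format DataFrame: one row per (expert, party)."""
        rows = []
        for e_idx, expert in enumerate(self.experts):
            for p_idx, party in enumerate(self.parties):
                row = {"Expert": expert, "Party": party}
                row.update(
                    {pol: int(self.ratings[e_idx, p_idx, k]) for k, pol in enumerate(self.policies)}
                )
                row[ideology_column] = int(self.ideology[e_idx, p_idx])
                rows.append(row)
        return pd.DataFrame(rows)


def read_survey_long(
    path: str | Path,
    policy_columns: Sequence[str],
    ideology_column: str,
    country_label: str | None = None,
) -> ExpertSurveyData:
    """Read a long-format survey CSV (one row per (expert, party)).

    The file must contain columns ``Expert``, ``Party``, the named policy
    columns and the ideology column; every (expert, party) pair appears
    exactly once and every expert rates the same party set.  Experts keep
    file order; parties keep first-appearance order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    policy_columns = list(policy_columns)
    needed = ["Expert", "Party", *policy_columns, ideology_column]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise SurveyValidationError(f"{path}: missing required columns {missing}")

    df = df.copy()
    df["Expert"] = df["Expert"].astype(str)
    df["Party"] = df["Party"].astype(str)

    dup_mask = df.duplicated(subset=["Expert", "Party"], keep=False)
    if dup_mask.any():
        row = df[dup_mask].iloc[0]
        raise DuplicateRowError(
            f"{path}: duplicated (expert, party) pair "
            f"({row['Expert']!r}, {row['Party']!r}) at file row {df[dup_mask].index[0] + 2}"
        )

    value_cols = [*policy_columns, ideology_column]
    for col in value_cols:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna()
        if bad.any():
            raise NonIntegerRatingError(
                f"{path}: non-numeric value {df.loc[bad, col].iloc[0]!r} in column "
                f"{col!r} at file row {df.index[bad][0] + 2}"
            )
        nonint = values != np.round(values)
        if nonint.any():
            raise NonIntegerRatingError(
                f"{path}: non-integer rating {values[nonint].iloc[0]} in column "
                f"{col!r} at file row {df.index[nonint][0] + 2}"
            )
        out = (values < RATING_MIN) | (values > RATING_MAX)
        if out.any():
            raise RatingRangeError(
                f"{path}: rating {int(values[out].iloc[0])} outside "
                f"[{RATING_MIN}, {RATING_MAX}] in column {col!r} at file row "
                f"{df.index[out][0] + 2}"
            )
        df[col] = values.astype(np.int64)

    experts = list(dict.fromkeys(df["Expert"]))
    parties = list(dict.fromkeys(df["Party"]))

    party_set = set(parties)
    for expert in experts:
        sub = df[df["Expert"] == expert]
        have = set(sub["Party"])
        if have != party_set:
            extra = have - party_set
            lacking = party_set - have
            if extra:
                raise InconsistentPartySetError(
                    f"{path}: expert {expert!r} rates parties {sorted(extra)} "
                    "not rated by earlier experts"
                )
            raise MissingCellError(
                f"{path}: expert {expert!r} is missing rows for parties {sorted(lacking)}"
            )

    n_e, n_p, n_k = len(experts), len(parties), len(policy_columns)
    ratings = np.zeros((n_e, n_p, n_k), dtype=np.int64)
    ideology = np.zeros((n_e, n_p), dtype=np.int64)
    e_index = {e: i for i, e in enumerate(experts)}
    p_index = {p: i for i, p in enumerate(parties)}
    for _, row in df.iterrows():
        i, j = e_index[row["Expert"]], p_index[row["Party"]]
        ratings[i, j] = [row[c] for c in policy_columns]
        ideology[i, j] = row[ideology_column]

    return ExpertSurveyData(
        country_label=country_label or path.stem,
        experts=experts,
        parties=parties,
        policies=policy_columns,
        ratings=ratings,
        ideology=ideology,
    )


def write_survey_long(
    data: ExpertSurveyData, path: str | Path, ideology_column: str = "Ideology"
) -> Path:
    """Write the long CSV layout read by :func:`read_survey_long`."""
    path = Path(path)
    data.to_frame(ideology_column=ideology_column).to_csv(path, index=False)
    return path


def _check_square(mat: np.ndarray, what: str, atol: float = 1e-10) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{what} must be square, got shape {mat.shape}")
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{what} must be finite")
    if np.any(mat < -atol):
        raise ValueError(f"{what} must be nonnegative")
    if not np.allclose(mat, mat.T, atol=atol):
        raise ValueError(f"{what} must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=atol):
        raise ValueError(f"{what} must have a zero diagonal")
    return mat


def average_dissimilarity(matrices: Sequence[np.ndarray]) -> np.ndarray:
    """Element-wise mean of same-shaped symmetric zero-diagonal matrices."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("average_dissimilarity requires at least one matrix")
    checked = [_check_square(m, "dissimilarity matrix") for m in matrices]
    shape = checked[0].shape
    for m in checked[1:]:
        if m.shape != shape:
            raise ValueError("all matrices must share the same shape")
    return np.mean(checked, axis=0)


@dataclass
class ThreeWayDissimilarities:
    """One symmetric party dissimilarity matrix per expert plus their average.

    ``matrices`` has shape (n_experts, n_parties, n_parties); ``constraint``
    is the element-wise mean over experts and plays the role of the weak
    constraint target in the penalized MDS loss.  ``profile_metric_p`` records
    the Minkowski order used on the policy profiles.
    """

    parties: list[str]
    matrices: np.ndarray = field(repr=False)
    constraint: np.ndarray = field(repr=False)
    profile_metric_p: float = 2.0
    experts: list[str] | None = None

    def __post_init__(self) -> None:
        self.matrices = np.asarray(self.matrices, dtype=float)
        if self.matrices.ndim != 3:
            raise ValueError("matrices must have shape (n_experts, n, n)")
        n = len(self.parties)
        if n < 3:
            raise ValueError("at least 3 parties are required (MDS is ill-posed below that)")
        if self.matrices.shape[1:] != (n, n):
            raise ValueError("matrix dimensions must match the party list")
        for k in range(self.matrices.shape[0]):
            _check_square(self.matrices[k], f"expert matrix {k}")
        self.constraint = _check_square(self.constraint, "constraint matrix")
        if not np.allclose(self.constraint, self.matrices.mean(axis=0), atol=1e-8):
            raise ValueError("constraint must equal the element-wise mean of the expert matrices")
        if self.experts is None:
            self.experts = [f"expert_{k + 1}" for k in range(self.matrices.shape[0])]
        if len(self.experts) != self.matrices.shape[0]:
            raise ValueError("experts length must match the number of matrices")
        if not (is_dominance(self.profile_metric_p) or self.profile_metric_p >= 1.0):
            raise ValueError("profile_metric_p must be >= 1 or DOMINANCE")

    @property
    def n_experts(self) -> int:
        return self.matrices.shape[0]

    @property
    def n_parties(self) -> int:
        return len(self.parties)

    @classmethod
    def from_matrices(
        cls,
        parties: Sequence[str],
        matrices: Sequence[np.ndarray],
        profile_metric_p: float = 2.0,
        experts: Sequence[str] | None = None,
    ) -> "ThreeWayDissimilarities":
        stacked = np.asarray([np.asarray(m, dtype=float) for m in matrices])
        return cls(
            parties=list(parties),
            matrices=stacked,
            constraint=average_dissimilarity(list(stacked)),
            profile_metric_p=profile_metric_p,
            experts=list(experts) if experts is not None else None,
        )


def profile_dissimilarities(data: ExpertSurveyData, p_in: float = 2.0) -> ThreeWayDissimilarities:
    """Per-expert Minkowski distances between party policy-rating profiles.

    The ideology column never enters the profiles; it is reserved for the
    correlation stage.  ``p_in`` >= 1 (or :data:`DOMINANCE`) selects the
    profile metric; the default Euclidean profile distance is conventional,
    and the downstream nonmetric fit depends only on rank order.
    """
    if not (is_dominance(p_in) or p_in >= 1.0):
        raise ValueError("p_in must be >= 1 or DOMINANCE")
    if data.n_parties < 3:
        raise ValueError("at least 3 parties are required (MDS is ill-posed below that)")
    mats = []
    for k in range(data.n_experts):
        profiles = data.ratings[k].astype(float)
        if is_dominance(p_in):
            vec = pdist(profiles, metric="chebyshev")
        else:
            vec = pdist(profiles, metric="minkowski", p=p_in)
        mats.append(squareform(vec))
    return ThreeWayDissimilarities.from_matrices(
        parties=data.parties,
        matrices=mats,
        profile_metric_p=p_in,
        experts=data.experts,
    )
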