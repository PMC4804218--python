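"""Per-fold within-fold TM_max profiles and query-fold similarity statistics.

A fold member's within-fold TM_max-score is the highest TM-score between it
and any other member of its fold; the vector of these scores (one per
member) is the fold's structural-heterogeneity profile.  Homogeneous folds
have within-fold TM_max means near 1 and small spread; heterogeneous folds
have lower means and larger spread, and it is the latter that attract
queries under continuity-aware classification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SimilarityMatrix

__all__ = [
    "FoldProfile",
    "within_fold_tmmax",
    "build_profile",
    "build_profiles",
    "query_fold_statistic",
    "fold_closeness",
    "heterogeneity_table",
    "MIN_FOLD_SIZE",
]

# Folds below this size carry too little information for the within-fold
# TM_max distribution to be estimated; they are excluded from classification.
MIN_FOLD_SIZE = 25


@dataclass(frozen=True)
class FoldProfile:
    """Within-fold TM_max profile of one fold."""

    fold_id: str
    member_ids: tuple[str, ...]
    x: np.ndarray  # within-fold TM_max, one per member
    mode: str  # local | global

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        if x.shape[0] != len(self.member_ids):
            raise ValueError("x length must match member count")
        if x.shape[0] < 2:
            raise ValueError("a fold profile needs at least 2 members")
        if (x <= 0).any() or (x > 1).any():
            raise ValueError("within-fold TM_max scores must lie in (0, 1]")
        object.__setattr__(self, "x", x)

    @property
    def n(self) -> int:
        return len(self.member_ids)

    @property
    def mean_x(self) -> float:
        return float(self.x.mean())

    @property
    def sd_x(self) -> float:
        """Sample standard deviation (N-1 denominator)."""
        return float(self.x.std(ddof=1))

    @property
    def range_x(self) -> float:
        """R = max(x) - min(x); sets the scale of the mixture priors."""
        return float(self.x.max() - self.x.min())


def within_fold_tmmax(matrix: SimilarityMatrix, members: Sequence[str]) -> np.ndarray:
    """Within-fold TM_max for each member: max score to any *other* member."""
    members = list(members)
    if len(members) < 2:
        raise ValueError("within-fold TM_max needs at least 2 members")
    sub = matrix.submatrix(members)
    if np.isnan(sub).any():
        i, j = np.argwhere(np.isnan(sub))[0]
        raise KeyError(f"missing pairwise score ({members[i]}, {members[j]})")
    np.fill_diagonal(sub, -np.inf)  # exclude self-scores
    return sub.max(axis=1)


def build_profile(
    matrix: SimilarityMatrix,
    fold_id: str,
    members: Iterable[str],
    min_fold_size: int = MIN_FOLD_SIZE,
) -> FoldProfile | None:
    """Build a fold's profile, or None (with a warning) below the size cut."""
    members = sorted(members)
    if len(members) < min_fold_size:
        warnings.warn(
            f"fold {fold_id}: {len(members)} members < min_fold_size={min_fold_size}; excluded",
            stacklevel=2,
        )
        return None
    x = within_fold_tmmax(matrix, members)
    return FoldProfile(fold_id, tuple(members), x, matrix.mode)


def build_profiles(
    matrix: SimilarityMatrix,
    folds: dict[str, list[str]],
    min_fold_size: int = MIN_FOLD_SIZE,
) -> dict[str, FoldProfile]:
    """Profiles for every fold that passes the size cut, keyed by fold id."""
    out: dict[str, FoldProfile] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for fold_id in sorted(folds):
            prof = build_profile(matrix, fold_id, folds[fold_id], min_fold_size)
            if prof is not None:
                out[fold_id] = prof
    return out


def query_fold_statistic(
    matrix: SimilarityMatrix,
    query_id: str,
    members: Sequence[str],
    stat: str = "max",
) -> tuple[float, str | None]:
    """Query-fold similarity: a statistic of the query's scores to members.

    Returns ``(value, partner_id)`` where ``partner_id`` is the member
    achieving the maximum (lexicographically smallest on ties) when
    ``stat='max'``, else None.  The query must not be a fold member — hold
    it out first.
    """
    members = list(members)
    if query_id in members:
        raise ValueError(f"query {query_id} is a member of the fold; hold it out first")
    scores = matrix.scores_to(query_id, members)
    if stat == "max":
        best = scores.max()
        partner = min(m for m, s in zip(members, scores) if s == best)
        return float(best), partner
    if stat == "mean":
        return float(scores.mean()), None
    if stat == "median":
        return float(np.median(scores)), None
    raise ValueError(f"unknown statistic {stat!r}")


def fold_closeness(
    matrix: SimilarityMatrix,
    members_a: Sequence[str],
    members_b: Sequence[str],
) -> float:
    """Closeness of two folds: the highest score over all cross pairs."""
    set_a, set_b = set(members_a), set(members_b)
    if set_a & set_b:
        raise ValueError(f"folds overlap: {sorted(set_a & set_b)[:5]}")
    best = -np.inf
    for a in members_a:
        best = max(best, matrix.scores_to(a, list(members_b)).max())
    return float(best)


def heterogeneity_table(profiles: Iterable[FoldProfile]) -> pd.DataFrame:
    """Per-fold heterogeneity summary: N, mean and SD of within-fold TM_max."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    rows = [
        {"fold_id": p.fold_id, "N": p.n, "mean_x": p.mean_x, "sd_x": p.sd_x}
        for p in profiles
    ]
    return pd.DataFrame(rows).sort_values("fold_id").reset_index(drop=True)
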