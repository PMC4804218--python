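"""Agreement metrics between classifications and fold-attraction analyses.

A "reclassified" query is one whose assignment by a method differs from
its original fold.  The fold attracting a reclassified query is the fold
it was assigned to; correlating attraction counts against fold properties
(within-fold TM_max mean/SD, fold size) quantifies which folds act as
sinks under continuity-aware classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import QueryResult
from .profiles import FoldProfile

__all__ = [
    "ComparisonSummary",
    "reclassification_rate",
    "heterogeneity_attraction_correlation",
    "method_overlap",
    "relative_length_difference",
    "rank_groups",
]


@dataclass
class ComparisonSummary:
    """Disagreement between a method's assignments and the original folds."""

    method: str
    n_queries: int
    n_disagreements: int
    attraction: dict[str, int]  # fold -> reclassified queries assigned to it

    @property
    def disagreement_fraction(self) -> float:
        return self.n_disagreements / self.n_queries


def reclassification_rate(results: Iterable[QueryResult], method: str) -> ComparisonSummary:
    """Count queries whose assignment differs from their original fold."""
    results = list(results)
    if not results:
        raise ValueError("no query results")
    attraction: dict[str, int] = {}
    n_bad = 0
    for r in results:
        if r.original_fold is None:
            raise ValueError(f"query {r.query_id} has no original fold")
        assigned = r.assigned[method]
        if assigned != r.original_fold:
            n_bad += 1
            attraction[assigned] = attraction.get(assigned, 0) + 1
    return ComparisonSummary(method, len(results), n_bad, attraction)


def heterogeneity_attraction_correlation(
    profiles: Mapping[str, FoldProfile],
    summary: ComparisonSummary,
    prop: str = "sd_x",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman correlation between a fold property and attraction count.

    ``prop`` is one of ``mean_x``, ``sd_x`` or ``size``.  Folds that
    attract no reclassified queries enter with count 0.  The two-sided
    p-value is computed by seeded label permutation (>= 10,000 shuffles).
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 folds")
    fold_ids = sorted(profiles)
    getters = {
        "mean_x": lambda p: p.mean_x,
        "sd_x": lambda p: p.sd_x,
        "size": lambda p: p.n,
    }
    if prop not in getters:
        raise ValueError(f"unknown property {prop!r}")
    x = np.array([getters[prop](profiles[f]) for f in fold_ids], dtype=float)
    y = np.array([summary.attraction.get(f, 0) for f in fold_ids], dtype=float)
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("constant property or attraction vector: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm_rho = stats.spearmanr(x, rng.permutation(y)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            hits += 1
    p = (hits + 1) / (n_permutations + 1)
    return rho, float(p)


def method_overlap(
    results_a: Sequence[QueryResult],
    results_b: Sequence[QueryResult],
    method_a: str,
    method_b: str,
) -> dict:
    """Three-way consistency of two methods against the original folds.

    Returns the Venn-style cell counts plus ``same_way_fraction``: among
    A's reclassifications, the fraction reclassified to the same fold by B.
    """
    by_id_b = {r.query_id: r for r in results_b}
    if set(by_id_b) != {r.query_id for r in results_a}:
        raise ValueError("result sets cover different queries")
    cells = {
        "all_agree": 0,  # A = B = original
        "ab_agree_not_original": 0,  # A = B != original
        "a_original_not_b": 0,  # A = original != B
        "b_original_not_a": 0,  # B = original != A
        "all_differ": 0,  # A != B, neither = original
    }
    n_a_reclass = 0
    n_same_way = 0
    for ra in results_a:
        rb = by_id_b[ra.query_id]
        orig = ra.original_fold
        a, b = ra.assigned[method_a], rb.assigned[method_b]
        if a == b == orig:
            cells["all_agree"] += 1
        elif a == b:
            cells["ab_agree_not_original"] += 1
        elif a == orig:
            cells["a_original_not_b"] += 1
        elif b == orig:
            cells["b_original_not_a"] += 1
        else:
            cells["all_differ"] += 1
        if a != orig:
            n_a_reclass += 1
            if b == a:
                n_same_way += 1
    cells["n_queries"] = len(results_a)
    cells["same_way_fraction"] = n_same_way / n_a_reclass if n_a_reclass else float("nan")
    return cells


def relative_length_difference(l_query: int, l_partner: int) -> float:
    """|L_query - L_partner| divided by the shorter length."""
    if l_query < 1 or l_partner < 1:
        raise ValueError("lengths must be >= 1")
    return abs(l_query - l_partner) / min(l_query, l_partner)


def rank_groups(a: Sequence[float], b: Sequence[float], paired: bool = False):
    """Convenience nonparametric group comparison.

    Wilcoxon signed-rank when ``paired``, else Mann-Whitney U; returns the
    scipy result object.
    """
    if paired:
        return stats.wilcoxon(np.asarray(a) - np.asarray(b))
    return stats.mannwhitneyu(a, b, alternative="two-sided")
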