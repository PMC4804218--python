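"""Fold assignment of query domains: TM_max/TM_mean/TM_median, CEP and C3P.

A query is compared against every profiled fold.  The plain similarity
methods assign it to the fold with the highest query-fold statistic.  The
cumulative empirical probability (CEP) instead asks how well the query-fold
TM_max-score *fits* the fold's own within-fold TM_max distribution: CEP is
the fraction of within-fold TM_max-scores at or below the query-fold
TM_max-score, so a structurally heterogeneous fold (wide distribution,
low scores in its tail) accommodates a mediocre query more readily than a
tight homogeneous fold does.  C3P replaces the empirical distribution with
the posterior predictive of a Bayesian Gaussian mixture (see
:mod:`foldcep.mixture`).

The repeated hold-out experiment mirrors the evaluation protocol used for
curated hierarchies: sample 10% of each large fold's members as queries,
rebuild the fold profiles without them, classify, and measure disagreement
with the original assignment, repeated over independent query sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ClassificationTable, SimilarityMatrix
from .profiles import FoldProfile, build_profiles, query_fold_statistic

__all__ = [
    "QueryResult",
    "HoldoutResult",
    "cep",
    "classify",
    "holdout_experiment",
    "FoldClassificationModel",
    "FoldClassificationResults",
    "TM_METHODS",
    "ALL_METHODS",
]

TM_METHODS = ("tm_max", "tm_mean", "tm_median")
ALL_METHODS = TM_METHODS + ("cep", "c3p")


@dataclass
class QueryResult:
    """Per-query classification outcome across folds and methods."""

    query_id: str
    original_fold: str | None
    mode: str
    # method -> {fold_id -> score used by that method}
    fold_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    # method -> assigned fold
    assigned: dict[str, str] = field(default_factory=dict)
    # fold_id -> partner domain achieving the query-fold TM_max
    partner: dict[str, str] = field(default_factory=dict)
    # fold_id -> query-fold TM_max (shared across cep/c3p/tm_max)
    tm_max: dict[str, float] = field(default_factory=dict)


def cep(s: float, profile: FoldProfile) -> float:
    """Cumulative empirical probability of a query-fold TM_max-score.

    The fraction of the fold's within-fold TM_max-scores equal to or
    smaller than ``s`` (inclusive comparison).
    """
    if not (0.0 < s <= 1.0):
        raise ValueError(f"query-fold TM_max-score must be in (0, 1], got {s}")
    if profile.n == 0:
        raise ValueError("empty fold profile")
    return float(np.mean(profile.x <= s))


def _query_tm_max(result: QueryResult, matrix, profiles) -> None:
    """Fill the per-fold query-fold TM_max scores and partner ids once."""
    if result.tm_max:
        return
    for fold_id, prof in profiles.items():
        val, partner = query_fold_statistic(matrix, result.query_id, prof.member_ids, "max")
        result.tm_max[fold_id] = val
        result.partner[fold_id] = partner


def _assign(scores: Mapping[str, float], tm_max: Mapping[str, float] | None) -> str:
    """Argmax fold; ties broken by higher query-fold TM_max, then fold id."""
    def key(fold):
        tm = tm_max.get(fold, 0.0) if tm_max else 0.0
        return (-scores[fold], -tm, fold)

    return min(scores, key=key)


def classify(
    query_id: str,
    matrix: SimilarityMatrix,
    profiles: Mapping[str, FoldProfile],
    method: str | Sequence[str] = "tm_max",
    original_fold: str | None = None,
    fitted: Mapping[str, object] | None = None,
    predictive_draws: int = 1,
    seed: int = 0,
    analytic: bool = True,
) -> QueryResult:
    """Classify one query against every profiled fold.

    ``method`` may be a single method or a sequence drawn from
    ``tm_max | tm_mean | tm_median | cep | c3p``.  For ``c3p``, ``fitted``
    maps fold ids to either lists of posterior samples or fitted
    :class:`~foldcep.mixture.TmMaxMixtureResults`; ``analytic=True`` uses
    the Rao-Blackwellized mixture-CDF estimator, otherwise Monte-Carlo
    predictive draws are used.

    The query must already be excluded from its own fold's profile.
    """
    if not profiles:
        raise ValueError("no fold profiles to classify against")
    methods = (method,) if isinstance(method, str) else tuple(method)
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}")
    for fold_id, prof in profiles.items():
        if query_id in prof.member_ids:
            raise ValueError(
                f"query {query_id} is still a member of fold {fold_id}; hold it out first"
            )

    result = QueryResult(query_id, original_fold, matrix.mode)
    for m in methods:
        if m in ("tm_max", "cep", "c3p"):
            _query_tm_max(result, matrix, profiles)
        if m == "tm_max":
            scores = dict(result.tm_max)
        elif m in ("tm_mean", "tm_median"):
            stat = m.split("_")[1]
            scores = {
                fid: query_fold_statistic(matrix, query_id, p.member_ids, stat)[0]
                for fid, p in profiles.items()
            }
        elif m == "cep":
            scores = {fid: cep(result.tm_max[fid], p) for fid, p in profiles.items()}
        else:  # c3p
            from .mixture import TmMaxMixtureResults, c3p as _c3p, c3p_analytic, posterior_predictive

            if fitted is None:
                raise ValueError("method 'c3p' requires fitted per-fold mixtures")
            scores = {}
            for fid in profiles:
                if fid not in fitted:
                    raise ValueError(f"no fitted mixture for fold {fid}")
                fit = fitted[fid]
                samples = fit.samples if isinstance(fit, TmMaxMixtureResults) else fit
                s = result.tm_max[fid]
                if analytic:
                    scores[fid] = c3p_analytic(s, samples)
                else:
                    pred = posterior_predictive(samples, predictive_draws, seed)
                    scores[fid] = _c3p(s, pred)
        result.fold_scores[m] = scores
        tie_tm = result.tm_max if m in ("cep", "c3p", "tm_max") else None
        result.assigned[m] = _assign(scores, tie_tm)
    return result


# ---------------------------------------------------------------------------
# Hold-out experiment
# ---------------------------------------------------------------------------

@dataclass
class HoldoutResult:
    """Outcome of the repeated hold-out experiment."""

    per_repeat: list[list[QueryResult]]
    summary: pd.DataFrame  # method, mean_disagreement, sd_disagreement
    methods: tuple[str, ...]
    fraction: float
    seed: int

    def disagreement(self, method: str) -> np.ndarray:
        """Per-repeat disagreement fractions for one method."""
        out = []
        for results in self.per_repeat:
            bad = sum(1 for r in results if r.assigned[method] != r.original_fold)
            out.append(bad / len(results))
        return np.array(out)


def holdout_experiment(
    table: ClassificationTable,
    matrix: SimilarityMatrix,
    fraction: float = 0.10,
    n_repeats: int = 30,
    methods: Sequence[str] = ("tm_max", "tm_mean", "tm_median", "cep"),
    seed: int = 0,
    min_fold_size: int = 25,
    mcmc_settings=None,
    priors=None,
) -> HoldoutResult:
    """Repeated hold-out evaluation against the original classification.

    Per repeat and per large fold (>= ``min_fold_size`` members),
    ``max(1, floor(fraction * N))`` members are sampled as queries; the
    remaining members keep their folds and the profiles are rebuilt without
    the queries.  Every query is classified independently by every method
    and compared with its original fold.  For ``c3p`` the per-fold mixture
    is refitted on each repeat's reduced profile.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    methods = tuple(methods)
    folds = table.folds()
    large = {f: m for f, m in folds.items() if len(m) >= min_fold_size}
    if not large:
        raise ValueError(f"no fold has >= {min_fold_size} members")

    per_repeat: list[list[QueryResult]] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([seed, rep])
        queries: list[str] = []
        remaining: dict[str, list[str]] = {}
        for fold_id in sorted(large):
            members = large[fold_id]
            n_q = max(1, math.floor(fraction * len(members)))
            if len(members) - n_q < 2:
                warnings.warn(
                    f"fold {fold_id} would drop below 2 members; excluded from sampling",
                    stacklevel=2,
                )
                remaining[fold_id] = list(members)
                continue
            picked = sorted(rng.choice(members, size=n_q, replace=False).tolist())
            queries.extend(picked)
            remaining[fold_id] = sorted(set(members) - set(picked))
        profiles = build_profiles(matrix, remaining, min_fold_size=2)

        fitted = None
        if "c3p" in methods:
            from .mixture import GmmPriors, McmcSettings, fit_rjmcmc

            settings = mcmc_settings if mcmc_settings is not None else McmcSettings()
            fitted = {}
            for fi, fold_id in enumerate(sorted(profiles)):
                prof = profiles[fold_id]
                pri = priors if priors is not None else GmmPriors.from_data(prof.x)
                fold_settings = McmcSettings(
                    iterations=settings.iterations,
                    burn_in=settings.burn_in,
                    thin=settings.thin,
                    seed=int(
                        np.random.SeedSequence([seed, rep, fi]).generate_state(1)[0] % (2**31)
                    ),
                )
                fitted[fold_id] = fit_rjmcmc(prof.x, pri, fold_settings)

        results = [
            classify(
                q,
                matrix,
                profiles,
                method=methods,
                original_fold=table.fold_of(q),
                fitted=fitted,
            )
            for q in queries
        ]
        per_repeat.append(results)

    rows = []
    for m in methods:
        frac = np.array(
            [
                sum(1 for r in results if r.assigned[m] != r.original_fold) / len(results)
                for results in per_repeat
            ]
        )
        rows.append(
            {
                "method": m,
                "mean_disagreement": float(frac.mean()),
                "sd_disagreement": float(frac.std(ddof=1)) if n_repeats > 1 else 0.0,
            }
        )
    summary = pd.DataFrame(rows)
    return HoldoutResult(per_repeat, summary, methods, fraction, seed)


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------

class FoldClassificationModel:
    """Fold-classification model over a domain set and its score matrix.

    Parameters
    ----------
    classification : ClassificationTable
        Domain -> fold assignments (the initial classification).
    matrix : SimilarityMatrix
        Pairwise TM-scores among all domains, local or global mode.
    min_fold_size : int
        Folds with fewer members are excluded from classification targets.
    """

    def __init__(
        self,
        classification: ClassificationTable,
        matrix: SimilarityMatrix,
        min_fold_size: int = 25,
    ):
        self.classification = classification
        self.matrix = matrix
        self.min_fold_size = min_fold_size

    def fit(
        self,
        methods: Sequence[str] = ("tm_max", "cep"),
        mcmc_settings=None,
        seed: int = 0,
    ) -> "FoldClassificationResults":
        """Build fold profiles (and mixture fits when c3p is requested)."""
        folds = self.classification.folds()
        large = {f: m for f, m in folds.items() if len(m) >= self.min_fold_size}
        profiles = build_profiles(self.matrix, large, min_fold_size=self.min_fold_size)
        fitted = None
        if "c3p" in methods:
            from .mixture import GmmPriors, McmcSettings, fit_rjmcmc

            settings = mcmc_settings if mcmc_settings is not None else McmcSettings()
            fitted = {}
            for fi, fold_id in enumerate(sorted(profiles)):
                prof = profiles[fold_id]
                fold_settings = McmcSettings(
                    iterations=settings.iterations,
                    burn_in=settings.burn_in,
                    thin=settings.thin,
                    seed=int(np.random.SeedSequence([seed, fi]).generate_state(1)[0] % (2**31)),
                )
                fitted[fold_id] = fit_rjmcmc(prof.x, GmmPriors.from_data(prof.x), fold_settings)
        return FoldClassificationResults(self, profiles, tuple(methods), fitted, seed)


class FoldClassificationResults:
    """Fitted profiles (and mixtures) ready to classify queries."""

    def __init__(self, model, profiles, methods, fitted, seed):
        self.model = model
        self.profiles = profiles
        self.methods = methods
        self.fitted = fitted
        self.seed = seed

    def classify(self, query_id: str, original_fold: str | None = None) -> QueryResult:
        """Classify an external query (not part of the profiled members)."""
        if original_fold is None and query_id in self.model.classification:
            original_fold = self.model.classification.fold_of(query_id)
        return classify(
            query_id,
            self.model.matrix,
            self.profiles,
            method=self.methods,
            original_fold=original_fold,
            fitted=self.fitted,
        )

    def classify_members(self) -> list[QueryResult]:
        """Leave-one-out classification of every profiled member.

        Each member is held out of its own fold's profile (which is
        rebuilt without it) and classified against all folds.
        """
        from .profiles import FoldProfile, within_fold_tmmax

        out = []
        for fold_id in sorted(self.profiles):
            prof = self.profiles[fold_id]
            for member in prof.member_ids:
                rest = tuple(m for m in prof.member_ids if m != member)
                x = within_fold_tmmax(self.model.matrix, rest)
                reduced = FoldProfile(fold_id, rest, x, self.model.matrix.mode)
                tmp = dict(self.profiles)
                tmp[fold_id] = reduced
                out.append(
                    classify(
                        member,
                        self.model.matrix,
                        tmp,
                        method=self.methods,
                        original_fold=fold_id,
                        fitted=self.fitted,
                    )
                )
        return out

    def holdout(self, fraction: float = 0.10, n_repeats: int = 30, mcmc_settings=None) -> HoldoutResult:
        return holdout_experiment(
            self.model.classification,
            self.model.matrix,
            fraction=fraction,
            n_repeats=n_repeats,
            methods=self.methods,
            seed=self.seed,
            min_fold_size=self.model.min_fold_size,
            mcmc_settings=mcmc_settings,
        )

    def summary(self) -> str:
        lines = [
            "Fold classification model",
            "=" * 40,
            f"mode:           {self.model.matrix.mode}",
            f"profiled folds: {len(self.profiles)}",
            f"methods:        {', '.join(self.methods)}",
        ]
        for fold_id in sorted(self.profiles):
            p = self.profiles[fold_id]
            lines.append(
                f"  {fold_id}: N={p.n}  mean_x={p.mean_x:.3f}  sd_x={p.sd_x:.3f}"
            )
        return "\n".join(lines)
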