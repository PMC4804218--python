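"""Synthetic fold universes, toy structures and mixture samples.

The generator produces classification tables plus local/global score
matrices with known ground truth, emulating the regimes seen in real fold
hierarchies:

* fold-structured score blocks — within-fold pairwise scores high,
  cross-fold scores low;
* a within-fold heterogeneity gradient — per-fold score spread varying
  from tight (homogeneous folds, mean TM_max near 1) to wide
  (heterogeneous folds, means down to 0.6-0.7), with the spread of the
  emergent within-fold TM_max distribution anti-correlated with its mean;
* "bridge" domains — members of a tight fold whose best structural match
  in a heterogeneous target fold (a single anchor/partner domain) scores
  far above the cross-fold background, the signature of fold-space
  continuity;
* Russian-doll pairs — cross-fold pairs whose local score greatly exceeds
  their global score because one domain resembles a substructure of the
  other.

Scores are generated directly as matrix entries: the classifiers consume
only scores, and direct generation gives exact control over the
within/between supports.  The induced within-fold TM_max distribution is
an order statistic of the pairwise draws and is therefore emergent; the
truth record stores the generating parameters, not the emergent maxima.
Toy helical structures exist separately to exercise the TM-score geometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ClassificationRecord, ClassificationTable, SimilarityMatrix
from .tmscore import AlignmentPairs, Structure

__all__ = [
    "MixtureSpec",
    "BridgeSpec",
    "RussianDollSpec",
    "UniverseConfig",
    "generate_universe",
    "generate_toy_structures",
    "generate_gmm_data",
    "discrete_config",
    "continuum_config",
]

SCORE_FLOOR = 0.0101  # open-below clip bound; TM-scores live in (0, 1]


@dataclass(frozen=True)
class MixtureSpec:
    """A mixture of Gaussians over pairwise scores, with clip bounds."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    support: tuple[float, float] = (SCORE_FLOOR, 1.0)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if len(self.weights) != len(self.means) or len(self.means) != len(self.sds):
            raise ValueError("weights/means/sds length mismatch")
        if any(s < 0 for s in self.sds):
            raise ValueError("negative sd")
        lo, hi = self.support
        if not (0.0 < lo < hi <= 1.0):
            raise ValueError("support must satisfy 0 < lo < hi <= 1")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        vals = rng.normal(np.asarray(self.means)[comp], np.asarray(self.sds)[comp])
        return np.clip(vals, self.support[0], self.support[1])

    @classmethod
    def single(cls, mean: float, sd: float, support=(SCORE_FLOOR, 1.0)) -> "MixtureSpec":
        return cls((1.0,), (mean,), (sd,), support)


@dataclass(frozen=True)
class BridgeSpec:
    """Bridge (boundary) domains connecting a source fold to a target fold.

    Each of the ``n_domains`` bridge members of the source fold strongly
    resembles one *anchor* domain of the target fold — its score to the
    anchor is ~ Normal(level, level_sd) — while its scores to the other
    target members stay at a low ``background`` level.  This mirrors how
    continuity shows up in real score data: a query's high similarity to a
    fold is carried by a single partner domain, not by the whole fold.
    Anchors are the target members with the highest within-fold TM_max, so
    a well-embedded target member, not a marginal one, carries the bridge.
    Optionally the bridge's own-fold scores can be depressed by
    ``own_penalty`` (boundary members in their own fold's low tail).
    """

    n_domains: int
    source_fold: int
    target_fold: int
    level: float
    level_sd: float = 0.005
    background: float = 0.65
    background_sd: float = 0.01
    own_penalty: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.level <= 1.0):
            raise ValueError("bridge level must be in (0, 1]")
        if self.n_domains < 1:
            raise ValueError("bridge needs at least one domain")
        if self.source_fold == self.target_fold:
            raise ValueError("bridge source and target must differ")


@dataclass(frozen=True)
class RussianDollSpec:
    """A cross-fold pair where one fold's domains nest inside the other's.

    All cross pairs between the two folds get local = base + local_boost
    and global = base - global_penalty (clipped); fold_a's lengths are set
    to ``nested_ratio`` times fold_b's mean length.
    """

    fold_a: int
    fold_b: int
    nested_ratio: float = 0.5
    local_boost: float = 0.3
    global_penalty: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 < self.nested_ratio < 1.0):
            raise ValueError("nested_ratio must be in (0, 1)")


@dataclass(frozen=True)
class UniverseConfig:
    members_per_fold: tuple[int, ...]
    within: tuple[MixtureSpec, ...]  # one spec per fold
    between: MixtureSpec
    bridges: tuple[BridgeSpec, ...] = ()
    russian_doll: tuple[RussianDollSpec, ...] = ()
    length_means: tuple[float, ...] = ()
    length_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.members_per_fold)
        if len(self.within) != n:
            raise ValueError("need one within-score spec per fold")
        if any(m < 2 for m in self.members_per_fold):
            raise ValueError("every fold needs at least 2 members")
        if self.length_means and len(self.length_means) != n:
            raise ValueError("length_means must match fold count")
        for b in self.bridges:
            if not (0 <= b.source_fold < n and 0 <= b.target_fold < n):
                raise ValueError("bridge fold index out of range")

    @property
    def n_folds(self) -> int:
        return len(self.members_per_fold)


def generate_universe(config: UniverseConfig, seed: int | None = None):
    """Generate (table, local matrix, global matrix, truth record)."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_folds = config.n_folds
    fold_ids = [f"9.{10 + f}.10" for f in range(n_folds)]
    domain_ids: list[str] = []
    fold_of: dict[str, int] = {}
    for f, m in enumerate(config.members_per_fold):
        for j in range(m):
            did = f"F{f:02d}_{j:03d}"
            domain_ids.append(did)
            fold_of[did] = f

    length_means = config.length_means or tuple([120.0] * n_folds)
    length_means = list(length_means)
    for rd in config.russian_doll:
        length_means[rd.fold_a] = rd.nested_ratio * length_means[rd.fold_b]
    lengths = {}
    for did in domain_ids:
        L = rng.normal(length_means[fold_of[did]], config.length_sd)
        lengths[did] = int(max(40, round(L)))

    records = [
        ClassificationRecord(did, fold_ids[fold_of[did]], lengths[did], "synthetic")
        for did in domain_ids
    ]
    table = ClassificationTable(records)

    n = len(domain_ids)
    idx = {d: i for i, d in enumerate(domain_ids)}
    local = np.ones((n, n))
    glob = np.ones((n, n))

    # base within/between draws, shared by the local and global matrices
    iu = np.triu_indices(n, k=1)
    fold_arr = np.array([fold_of[d] for d in domain_ids])
    fa, fb = fold_arr[iu[0]], fold_arr[iu[1]]
    base = np.empty(iu[0].size)
    between_mask = fa != fb
    base[between_mask] = config.between.draw(int(between_mask.sum()), rng)
    for f in range(n_folds):
        m = (fa == f) & (fb == f)
        base[m] = config.within[f].draw(int(m.sum()), rng)
    local[iu] = base
    glob[iu] = base.copy()

    # Russian-doll pairs: substructure similarity inflates the local score
    # and the length mismatch deflates the global one
    for rd in config.russian_doll:
        m = ((fa == rd.fold_a) & (fb == rd.fold_b)) | ((fa == rd.fold_b) & (fb == rd.fold_a))
        local[iu[0][m], iu[1][m]] = np.clip(base[m] + rd.local_boost, SCORE_FLOOR, 1.0)
        glob[iu[0][m], iu[1][m]] = np.clip(base[m] - rd.global_penalty, SCORE_FLOOR, 1.0)

    # bridge domains: each bridge pairs with one anchor in the target fold
    def _sym_get(mat, a, b):
        i, j = min(a, b), max(a, b)
        return mat[i, j]

    def _sym_set(mat, a, b, v):
        i, j = min(a, b), max(a, b)
        mat[i, j] = v

    bridge_ids: list[str] = []
    anchors: dict[str, str] = {}
    used: dict[int, int] = {}
    for br in config.bridges:
        start = used.get(br.source_fold, 0)
        members = [d for d in domain_ids if fold_of[d] == br.source_fold]
        chosen = members[start : start + br.n_domains]
        if len(chosen) < br.n_domains:
            raise ValueError(f"fold {br.source_fold} too small for its bridges")
        used[br.source_fold] = start + br.n_domains
        targets = [d for d in domain_ids if fold_of[d] == br.target_fold]
        # anchor ranking by within-fold TM_max of the (pre-bridge) target block
        tidx = [idx[t] for t in targets]
        sub = np.full((len(targets), len(targets)), -np.inf)
        for a in range(len(targets)):
            for b in range(a + 1, len(targets)):
                sub[a, b] = sub[b, a] = _sym_get(local, tidx[a], tidx[b])
        tmmax = sub.max(axis=1)
        order = np.argsort(-tmmax)
        if len(targets) < br.n_domains:
            raise ValueError(f"fold {br.target_fold} too small to anchor the bridges")
        for bi, d in enumerate(chosen):
            bridge_ids.append(d)
            di = idx[d]
            anchor = targets[int(order[bi])]
            anchors[d] = anchor
            for t in targets:
                level, sd = (
                    (br.level, br.level_sd)
                    if t == anchor
                    else (br.background, br.background_sd)
                )
                s = float(np.clip(rng.normal(level, sd), SCORE_FLOOR, 1.0))
                _sym_set(local, di, idx[t], s)
                _sym_set(glob, di, idx[t], s)
            if br.own_penalty > 0:
                for o in members:
                    if o == d:
                        continue
                    oi = idx[o]
                    _sym_set(local, di, oi, np.clip(_sym_get(local, di, oi) - br.own_penalty, SCORE_FLOOR, 1.0))
                    _sym_set(glob, di, oi, np.clip(_sym_get(glob, di, oi) - br.own_penalty, SCORE_FLOOR, 1.0))

    local = np.triu(local, 1) + np.triu(local, 1).T + np.eye(n)
    glob = np.triu(glob, 1) + np.triu(glob, 1).T + np.eye(n)
    local_m = SimilarityMatrix.from_array(domain_ids, local, mode="local")
    glob_m = SimilarityMatrix.from_array(domain_ids, glob, mode="global")

    truth = {
        "config": config,
        "fold_ids": fold_ids,
        "fold_of": {d: fold_ids[fold_of[d]] for d in domain_ids},
        "bridge_domains": bridge_ids,
        "bridge_anchors": anchors,
        "lengths": lengths,
    }
    return table, local_m, glob_m, truth


# ---------------------------------------------------------------------------
# Preset universes
# ---------------------------------------------------------------------------

def discrete_config(
    n_folds: int = 8,
    members: int = 30,
    seed: int = 0,
) -> UniverseConfig:
    """A completely discrete fold space: within-fold pairwise scores in
    [0.80, 0.98], cross-fold scores in [0.15, 0.40], no bridges.  Every
    classification method must agree with the truth here."""
    within = tuple(
        MixtureSpec.single(0.88, 0.03, support=(0.80, 0.98)) for _ in range(n_folds)
    )
    between = MixtureSpec.single(0.30, 0.04, support=(0.15, 0.40))
    return UniverseConfig(
        members_per_fold=tuple([members] * n_folds),
        within=within,
        between=between,
        length_means=tuple(np.linspace(80, 220, n_folds)),
        seed=seed,
    )


def continuum_config(
    n_folds: int = 10,
    members: int = 40,
    n_bridges: int = 10,
    seed: int = 0,
) -> UniverseConfig:
    """A fold space with a heterogeneity gradient and bridge domains.

    Per-fold pairwise score means fall while the spreads rise (mean and
    spread anti-correlated, as observed for real folds; means stay clear
    of the clip at 1 so the emergent within-fold TM_max spread inherits
    the gradient), and the last two folds are markedly more heterogeneous
    than the rest.  Bridge domains from the two tightest folds are
    targeted at those two most heterogeneous folds via anchor members:
    the bridge's query-fold TM_max (carried by its anchor) lands in the
    upper tail of the wide target distribution, giving a high CEP there,
    while its rank within its own tight fold is middling —
    continuity-aware classification pulls it across.  Background
    bridge-target scores stay below every target member's own within-fold
    TM_max so the pull is one-directional.  The bridges are split
    unevenly between the two targets so fold-attraction counts are not
    tied.
    """
    if n_folds < 4:
        raise ValueError("continuum preset needs at least 4 folds")
    means = np.concatenate([np.linspace(0.95, 0.72, n_folds - 2), [0.62, 0.55]])
    sds = np.concatenate([np.geomspace(0.008, 0.03, n_folds - 2), [0.095, 0.13]])
    within = tuple(
        MixtureSpec.single(float(m), float(s)) for m, s in zip(means, sds)
    )
    between = MixtureSpec.single(0.35, 0.05, support=(SCORE_FLOOR, 0.55))
    n_first = n_bridges - n_bridges // 3
    bridges = (
        BridgeSpec(
            n_domains=n_first,
            source_fold=0,
            target_fold=n_folds - 1,
            level=0.89,
        ),
        BridgeSpec(
            n_domains=n_bridges // 3,
            source_fold=1,
            target_fold=n_folds - 2,
            level=0.89,
        ),
    )
    return UniverseConfig(
        members_per_fold=tuple([members] * n_folds),
        within=within,
        between=between,
        bridges=bridges,
        length_means=tuple(np.linspace(90, 200, n_folds)),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Toy structures and mixture samples
# ---------------------------------------------------------------------------

HELIX_RISE = 1.5  # Angstrom per residue
HELIX_RADIUS = 2.3  # Angstrom
HELIX_TWIST = np.deg2rad(100.0)  # per residue


def _ideal_helix(length: int) -> np.ndarray:
    i = np.arange(length)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(i * HELIX_TWIST),
            HELIX_RADIUS * np.sin(i * HELIX_TWIST),
            HELIX_RISE * i,
        ]
    )


def generate_toy_structures(
    n: int,
    length: int = 30,
    perturbation_sd: float = 0.0,
    truncation: float | None = None,
    seed: int = 0,
):
    """Perturbed copies of an ideal alpha-helical CA trace.

    Every structure is the ideal helix plus i.i.d. Normal(0, sd^2)
    coordinate noise.  When ``truncation`` is given, odd-indexed
    structures keep only the first ceil(truncation * length) residues
    (nested substructures, the Russian-doll geometry).  Returns
    ``(structures, correspondences)`` where correspondences are identity
    alignments over the shared residue range of each pair.
    """
    if length < 10:
        raise ValueError("length must be >= 10")
    if perturbation_sd < 0:
        raise ValueError("perturbation_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base = _ideal_helix(length)
    trunc_len = None
    if truncation is not None:
        trunc_len = int(np.ceil(truncation * length))
        if trunc_len < 4:
            raise ValueError("truncation leaves fewer than 4 residues")
    structures = []
    for i in range(n):
        coords = base + rng.normal(0.0, perturbation_sd, size=base.shape)
        if trunc_len is not None and i % 2 == 1:
            coords = coords[:trunc_len]
        structures.append(Structure(f"toy{i:03d}", coords))
    correspondences = {}
    for i, a in enumerate(structures):
        for b in structures[i + 1 :]:
            shared = min(a.length, b.length)
            correspondences[(a.domain_id, b.domain_id)] = AlignmentPairs.identity(shared)
    return structures, correspondences


def generate_gmm_data(
    weights: Sequence[float],
    means: Sequence[float],
    sds: Sequence[float],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """I.i.d. Gaussian-mixture draws clipped to (0.01, 1)."""
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 1 or abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValueError("weights must form a simplex")
    sds = np.asarray(sds, dtype=float)
    if (sds <= 0).any():
        raise ValueError("sds must be positive")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(weights), size=n, p=weights)
    vals = rng.normal(np.asarray(means, dtype=float)[comp], sds[comp])
    clipped = (vals <= 0.01) | (vals >= 1.0)
    if clipped.mean() > 0.01:
        warnings.warn(
            f"{clipped.mean():.1%} of mixture draws clipped to (0.01, 1)", stacklevel=2
        )
    return np.clip(vals, 0.01, 1.0 - 1e-9)
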