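"""TM-score computation for a fixed residue correspondence.

The TM-score between two superposed structures is

    TM = max over superpositions of (1/L_norm) * sum_i 1 / (1 + (d_i/d0)^2)

where the sum runs over the L_ali aligned residue pairs, d_i is the CA-CA
distance of pair i after superposition, and d0 = max(1.24 (L_norm-15)^(1/3)
- 1.8, 0.5) Angstrom normalizes the score so that random pairs score
independently of size.  L_norm is the length of the shorter structure
("local" normalization, emphasizing substructure similarity) or the mean
length of the two ("global", penalizing length mismatch).

Finding the correspondence (the alignment) is out of scope here: pairs are
supplied by the caller.  The maximization over rigid superpositions uses
the standard seed-and-refine scheme: superpose on every contiguous
alignment fragment (lengths L_ali, L_ali/2, L_ali/4, minimum 4; all
offsets), then iteratively re-superpose on the close pairs until the
included set is stable, and keep the best score over all seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Structure",
    "AlignmentPairs",
    "TmScoreResult",
    "d0_scale",
    "kabsch_superpose",
    "tm_score",
    "pairwise_matrix",
]

MAX_REFINE_ROUNDS = 20
D_CUT_STEP = 0.5  # Angstrom growth of the inclusion cutoff
MIN_INCLUDED = 3


@dataclass(frozen=True)
class Structure:
    """A protein domain reduced to its ordered CA trace."""

    domain_id: str
    ca_coords: np.ndarray  # (L, 3) in Angstrom

    def __post_init__(self) -> None:
        coords = np.asarray(self.ca_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("ca_coords must be an (L, 3) array")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        object.__setattr__(self, "ca_coords", coords)

    @property
    def length(self) -> int:
        return self.ca_coords.shape[0]


@dataclass(frozen=True)
class AlignmentPairs:
    """Sequential residue correspondence between two structures (0-based)."""

    pairs: np.ndarray  # (L_ali, 2) int

    def __post_init__(self) -> None:
        arr = np.asarray(self.pairs, dtype=int)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be an (L_ali, 2) array")
        if arr.shape[0] >= 2:
            if not (np.diff(arr[:, 0]) > 0).all() or not (np.diff(arr[:, 1]) > 0).all():
                raise ValueError("alignment must be sequential (strictly increasing indices)")
        if arr.shape[0] < 1:
            raise ValueError("alignment must contain at least one pair")
        object.__setattr__(self, "pairs", arr)

    @property
    def l_ali(self) -> int:
        return self.pairs.shape[0]

    @classmethod
    def identity(cls, n: int) -> "AlignmentPairs":
        idx = np.arange(n)
        return cls(np.column_stack([idx, idx]))

    def reversed(self) -> "AlignmentPairs":
        return AlignmentPairs(self.pairs[:, ::-1])


@dataclass(frozen=True)
class TmScoreResult:
    score: float
    mode: str
    d0: float
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    distances: np.ndarray  # (L_ali,) pair distances under the best superposition


def d0_scale(l_norm: int) -> float:
    """Distance scale d0(L) = max(1.24 (L-15)^(1/3) - 1.8, 0.5) Angstrom."""
    if l_norm < 1:
        raise ValueError(f"normalization length must be >= 1, got {l_norm}")
    if l_norm <= 15:
        return 0.5
    return max(1.24 * (l_norm - 15) ** (1.0 / 3.0) - 1.8, 0.5)


def kabsch_superpose(
    P: np.ndarray,
    Q: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of Q onto P.

    Returns (rotation, translation, rmsd) such that ``Q @ rotation.T +
    translation`` minimizes the (weighted) RMSD to P.  Reflections are
    excluded by flipping the sign of the smallest singular value when the
    determinant would be negative, so the rotation is always proper.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any() or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    Pc = P - cp
    Qc = Q - cq
    H = (Qc * w[:, None]).T @ Pc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[-1] < 1e-12 and S[-2] < 1e-12:
        raise ValueError("degenerate (collinear) point set")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cp - R @ cq
    diff = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((w * (diff**2).sum(axis=1)).sum()))
    return R, t, rmsd


def _score_sum(d2: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + d2 / (d0 * d0))))


def tm_score(
    A: Structure,
    B: Structure,
    pairs: AlignmentPairs,
    mode: str = "local",
) -> TmScoreResult:
    """TM-score of B against A for the given correspondence.

    ``mode='local'`` normalizes by the shorter length, ``'global'`` by the
    mean length (rounded half-up).  The reported rotation/translation map
    B's aligned coordinates onto A's frame.
    """
    if mode not in ("local", "global"):
        raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
    arr = pairs.pairs
    if arr[:, 0].max() >= A.length or arr[:, 1].max() >= B.length:
        raise ValueError("alignment indices out of bounds")
    l_ali = pairs.l_ali
    if l_ali < 4:
        raise ValueError("need at least 4 aligned pairs for a robust superposition")

    if mode == "local":
        l_norm = min(A.length, B.length)
    else:
        l_norm = int(np.floor((A.length + B.length) / 2.0 + 0.5))  # half-up
    d0 = d0_scale(l_norm)

    pa = A.ca_coords[arr[:, 0]]
    pb = B.ca_coords[arr[:, 1]]

    best = (-np.inf, None, None)  # (raw score sum, R, t)
    for lo, hi in _seed_fragments(l_ali):
        try:
            R, t, _ = kabsch_superpose(pa[lo:hi], pb[lo:hi])
        except ValueError:
            continue
        R, t, s = _refine(pa, pb, R, t, d0)
        if s > best[0]:
            best = (s, R, t)
    if best[1] is None:
        raise ValueError("no valid seed superposition (degenerate coordinates)")
    s, R, t = best
    d = np.linalg.norm(pb @ R.T + t - pa, axis=1)
    return TmScoreResult(
        score=s / l_norm,
        mode=mode,
        d0=d0,
        rotation=R,
        translation=t,
        distances=d,
    )


def _seed_fragments(l_ali: int):
    """Contiguous seed windows: lengths L, L/2, L/4 (floor, min 4), all offsets."""
    lengths = {l_ali, max(l_ali // 2, 4), max(l_ali // 4, 4)}
    for L in sorted(lengths, reverse=True):
        if L > l_ali:
            continue
        for lo in range(0, l_ali - L + 1):
            yield lo, lo + L


def _refine(pa, pb, R, t, d0):
    """Iteratively re-superpose on pairs closer than a growing cutoff."""
    prev_mask = None
    best_s = _score_sum(((pb @ R.T + t - pa) ** 2).sum(axis=1), d0)
    best_R, best_t = R, t
    for _ in range(MAX_REFINE_ROUNDS):
        d2 = ((pb @ R.T + t - pa) ** 2).sum(axis=1)
        s = _score_sum(d2, d0)
        if s > best_s:
            best_s, best_R, best_t = s, R, t
        d_cut = d0
        mask = d2 < d_cut * d_cut
        while mask.sum() < MIN_INCLUDED:
            d_cut += D_CUT_STEP
            mask = d2 < d_cut * d_cut
        if prev_mask is not None and np.array_equal(mask, prev_mask):
            break
        prev_mask = mask
        try:
            R, t, _ = kabsch_superpose(pa[mask], pb[mask])
        except ValueError:
            break
    d2 = ((pb @ R.T + t - pa) ** 2).sum(axis=1)
    s = _score_sum(d2, d0)
    if s > best_s:
        best_s, best_R, best_t = s, R, t
    return _polish(pa, pb, best_R, best_t, best_s, d0)


def _polish(pa, pb, R, t, s, d0, max_iter: int = 200):
    """Majorize-minimize ascent on the TM objective itself.

    1/(1+u) is convex in u = (d/d0)^2, so its tangent minorizes it; each
    weighted Kabsch step with weights 1/(1+(d_i/d0)^2)^2 maximizes that
    minorant and cannot decrease the score.  Converges to a stationary
    point of the score, sharpening the subset-RMSD refinement.
    """
    best_R, best_t, best_s = R, t, s
    for _ in range(max_iter):
        d2 = ((pb @ best_R.T + best_t - pa) ** 2).sum(axis=1)
        w = 1.0 / (1.0 + d2 / (d0 * d0)) ** 2
        try:
            R2, t2, _ = kabsch_superpose(pa, pb, weights=w)
        except ValueError:
            break
        s2 = _score_sum(((pb @ R2.T + t2 - pa) ** 2).sum(axis=1), d0)
        if s2 <= best_s + 1e-13:
            break
        best_R, best_t, best_s = R2, t2, s2
    return best_R, best_t, best_s


def pairwise_matrix(
    structures: Sequence[Structure],
    correspondences: Mapping[tuple[str, str], AlignmentPairs],
    mode: str = "local",
):
    """All-vs-all TM-score matrix for the supplied correspondences.

    A correspondence must exist (in either orientation) for every pair of
    the given structures.
    """
    from .io import SimilarityMatrix

    by_id = {s.domain_id: s for s in structures}
    ids = [s.domain_id for s in structures]
    mat = SimilarityMatrix(ids, mode=mode)
    missing = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if (a, b) in correspondences:
                pairs = correspondences[(a, b)]
                res = tm_score(by_id[a], by_id[b], pairs, mode=mode)
            elif (b, a) in correspondences:
                pairs = correspondences[(b, a)]
                res = tm_score(by_id[b], by_id[a], pairs, mode=mode)
            else:
                missing.append((a, b))
                continue
            mat.set(a, b, res.score)
    if missing:
        raise KeyError(f"missing correspondences for pairs: {missing[:10]}")
    return mat
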