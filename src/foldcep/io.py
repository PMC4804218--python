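"""Readers and writers for classification tables, score matrices and reports.

Supported formats:

* CATH ``CathDomainList``-style whitespace tables (domain id, C/A/T/H
  integer levels, trailing domain length).
* SCOP ``dir.cla``-style tab tables (sid, PDB id, region, sccs, sunid, ...).
* Tab-separated pairwise score tables (domain_a, domain_b, local, global).
* PDB coordinate files (CA trace only, via Biopython when reading real
  files is needed; here a small dedicated reader keeps the dependency
  surface minimal and the semantics explicit).
* Tab-separated classification reports.

All readers return plain in-memory containers (:class:`ClassificationTable`,
:class:`SimilarityMatrix`) that the rest of the package consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ClassificationRecord",
    "ClassificationTable",
    "SimilarityMatrix",
    "FormatError",
    "read_cath_domain_list",
    "read_scop_cla",
    "read_score_table",
    "write_score_table",
    "read_ca_coordinates",
    "write_classification_report",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ClassificationRecord:
    domain_id: str
    fold_id: str
    length: int
    source: str = "synthetic"  # one of {"CATH", "SCOP", "synthetic"}

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"domain {self.domain_id}: length must be >= 1")
        if not self.fold_id:
            raise ValueError(f"domain {self.domain_id}: empty fold id")


class ClassificationTable:
    """Domain -> fold assignment table (the "initial classification").

    Each domain belongs to exactly one fold; domain ids are unique.
    """

    def __init__(self, records: Iterable[ClassificationRecord]):
        self._records: list[ClassificationRecord] = list(records)
        seen: set[str] = set()
        for rec in self._records:
            if rec.domain_id in seen:
                raise FormatError(f"duplicate domain id: {rec.domain_id}")
            seen.add(rec.domain_id)
        self._by_id = {r.domain_id: r for r in self._records}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self):
        return iter(self._records)

    def __contains__(self, domain_id: str) -> bool:
        return domain_id in self._by_id

    def __getitem__(self, domain_id: str) -> ClassificationRecord:
        return self._by_id[domain_id]

    @property
    def domain_ids(self) -> list[str]:
        return [r.domain_id for r in self._records]

    def fold_of(self, domain_id: str) -> str:
        return self._by_id[domain_id].fold_id

    def length_of(self, domain_id: str) -> int:
        return self._by_id[domain_id].length

    def folds(self) -> dict[str, list[str]]:
        """Map fold_id -> sorted list of member domain ids."""
        out: dict[str, list[str]] = {}
        for rec in self._records:
            out.setdefault(rec.fold_id, []).append(rec.domain_id)
        for members in out.values():
            members.sort()
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "domain_id": [r.domain_id for r in self._records],
                "fold_id": [r.fold_id for r in self._records],
                "length": [r.length for r in self._records],
                "source": [r.source for r in self._records],
            }
        )


class SimilarityMatrix:
    """Symmetric pairwise structure-similarity store with scores in (0, 1].

    Backed by a dense ndarray over a fixed id order.  The diagonal is 1
    (a structure compared with itself); missing off-diagonal pairs are NaN.
    """

    def __init__(self, ids: Sequence[str], mode: str = "local"):
        if mode not in ("local", "global"):
            raise ValueError(f"mode must be 'local' or 'global', got {mode!r}")
        self.ids = list(ids)
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in similarity matrix")
        self.mode = mode
        self._index = {d: i for i, d in enumerate(self.ids)}
        n = len(self.ids)
        self._m = np.full((n, n), np.nan)
        np.fill_diagonal(self._m, 1.0)

    @classmethod
    def from_array(cls, ids: Sequence[str], values: np.ndarray, mode: str = "local") -> "SimilarityMatrix":
        mat = cls(ids, mode=mode)
        values = np.asarray(values, dtype=float)
        if values.shape != mat._m.shape:
            raise ValueError("array shape does not match id count")
        if not np.allclose(values, values.T, equal_nan=True):
            raise ValueError("similarity array must be symmetric")
        off = values[~np.eye(len(ids), dtype=bool)]
        off = off[~np.isnan(off)]
        if off.size and (off.min() <= 0 or off.max() > 1):
            raise ValueError("scores must lie in (0, 1]")
        mat._m = values.copy()
        np.fill_diagonal(mat._m, 1.0)
        return mat

    def set(self, a: str, b: str, score: float) -> None:
        if not (0.0 < score <= 1.0):
            raise FormatError(f"score for ({a}, {b}) outside (0, 1]: {score}")
        if a == b and score != 1.0:
            raise FormatError(f"self-pair {a} with score != 1: {score}")
        i, j = self._index[a], self._index[b]
        self._m[i, j] = score
        self._m[j, i] = score

    def get(self, a: str, b: str) -> float:
        s = self._m[self._index[a], self._index[b]]
        if np.isnan(s):
            raise KeyError(f"no score for pair ({a}, {b})")
        return float(s)

    def has(self, a: str, b: str) -> bool:
        return not np.isnan(self._m[self._index[a], self._index[b]])

    def scores_to(self, query: str, others: Sequence[str]) -> np.ndarray:
        qi = self._index[query]
        idx = [self._index[o] for o in others]
        vals = self._m[qi, idx]
        if np.isnan(vals).any():
            missing = [o for o, v in zip(others, vals) if np.isnan(v)]
            raise KeyError(f"missing scores between {query} and {missing[:5]}")
        return vals

    def submatrix(self, members: Sequence[str]) -> np.ndarray:
        idx = [self._index[m] for m in members]
        return self._m[np.ix_(idx, idx)]

    def to_array(self) -> np.ndarray:
        return self._m.copy()

    def pairs(self):
        """Yield (id_a, id_b, score) over stored upper-triangle pairs."""
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isnan(self._m[i, j]):
                    yield self.ids[i], self.ids[j], float(self._m[i, j])


# ---------------------------------------------------------------------------
# Classification readers
# ---------------------------------------------------------------------------

def read_cath_domain_list(path: str | Path, source: str = "CATH") -> ClassificationTable:
    """Read a CathDomainList-style whitespace table.

    Columns: domain id, then the C, A, T, H (and deeper) integer levels,
    with the domain length in the last column.  ``#`` lines are comments.
    The fold id is the "C.A.T" prefix (topology level).
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected >= 5 columns, got {len(cols)}")
            domain_id = cols[0]
            try:
                c, a, t = (int(cols[i]) for i in (1, 2, 3))
                length = int(cols[-1])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field ({exc})") from None
            records.append(
                ClassificationRecord(domain_id, f"{c}.{a}.{t}", length, source)
            )
    try:
        return ClassificationTable(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def read_scop_cla(path: str | Path, lengths: Mapping[str, int] | None = None) -> ClassificationTable:
    """Read a SCOP dir.cla-style tab table.

    Columns: sid, PDB id, region, sccs (e.g. ``a.1.1.1``), sunid, hierarchy.
    The fold id is the first two dot-fields of the sccs (class.fold).  SCOP
    release files carry no explicit length column; lengths are taken from
    the ``lengths`` mapping when given, else inferred from the region
    string (``A:12-87`` style), else an error is raised.
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}:{lineno}: expected >= 4 tab-separated columns")
            sid, _pdb, region, sccs = cols[0], cols[1], cols[2], cols[3]
            if not sccs or "." not in sccs:
                raise FormatError(f"{path}:{lineno}: missing or malformed sccs field {sccs!r}")
            fold_id = ".".join(sccs.split(".")[:2])
            if lengths is not None and sid in lengths:
                length = lengths[sid]
            else:
                length = _region_length(region)
                if length is None:
                    raise FormatError(
                        f"{path}:{lineno}: cannot infer length for {sid} "
                        f"from region {region!r} and no length supplied"
                    )
            records.append(ClassificationRecord(sid, fold_id, length, "SCOP"))
    try:
        return ClassificationTable(records)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from None


def _region_length(region: str) -> int | None:
    """Total residue count of a region string like ``A:12-87`` or ``1-64,70-90``."""
    total = 0
    for part in region.split(","):
        part = part.split(":")[-1].strip()
        if "-" not in part:
            return None
        lo, _, hi = part.partition("-")
        try:
            total += int(hi) - int(lo) + 1
        except ValueError:
            return None
    return total if total > 0 else None


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

def read_score_table(path: str | Path) -> tuple[SimilarityMatrix, SimilarityMatrix]:
    """Read a tab-separated pairwise score table.

    Columns: domain_a, domain_b, score_local, score_global.  Returns the
    (local, global) matrix pair.  If both (a, b) and (b, a) appear with
    unequal scores the maximum is kept with a warning — alignment programs
    are not perfectly symmetric, and TM_max statistics consume the higher
    score.
    """
    rows = []
    ids: list[str] = []
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            a, b = cols[0], cols[1]
            try:
                s_loc, s_glob = float(cols[2]), float(cols[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from None
            for s in (s_loc, s_glob):
                if not (0.0 < s <= 1.0):
                    raise FormatError(f"{path}:{lineno}: score {s} outside (0, 1]")
            if a == b and (s_loc != 1.0 or s_glob != 1.0):
                raise FormatError(f"{path}:{lineno}: self-pair {a} with score != 1")
            rows.append((a, b, s_loc, s_glob))
            for d in (a, b):
                if d not in seen_ids:
                    seen_ids.add(d)
                    ids.append(d)

    local = SimilarityMatrix(ids, mode="local")
    glob = SimilarityMatrix(ids, mode="global")
    staged: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, s_loc, s_glob in rows:
        key = (a, b) if a <= b else (b, a)
        if key in staged:
            old = staged[key]
            if old != (s_loc, s_glob):
                warnings.warn(
                    f"asymmetric duplicate scores for pair {key}; keeping the maximum",
                    stacklevel=2,
                )
            staged[key] = (max(old[0], s_loc), max(old[1], s_glob))
        else:
            staged[key] = (s_loc, s_glob)
    for (a, b), (s_loc, s_glob) in staged.items():
        if a == b:
            continue
        local.set(a, b, s_loc)
        glob.set(a, b, s_glob)
    return local, glob


def write_score_table(local: SimilarityMatrix, glob: SimilarityMatrix, path: str | Path) -> None:
    """Write the (local, global) matrix pair as a 4-column score table."""
    if local.ids != glob.ids:
        raise ValueError("local and global matrices must share id order")
    with open(path, "w") as fh:
        fh.write("# domain_a\tdomain_b\tscore_local\tscore_global\n")
        for a, b, s_loc in local.pairs():
            s_glob = glob.get(a, b)
            fh.write(f"{a}\t{b}\t{s_loc:.6f}\t{s_glob:.6f}\n")


# ---------------------------------------------------------------------------
# PDB CA reader
# ---------------------------------------------------------------------------

def read_ca_coordinates(path: str | Path, chain: str | None = None, domain_id: str | None = None):
    """Extract the CA trace from a PDB-format file.

    Only the first model is read; altloc 'A' or blank is accepted; residues
    are ordered by (chain, residue number, insertion code).  A duplicate CA
    for a residue keeps the first occurrence with a warning.
    """
    from .tmscore import Structure  # local import to avoid a cycle

    coords: list[tuple[float, float, float]] = []
    keys: list[tuple[str, int, str]] = []
    seen: set[tuple[str, int, str]] = set()
    with open(path) as fh:
        for raw in fh:
            if raw.startswith("ENDMDL"):
                break
            if not raw.startswith(("ATOM", "HETATM")):
                continue
            name = raw[12:16].strip()
            if name != "CA":
                continue
            altloc = raw[16].strip()
            if altloc not in ("", "A"):
                continue
            ch = raw[21].strip()
            if chain is not None and ch != chain:
                continue
            resseq = int(raw[22:26])
            icode = raw[26].strip()
            key = (ch, resseq, icode)
            if key in seen:
                warnings.warn(f"duplicate CA for residue {key}; keeping first", stacklevel=2)
                continue
            seen.add(key)
            keys.append(key)
            coords.append((float(raw[30:38]), float(raw[38:46]), float(raw[46:54])))
    if not coords:
        raise FormatError(f"{path}: no CA atoms found" + (f" in chain {chain}" if chain else ""))
    order = sorted(range(len(keys)), key=lambda i: keys[i])
    arr = np.array([coords[i] for i in order], dtype=float)
    return Structure(domain_id or Path(path).stem, arr)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_classification_report(results, path: str | Path, top_n: int = 3) -> None:
    """Write a deterministic tab-separated classification report.

    One row per query (sorted by query id): the original fold, the
    assignment under each computed method, and the top-``top_n`` fold
    scores per method.
    """
    results = list(results)
    if not results:
        raise ValueError("cannot write a report for an empty result set")
    methods = sorted({m for r in results for m in r.assigned})
    header = ["query_id", "original_fold"]
    for m in methods:
        header.append(f"assigned_{m}")
        header.append(f"top{top_n}_{m}")
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for r in sorted(results, key=lambda r: r.query_id):
            row = [r.query_id, r.original_fold or "NA"]
            for m in methods:
                row.append(r.assigned.get(m, "NA"))
                scores = r.fold_scores.get(m, {})
                top = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
                row.append(",".join(f"{f}:{s:.4f}" for f, s in top))
            fh.write("\t".join(row) + "\n")
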