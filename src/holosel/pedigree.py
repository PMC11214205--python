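"""Pedigrees and the additive (numerator) relationship matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

UNKNOWN = "0"

_COLUMNS = ["animal", "sire", "dam", "generation", "line", "sex", "litter", "batch"]


@dataclass
class Pedigree:
    """Animal/sire/dam records with study metadata.

    ``frame`` holds one row per animal with columns animal, sire, dam,
    generation, line, sex, litter, batch.  Unknown parents are coded "0" and
    treated as unrelated founders.  Construction validates acyclicity and
    reorders records so that parents precede offspring.
    """

    frame: pd.DataFrame
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in ("animal", "sire", "dam") if c not in df.columns]
        if missing:
            raise ValueError(f"pedigree is missing columns: {missing}")
        for c in _COLUMNS:
            if c not in df.columns:
                df[c] = UNKNOWN if c in ("sire", "dam") else ""
        df = df[_COLUMNS].astype({"animal": str, "sire": str, "dam": str})
        if df["animal"].duplicated().any():
            dups = df.loc[df["animal"].duplicated(), "animal"].tolist()[:5]
            raise ValueError(f"duplicate animal ids: {dups}")
        self.frame = _topological_sort(df)
        self._index = {a: i for i, a in enumerate(self.frame["animal"])}

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def animals(self) -> list[str]:
        return list(self.frame["animal"])

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """(sire_idx, dam_idx) per animal in sorted order; -1 for unknown."""
        sire = np.array([self._index.get(s, -1) for s in self.frame["sire"]])
        dam = np.array([self._index.get(d, -1) for d in self.frame["dam"]])
        return sire, dam

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Pedigree":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def _topological_sort(df: pd.DataFrame) -> pd.DataFrame:
    """Order records parents-before-offspring; raise on cycles."""
    ids = list(df["animal"])
    idx = {a: i for i, a in enumerate(ids)}
    children: dict[int, list[int]] = {i: [] for i in range(len(ids))}
    indeg = np.zeros(len(ids), dtype=int)
    for i, (s, d) in enumerate(zip(df["sire"], df["dam"])):
        for p in (s, d):
            if p != UNKNOWN and p in idx:
                children[idx[p]].append(i)
                indeg[i] += 1
    from collections import deque

    order = []
    queue = deque(i for i in range(len(ids)) if indeg[i] == 0)
    while queue:
        i = queue.popleft()  # FIFO keeps the input order stable
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != len(ids):
        cycle = [ids[i] for i in range(len(ids)) if indeg[i] > 0]
        raise ValueError(f"pedigree contains a cycle involving: {cycle[:10]}")
    return df.iloc[order].reset_index(drop=True)


def a_matrix(ped: Pedigree, subjects: list[str] | None = None) -> pd.DataFrame:
    """Additive relationship matrix by the tabular method.

    a_ii = 1 + 0.5 * a(sire, dam); a_ij = 0.5 * (a(j, sire_i) + a(j, dam_i))
    for j processed before i.  Unknown parents contribute zero (founders are
    assumed unrelated and non-inbred).  ``subjects`` restricts the returned
    matrix to those animals (the full recursion always runs over the whole
    pedigree).
    """
    n = len(ped)
    sire, dam = ped.parent_indices()
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if i > 0:
            row = np.zeros(i)
            if s >= 0:
                row += 0.5 * A[s, :i]
            if d >= 0:
                row += 0.5 * A[d, :i]
            A[i, :i] = row
            A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    out = pd.DataFrame(A, index=ped.animals, columns=ped.animals)
    if subjects is not None:
        missing = [s for s in subjects if s not in out.index]
        if missing:
            raise KeyError(f"subjects not in pedigree: {missing[:5]}")
        out = out.loc[subjects, subjects]
    return out


def inbreeding(ped: Pedigree) -> pd.Series:
    """Inbreeding coefficients F_i = a_ii - 1."""
    A = a_matrix(ped)
    return pd.Series(np.diag(A.to_numpy()) - 1.0, index=A.index, name="F")
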