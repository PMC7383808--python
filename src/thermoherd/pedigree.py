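"""Pedigree handling: numerator relationship matrix A, its sparse inverse, and
genotyped-block (A22) operations.

Animals are re-coded internally to consecutive integers in topological order
(parents before offspring).  Unknown parents are treated as unrelated base
animals.  Inbreeding is accounted for throughout: the tabular method yields
``diag(A) = 1 + F`` and the sparse inverse uses Henderson's rules with
Meuwissen–Luo Mendelian-sampling variances.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = ["Pedigree", "read_pedigree"]

UNKNOWN = -1


def read_pedigree(path) -> "Pedigree":
    """Read an animal,sire,dam CSV ("0" or empty parent = unknown)."""
    df = pd.read_csv(path, dtype=str).fillna("0")
    return Pedigree.from_frame(df)


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    Attributes
    ----------
    ids : list
        Original animal identifiers, in internal (topological) order.
    sire, dam : ndarray of int
        Internal parent indices, ``-1`` for unknown.
    """

    ids: list
    sire: np.ndarray
    dam: np.ndarray
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._pos:
            self._pos = {a: i for i, a in enumerate(self.ids)}
        if len(self._pos) != len(self.ids):
            raise ValueError("animal ids are not unique")

    # ------------------------------------------------------------------ build
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        """Build from a DataFrame with columns animal, sire, dam.

        Parents not listed as animals are added as founders.  Output order is
        topological (parents precede offspring); a cycle raises with the
        offending animals named.
        """
        cols = list(df.columns[:3])
        animals = df[cols[0]].tolist()
        sires = df[cols[1]].tolist()
        dams = df[cols[2]].tolist()

        def known(x):
            return not (pd.isna(x) or x == 0 or x == "0" or x == "")

        known_ids = set(animals)
        extra = []
        for p in sires + dams:
            if known(p) and p not in known_ids:
                known_ids.add(p)
                extra.append(p)
        all_ids = extra + animals  # founders-first guess; real order from sort
        parent_of = {a: (s if known(s) else None, d if known(d) else None) for a, s, d in zip(animals, sires, dams)}
        for p in extra:
            parent_of[p] = (None, None)

        # Kahn topological sort
        children: dict = {a: [] for a in all_ids}
        indeg = {a: 0 for a in all_ids}
        for a, (s, d) in parent_of.items():
            for p in (s, d):
                if p is not None:
                    children[p].append(a)
                    indeg[a] += 1
        queue = deque(a for a in all_ids if indeg[a] == 0)
        order = []
        while queue:
            a = queue.popleft()
            order.append(a)
            for c in children[a]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(all_ids):
            cyclic = sorted(str(a) for a in all_ids if indeg[a] > 0)
            raise ValueError(f"pedigree contains a cycle involving: {', '.join(cyclic)}")

        pos = {a: i for i, a in enumerate(order)}
        sire_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
        dam_idx = np.full(len(order), UNKNOWN, dtype=np.int64)
        for a, (s, d) in parent_of.items():
            if s is not None:
                sire_idx[pos[a]] = pos[s]
            if d is not None:
                dam_idx[pos[a]] = pos[d]
        return cls(ids=order, sire=sire_idx, dam=dam_idx, _pos=pos)

    # ------------------------------------------------------------- utilities
    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, animal) -> int:
        return self._pos[animal]

    def indices(self, animals) -> np.ndarray:
        return np.array([self._pos[a] for a in animals], dtype=np.int64)

    def to_frame(self) -> pd.DataFrame:
        def name(i):
            return self.ids[i] if i != UNKNOWN else "0"

        return pd.DataFrame(
            {
                "animal": self.ids,
                "sire": [name(s) for s in self.sire],
                "dam": [name(d) for d in self.dam],
            }
        )

    def extract_generations(self, focal, n_gen: int) -> "Pedigree":
        """Sub-pedigree of ``focal`` animals plus ancestors up to ``n_gen``
        generations back; parents outside the cut become unknown."""
        if n_gen < 0:
            raise ValueError("n_gen must be >= 0")
        focal_idx = self.indices(list(focal))
        keep: dict[int, int] = {}  # index -> generations remaining when reached
        frontier = {int(i): n_gen for i in focal_idx}
        while frontier:
            nxt: dict[int, int] = {}
            for i, g in frontier.items():
                if i in keep and keep[i] >= g:
                    continue
                keep[i] = g
                if g > 0:
                    for p in (self.sire[i], self.dam[i]):
                        if p != UNKNOWN:
                            nxt[int(p)] = max(g - 1, nxt.get(int(p), -1))
            frontier = nxt
        order = sorted(keep)  # topological order is preserved by index order
        sel = {i: k for k, i in enumerate(order)}
        sire = np.array([sel.get(int(self.sire[i]), UNKNOWN) if self.sire[i] != UNKNOWN else UNKNOWN for i in order])
        dam = np.array([sel.get(int(self.dam[i]), UNKNOWN) if self.dam[i] != UNKNOWN else UNKNOWN for i in order])
        return Pedigree(ids=[self.ids[i] for i in order], sire=sire, dam=dam)

    # ---------------------------------------------------------- relationship
    def a_matrix(self) -> np.ndarray:
        """Dense numerator relationship matrix by the tabular method."""
        n = len(self)
        A = np.zeros((n, n))
        for i in range(n):
            s, d = self.sire[i], self.dam[i]
            if s != UNKNOWN and d != UNKNOWN:
                A[i, i] = 1.0 + 0.5 * A[s, d]
            else:
                A[i, i] = 1.0
            if i:
                row = np.zeros(i)
                if s != UNKNOWN:
                    row += 0.5 * A[:i, s]
                if d != UNKNOWN:
                    row += 0.5 * A[:i, d]
                A[i, :i] = row
                A[:i, i] = row
        return A

    def inbreeding(self) -> np.ndarray:
        """Inbreeding coefficients F (Meuwissen–Luo style, via kinships)."""
        memo: dict[tuple[int, int], float] = {}
        sire, dam = self.sire, self.dam

        def kin(i: int, j: int) -> float:
            # kinship phi(i,j); pedigree order means max(i,j) is never an
            # ancestor of min(i,j)'s parents' recursion target
            if i == UNKNOWN or j == UNKNOWN:
                return 0.0
            if i > j:
                i, j = j, i
            key = (i, j)
            if key in memo:
                return memo[key]
            if i == j:
                val = 0.5 * (1.0 + kin(sire[i], dam[i]))
            else:
                # j is the later animal: expand through j's parents
                val = 0.5 * (kin(i, sire[j]) + kin(i, dam[j]))
            memo[key] = val
            return val

        F = np.empty(len(self))
        for i in range(len(self)):
            F[i] = kin(sire[i], dam[i])  # phi(s,d) = F of offspring
        return F

    def a_inverse(self, inbreeding: bool = True) -> sparse.csr_matrix:
        """Sparse A^-1 via Henderson's rules.

        With ``inbreeding=True`` (default) the Mendelian-sampling variances
        use parental inbreeding coefficients (Meuwissen–Luo); otherwise the
        classic non-inbred rules apply.
        """
        n = len(self)
        F = self.inbreeding() if inbreeding else np.zeros(n)
        rows, cols, vals = [], [], []

        def add(i, j, v):
            rows.append(i)
            cols.append(j)
            vals.append(v)

        for i in range(n):
            s, d = int(self.sire[i]), int(self.dam[i])
            if s != UNKNOWN and d != UNKNOWN:
                mend = 0.5 - 0.25 * (F[s] + F[d])
            elif s != UNKNOWN or d != UNKNOWN:
                p = s if s != UNKNOWN else d
                mend = 0.75 - 0.25 * F[p]
            else:
                mend = 1.0
            alpha = 1.0 / mend
            add(i, i, alpha)
            for p in (s, d):
                if p != UNKNOWN:
                    add(i, p, -alpha / 2)
                    add(p, i, -alpha / 2)
            for p in (s, d):
                if p != UNKNOWN:
                    for q in (s, d):
                        if q != UNKNOWN:
                            add(p, q, alpha / 4)
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def a22(self, genotyped) -> np.ndarray:
        """Genotyped-by-genotyped block of A (dense)."""
        idx = self.indices(list(genotyped))
        A = self.a_matrix()
        return A[np.ix_(idx, idx)]

    def a22_inverse(self, genotyped) -> np.ndarray:
        """Inverse of the genotyped block of A (computed from full A)."""
        block = self.a22(genotyped)
        try:
            return np.linalg.inv(block)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
            raise ValueError("A22 block is singular (duplicate identical animals?)") from exc
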