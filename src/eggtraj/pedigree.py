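"""Pedigree storage and pedigree relationship matrices.

Holds renumbered pedigrees (parents always precede offspring), computes
inbreeding coefficients, the numerator relationship matrix A by the tabular
method, its sparse inverse by Henderson's rules with inbreeding, and the
genotyped-subset block A22 sliced from the full-pedigree A.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import sparse

__all__ = [
    "Pedigree",
    "RelMatrix",
    "PedigreeError",
    "read_pedigree",
    "inbreeding",
    "build_A",
    "build_A_inverse",
]

UNKNOWN = -1


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Renumbered pedigree: index i has parents sire[i], dam[i] (or -1).

    ``labels`` maps the internal 0-based index back to the original animal
    identifiers; ``hatch_week`` is the contemporary-group label (and age
    proxy) of each animal, NaN-able for founders without records.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: np.ndarray
    hatch_week: np.ndarray
    sex: np.ndarray | None = None
    generation: np.ndarray | None = None
    _label_to_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        self.labels = np.asarray(self.labels)
        n = self.n
        for name, arr in (("sire", self.sire), ("dam", self.dam)):
            if arr.shape != (n,):
                raise PedigreeError(f"{name} has wrong length")
            bad = np.flatnonzero((arr >= np.arange(n)) & (arr != UNKNOWN))
            if bad.size:
                raise PedigreeError(
                    f"parents must precede offspring; offending index {bad[0]}"
                )
            if ((arr < UNKNOWN)).any():
                raise PedigreeError(f"negative {name} index other than UNKNOWN")
        if len(set(self.labels.tolist())) != n:
            raise PedigreeError("duplicate animal labels")
        self._label_to_index = {lab: i for i, lab in enumerate(self.labels.tolist())}

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    def index_of(self, labels) -> np.ndarray:
        """Internal indices for original animal labels (fatal if absent)."""
        try:
            return np.array([self._label_to_index[l] for l in labels], dtype=np.int64)
        except KeyError as e:
            raise PedigreeError(f"animal {e.args[0]!r} not in pedigree") from None

    def is_founder(self) -> np.ndarray:
        return (self.sire == UNKNOWN) & (self.dam == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        def lab(parent):
            out = self.labels[np.maximum(parent, 0)].astype(object)
            out[parent == UNKNOWN] = "0"
            return out

        return pd.DataFrame(
            {
                "animal": self.labels,
                "sire": lab(self.sire),
                "dam": lab(self.dam),
                "hatch_week": self.hatch_week,
            }
        )


@dataclass
class RelMatrix:
    """A relationship matrix (dense or sparse) with its id map.

    ``kind`` is one of A, Ainv, A22, A22inv, G, Gblend, Ginv, Hinv.
    """

    values: object
    ids: np.ndarray
    kind: str

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def toarray(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)


def _toposort(animal, sire, dam):
    """Kahn topological order over parent->offspring edges.

    Ties are broken by animal label so the renumbering is independent of
    the input row order.  Raises on cycles with an offending chain.
    """
    import heapq

    n = len(animal)
    pos = {a: i for i, a in enumerate(animal)}
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=int)
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p in pos:
                children[pos[p]].append(i)
                indeg[i] += 1
    order = []
    heap = [(str(animal[i]), i) for i in np.flatnonzero(indeg == 0)]
    heapq.heapify(heap)
    seen = np.zeros(n, dtype=bool)
    while heap:
        _, i = heapq.heappop(heap)
        order.append(i)
        seen[i] = True
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, (str(animal[c]), c))
    if len(order) < n:
        rem = np.flatnonzero(~seen)
        # walk one cycle for the error message
        start = rem[0]
        chain, cur = [animal[start]], start
        while True:
            nxt = sire[cur] if sire[cur] in pos and not seen[pos[sire[cur]]] else dam[cur]
            cur = pos[nxt]
            chain.append(animal[cur])
            if animal[cur] == chain[0] or len(chain) > n:
                break
        raise PedigreeError(f"pedigree cycle detected: {' -> '.join(map(str, chain))}")
    return order


def read_pedigree(path) -> Pedigree:
    """Read a pedigree CSV with columns animal, sire, dam, hatch_week.

    A parent of 0 or blank is unknown.  Animals listed out of order are
    renumbered so parents precede offspring; parents appearing only as
    parents are added as founders.  Duplicate ids and cycles are fatal.
    """
    df = pd.read_csv(path, comment="#", dtype={"animal": str, "sire": str, "dam": str})
    required = {"animal", "sire", "dam", "hatch_week"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"pedigree file must have columns {sorted(required)}, got {list(df.columns)}"
        )

    def norm(col):
        s = df[col].fillna("0").astype(str).str.strip()
        return s.replace({"": "0", "0.0": "0"}).tolist()

    animal, sire, dam = norm("animal"), norm("sire"), norm("dam")
    if len(set(animal)) != len(animal):
        dup = pd.Series(animal)
        dup = dup[dup.duplicated()].iloc[0]
        raise PedigreeError(f"duplicate animal id {dup!r}")
    for i, a in enumerate(animal):
        if a != "0" and (a == sire[i] or a == dam[i]):
            raise PedigreeError(f"pedigree cycle detected: {a} is its own parent")
    hatch = dict(zip(animal, df["hatch_week"].tolist()))
    # parents never listed as animals become founders
    listed = set(animal)
    extra = [p for p in dict.fromkeys(sire + dam) if p != "0" and p not in listed]
    animal = extra + animal
    sire = ["0"] * len(extra) + sire
    dam = ["0"] * len(extra) + dam
    order = _toposort(animal, sire, dam)
    labels = [animal[i] for i in order]
    newpos = {animal[i]: k for k, i in enumerate(order)}
    sire_ix = np.array(
        [newpos[sire[i]] if sire[i] != "0" else UNKNOWN for i in order], dtype=np.int64
    )
    dam_ix = np.array(
        [newpos[dam[i]] if dam[i] != "0" else UNKNOWN for i in order], dtype=np.int64
    )
    hw = np.array([hatch.get(l, np.nan) for l in labels], dtype=float)
    return Pedigree(sire=sire_ix, dam=dam_ix, labels=np.array(labels), hatch_week=hw)


@njit(cache=True)
def _tabular_A(sire, dam):  # pragma: no cover - exercised via build_A
    n = sire.shape[0]
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        for i in range(j):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[i, s]
            if d >= 0:
                a += 0.5 * A[i, d]
            A[i, j] = a
            A[j, i] = a
        ajj = 1.0
        if s >= 0 and d >= 0:
            ajj += 0.5 * A[s, d]
        A[j, j] = ajj
    return A


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients F with F_i = A_ii - 1 (founders 0)."""
    # The tabular diagonal is the reference definition; for the pedigree
    # sizes this package targets the O(N^2) tabular method is fast enough
    # and avoids a subtle ancestor-bookkeeping implementation.
    A_diag = _tabular_diag(ped.sire, ped.dam)
    return A_diag - 1.0


@njit(cache=True)
def _tabular_diag(sire, dam):  # pragma: no cover
    n = sire.shape[0]
    A = np.zeros((n, n))
    for j in range(n):
        s, d = sire[j], dam[j]
        for i in range(j):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[i, s]
            if d >= 0:
                a += 0.5 * A[i, d]
            A[i, j] = a
            A[j, i] = a
        ajj = 1.0
        if s >= 0 and d >= 0:
            ajj += 0.5 * A[s, d]
        A[j, j] = ajj
    return np.diag(A).copy()


def build_A(ped: Pedigree, subset: Sequence | None = None) -> RelMatrix:
    """Numerator relationship matrix by the tabular method.

    With ``subset`` (original labels), A is computed over the FULL pedigree
    and then sliced to the subset rows/columns (kind A22).
    """
    A = _tabular_A(ped.sire, ped.dam)
    if subset is None:
        return RelMatrix(values=A, ids=ped.labels.copy(), kind="A")
    subset = list(subset)
    if len(subset) == 0:
        return RelMatrix(values=np.zeros((0, 0)), ids=np.array([]), kind="A22")
    ix = ped.index_of(subset)
    return RelMatrix(values=A[np.ix_(ix, ix)], ids=np.asarray(subset), kind="A22")


def build_A_inverse(ped: Pedigree, F: np.ndarray | None = None) -> RelMatrix:
    """Sparse inverse of A by Henderson's rules, accounting for inbreeding.

    For animal i with Mendelian-sampling variance
    d_i = 0.5 - 0.25 (F_s + F_d) (an unknown parent contributes F = -1,
    i.e. d_i gains 0.25 per unknown parent), add (1/d_i) * w w' over the
    (i, sire, dam) triple with weights (1, -0.5, -0.5).
    """
    if F is None:
        F = inbreeding(ped)
    n = ped.n
    rows, cols, vals = [], [], []
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        di = 0.5
        di += 0.25 if s == UNKNOWN else -0.25 * F[s]
        di += 0.25 if d == UNKNOWN else -0.25 * F[d]
        alpha = 1.0 / di
        members = [(i, 1.0)]
        if s != UNKNOWN:
            members.append((s, -0.5))
        if d != UNKNOWN:
            members.append((d, -0.5))
        for a, wa in members:
            for b, wb in members:
                rows.append(a)
                cols.append(b)
                vals.append(alpha * wa * wb)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelMatrix(values=Ainv, ids=ped.labels.copy(), kind="Ainv")
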