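"""Numerator relationship machinery.

The pedigree is stored renumbered so that parents always precede their
offspring; individuals are 1..n and the unknown-parent sentinel is 0 (the
usual BLUP convention).  From it we compute inbreeding coefficients
(Meuwissen & Luo's recursive algorithm), the sparse inverse of the
numerator relationship matrix A via Henderson's rules with
inbreeding-adjusted Mendelian-sampling variances, and the dense
genotyped-by-genotyped block A22 without ever forming the full dense A.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """Renumbered pedigree.

    Attributes
    ----------
    sire, dam : int arrays of length n+1 (index 0 unused); entry 0 = unknown.
    labels : original identifiers, labels[i] for individual i (1-based).
    F : inbreeding coefficients, length n+1, F[0] = 0 by convention.
    genotyped : boolean mask, length n+1.
    """

    sire: np.ndarray
    dam: np.ndarray
    labels: np.ndarray
    F: np.ndarray | None = None
    genotyped: np.ndarray | None = None
    _label_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._label_index:
            self._label_index = {lab: i for i, lab in enumerate(self.labels)}
        for i in range(1, self.n + 1):
            if self.sire[i] >= i or self.dam[i] >= i:
                raise PedigreeError(f"pedigree not renumbered: parent of {i} does not precede it")

    @property
    def n(self) -> int:
        return len(self.sire) - 1

    def id_of(self, label) -> int:
        return self._label_index[label]

    def ids_of(self, labels) -> np.ndarray:
        return np.asarray([self._label_index[l] for l in labels], dtype=np.int64)

    def with_inbreeding(self) -> "Pedigree":
        if self.F is None:
            self.F = compute_inbreeding(self)
        return self

    def set_genotyped(self, labels) -> "Pedigree":
        mask = np.zeros(self.n + 1, dtype=bool)
        mask[self.ids_of(labels)] = True
        self.genotyped = mask
        return self


def renumber(triples, id_policy: str = "strict") -> Pedigree:
    """Topologically renumber (individual, sire, dam) triples.

    Unknown parents are coded 0, "0", "" or None.  With
    ``id_policy="add_missing_founders"``, parent labels never listed as
    individuals are appended as founders; with ``"strict"`` they raise.
    A cycle (an individual among its own ancestors) raises
    :class:`PedigreeError` naming one individual on the cycle.
    """
    if id_policy not in ("strict", "add_missing_founders"):
        raise ValueError(f"unknown id_policy {id_policy!r}")

    def _missing(x) -> bool:
        return x is None or x == 0 or x == "0" or x == "" or (isinstance(x, float) and np.isnan(x))

    parents: dict = {}
    order_seen: list = []
    for ind, s, d in triples:
        if _missing(ind):
            raise PedigreeError("individual id missing in pedigree row")
        if ind in parents:
            raise PedigreeError(f"duplicate pedigree entry for {ind!r}")
        parents[ind] = (None if _missing(s) else s, None if _missing(d) else d)
        order_seen.append(ind)

    extra = []
    for ind in order_seen:
        for p in parents[ind]:
            if p is not None and p not in parents and p not in extra:
                if id_policy == "strict":
                    raise PedigreeError(f"parent {p!r} of {ind!r} not listed as an individual")
                extra.append(p)
    for p in extra:
        parents[p] = (None, None)
    all_ids = extra + order_seen  # founders first helps but Kahn handles any order

    # Kahn's algorithm on the parent -> offspring DAG.
    n_par = {ind: sum(p is not None for p in parents[ind]) for ind in all_ids}
    children: dict = {ind: [] for ind in all_ids}
    for ind in all_ids:
        for p in parents[ind]:
            if p is not None:
                children[p].append(ind)
    queue = [ind for ind in all_ids if n_par[ind] == 0]
    topo: list = []
    qi = 0
    while qi < len(queue):
        ind = queue[qi]
        qi += 1
        topo.append(ind)
        for c in children[ind]:
            n_par[c] -= 1
            if n_par[c] == 0:
                queue.append(c)
    if len(topo) != len(all_ids):
        on_cycle = next(ind for ind in all_ids if n_par[ind] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving {on_cycle!r}")

    n = len(topo)
    labels = np.empty(n + 1, dtype=object)
    labels[0] = None
    idx = {}
    for i, ind in enumerate(topo, start=1):
        labels[i] = ind
        idx[ind] = i
    sire = np.zeros(n + 1, dtype=np.int64)
    dam = np.zeros(n + 1, dtype=np.int64)
    for ind in topo:
        i = idx[ind]
        s, d = parents[ind]
        sire[i] = 0 if s is None else idx[s]
        dam[i] = 0 if d is None else idx[d]
    return Pedigree(sire=sire, dam=dam, labels=labels, _label_index=idx)


def compute_inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo recursion.

    Runs in O(n * mean ancestral path length^2); exact, no dense A.
    """
    n = ped.n
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n + 1)
    # Mendelian sampling D computed on the fly; point[] holds the partial
    # contribution of each ancestor while sweeping one individual.
    point = np.zeros(n + 1)
    for i in range(1, n + 1):
        s, d = sire[i], dam[i]
        if s == 0 or d == 0:
            F[i] = 0.0
            continue
        fi = -1.0
        point[i] = 1.0
        stack = [i]
        # process ancestors in decreasing id order
        anc = {i}
        j = i
        while j > 0:
            if j in anc:
                r = point[j]
                sj, dj = sire[j], dam[j]
                if sj > 0:
                    point[sj] += 0.5 * r
                    anc.add(sj)
                if dj > 0:
                    point[dj] += 0.5 * r
                    anc.add(dj)
                Dj = 0.5 - 0.25 * (F[sj] + F[dj])
                if sj == 0 and dj == 0:
                    Dj = 1.0
                elif sj == 0 or dj == 0:
                    Dj = 0.75 - 0.25 * (F[sj] if sj > 0 else F[dj])
                fi += r * r * Dj
                point[j] = 0.0
                anc.discard(j)
            j -= 1
        F[i] = fi
    return F


def _mendelian_variance(F: np.ndarray, s: int, d: int) -> float:
    if s > 0 and d > 0:
        return 0.5 - 0.25 * (F[s] + F[d])
    if s > 0 or d > 0:
        return 0.75 - 0.25 * (F[s] if s > 0 else F[d])
    return 1.0


def build_A_inverse(ped: Pedigree) -> sp.csc_matrix:
    """Sparse A^{-1} via Henderson's rules with parental inbreeding."""
    ped.with_inbreeding()
    n, sire, dam, F = ped.n, ped.sire, ped.dam, ped.F
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i - 1)
        cols.append(j - 1)
        vals.append(v)

    for i in range(1, n + 1):
        s, d = sire[i], dam[i]
        b = 1.0 / _mendelian_variance(F, s, d)
        add(i, i, b)
        for p in (s, d):
            if p > 0:
                add(i, p, -0.5 * b)
                add(p, i, -0.5 * b)
        if s > 0:
            add(s, s, 0.25 * b)
        if d > 0:
            add(d, d, 0.25 * b)
        if s > 0 and d > 0:
            add(s, d, 0.25 * b)
            add(d, s, 0.25 * b)
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def tabular_A(ped: Pedigree) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    O(n^2) memory — an oracle / small-pedigree utility, not the production
    route (build_A_inverse and build_A22 avoid it).
    """
    n, sire, dam = ped.n, ped.sire, ped.dam
    A = np.zeros((n + 1, n + 1))
    for i in range(1, n + 1):
        s, d = sire[i], dam[i]
        for j in range(1, i):
            a = 0.0
            if s > 0:
                a += 0.5 * A[j, s]
            if d > 0:
                a += 0.5 * A[j, d]
            A[j, i] = A[i, j] = a
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s > 0 and d > 0) else 0.0)
    return A[1:, 1:]


def build_A22(ped: Pedigree, genotyped_ids: np.ndarray | None = None) -> np.ndarray:
    """Genotyped block of A, computed indirectly.

    Solves A^{-1} x = e_j for each genotyped column j with a single sparse
    LU factorization, reading off the genotyped rows; this is the exact
    A22 (NOT the inverse of a block of A^{-1}) at O(g) sparse solves.
    """
    if genotyped_ids is None:
        if ped.genotyped is None:
            raise PedigreeError("no genotyped individuals recorded on the pedigree")
        genotyped_ids = np.flatnonzero(ped.genotyped)
    genotyped_ids = np.asarray(genotyped_ids, dtype=np.int64)
    if genotyped_ids.size == 0:
        raise PedigreeError("empty genotyped set")
    ainv = build_A_inverse(ped)
    lu = splu(ainv)
    g = genotyped_ids.size
    rhs = np.zeros((ped.n, g))
    rhs[genotyped_ids - 1, np.arange(g)] = 1.0
    cols = lu.solve(rhs)
    a22 = cols[genotyped_ids - 1, :]
    return 0.5 * (a22 + a22.T)
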