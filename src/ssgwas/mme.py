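"""Henderson's mixed-model equations for the direct and maternal animal
models.

The direct model is  y = Xb + Vu + Wp + e  with var(u) = H sigma2_a,
var(p) = I sigma2_p, var(e) = I sigma2_e.  The maternal (weaning-weight)
model adds the dam's additive maternal effect, y = Xb + Zu + Tm + Wp + e,
with var([u; m]) = K0 (x) H where K0 = [[s2_a, s_am], [s_am, s2_m]].

Random effects are held as generic *terms*: one or more incidence
matrices sharing a correlation structure (H for the genetic term, I for
herd-year-season), which is what the REML engine iterates over.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import cg, splu

from .pedigree import Pedigree


class ModelError(ValueError):
    pass


@dataclass
class TraitModelSpec:
    """Which effects enter the model for one trait."""

    trait: str
    factors: tuple = ("sex", "dam_age")
    covariates: tuple = ()
    hys: str = "hys"
    maternal: bool = False


@dataclass
class RandomTerm:
    """One (group of) random effect(s) sharing a correlation structure.

    ``incidence`` holds t record-by-level matrices (t = 2 for the
    correlated direct + maternal pair); ``Kinv`` is the q x q inverse
    structure matrix (H^-1, or I), ``logdet_K`` its log-determinant.
    """

    name: str
    effect_names: tuple
    incidence: list
    Kinv: sp.spmatrix
    logdet_K: float

    @property
    def n_effects(self) -> int:
        return len(self.incidence)

    @property
    def n_levels(self) -> int:
        return self.incidence[0].shape[1]


@dataclass
class MMESystem:
    """Design of one trait's evaluation: response, fixed design and the
    random terms, plus bookkeeping for solution labelling."""

    y: np.ndarray
    X: np.ndarray
    x_labels: list
    terms: list
    record_ids: np.ndarray
    hys_levels: list = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.y)

    @property
    def rank_X(self) -> int:
        return int(np.linalg.matrix_rank(self.X))

    def term(self, name: str) -> RandomTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


def _indicator(codes: np.ndarray, n_cols: int) -> sp.csr_matrix:
    n = len(codes)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), codes)), shape=(n, n_cols)
    )


def build_fixed_design(records, factors, covariates):
    """Reference-level fixed design: the first factor contributes all its
    levels (absorbing the intercept), later factors drop their first
    level; covariates are centered at the sample mean."""
    cols, labels = [], []
    for k, f in enumerate(factors):
        levels = sorted(records[f].unique())
        if len(levels) < 2 and k > 0:
            continue  # single-level factor after the first is vacuous
        use = levels if k == 0 else levels[1:]
        for lev in use:
            cols.append((records[f] == lev).to_numpy(float))
            labels.append(f"{f}:{lev}")
    if not cols:
        cols.append(np.ones(len(records)))
        labels.append("intercept")
    for c in covariates:
        v = records[c].to_numpy(float)
        cols.append(v - v.mean())
        labels.append(f"{c}(centered)")
    return np.column_stack(cols), labels


def build_incidence(
    records,
    spec: TraitModelSpec,
    ped: Pedigree,
    Kinv_genetic: sp.spmatrix,
    logdet_K_genetic: float,
) -> MMESystem:
    """Assemble the design of the MME (structure only — no variance
    components yet).

    ``Kinv_genetic`` is H^-1 (or A^-1 for a pedigree-only run) over all
    pedigree individuals, in pedigree order.
    """
    y = records[spec.trait].to_numpy(float)
    X, x_labels = build_fixed_design(records, spec.factors, spec.covariates)

    animal = ped.ids_of(records["individual"])
    V = _indicator(animal - 1, ped.n)
    terms = []
    if spec.maternal:
        dams = ped.dam[animal]
        if np.any(dams == 0):
            bad = records["individual"].to_numpy()[dams == 0][:10]
            raise ModelError(
                f"maternal model requires a known dam for every record; offending "
                f"individuals include {list(bad)}"
            )
        T = _indicator(dams - 1, ped.n)
        terms.append(RandomTerm("genetic", ("additive", "maternal"), [V, T],
                                Kinv_genetic, logdet_K_genetic))
    else:
        terms.append(RandomTerm("genetic", ("additive",), [V],
                                Kinv_genetic, logdet_K_genetic))

    hys_levels = sorted(records[spec.hys].unique())
    hys_code = records[spec.hys].map({l: i for i, l in enumerate(hys_levels)}).to_numpy()
    W = _indicator(hys_code, len(hys_levels))
    terms.append(RandomTerm("hys", ("hys",), [W], sp.identity(len(hys_levels), format="csc"), 0.0))

    return MMESystem(y=y, X=X, x_labels=x_labels, terms=terms,
                     record_ids=records["individual"].to_numpy(),
                     hys_levels=hys_levels)


# ---------------------------------------------------------------------------
# assembly and solving

def stack_design(sys: MMESystem):
    """Full design W = [X, Z_1, ..., Z_k] (sparse) and block offsets."""
    blocks = [sp.csr_matrix(sys.X)]
    offsets = {"fixed": (0, sys.X.shape[1])}
    pos = sys.X.shape[1]
    for t in sys.terms:
        for name, Z in zip(t.effect_names, t.incidence):
            blocks.append(Z)
            offsets[f"{t.name}:{name}"] = (pos, pos + Z.shape[1])
            pos += Z.shape[1]
    return sp.hstack(blocks, format="csr"), offsets


def assemble_mme(sys: MMESystem, varcomp: dict):
    """Fill the MME:  C s = rhs  with
    C = W' W / s2e  +  blockdiag(0, K0^-1 (x) Kinv per term)  and
    rhs = W' y / s2e.

    ``varcomp`` maps each term name to its K0 matrix (t x t) plus key
    ``sigma2_e``.  With this (unscaled) form, C^-1 is directly the
    prediction-error (co)variance matrix.
    """
    s2e = float(varcomp["sigma2_e"])
    if s2e <= 0:
        raise ModelError("residual variance must be positive")
    Wfull, offsets = stack_design(sys)
    dim = Wfull.shape[1]
    parts = [((Wfull.T @ Wfull) / s2e).tocoo()]
    for t in sys.terms:
        K0 = np.atleast_2d(np.asarray(varcomp[t.name], dtype=float))
        if K0.shape != (t.n_effects, t.n_effects):
            raise ModelError(f"K0 for term {t.name!r} has shape {K0.shape}, "
                             f"expected {(t.n_effects, t.n_effects)}")
        eigs = np.linalg.eigvalsh(K0)
        if eigs.min() <= 0:
            raise ModelError(f"(co)variance matrix for term {t.name!r} is not positive definite")
        K0inv = np.linalg.inv(K0)
        kin = t.Kinv.tocoo()
        for a in range(t.n_effects):
            ra = offsets[f"{t.name}:{t.effect_names[a]}"][0]
            for b in range(t.n_effects):
                rb = offsets[f"{t.name}:{t.effect_names[b]}"][0]
                parts.append(sp.coo_matrix(
                    (K0inv[a, b] * kin.data, (kin.row + ra, kin.col + rb)),
                    shape=(dim, dim)))
    C = parts[0]
    for p in parts[1:]:
        C = C + p
    rhs = Wfull.T @ sys.y / s2e
    return C.tocsc(), rhs, offsets


def solve_mme(C, rhs, method: str = "direct", tol: float = None, max_iter: int = 10000):
    """Solve the assembled equations; direct sparse LU or Jacobi-
    preconditioned conjugate gradients."""
    if method == "direct":
        tol = 1e-10 if tol is None else tol
        sol = splu(C.tocsc()).solve(rhs)
    elif method == "pcg":
        tol = 1e-8 if tol is None else tol
        d = C.diagonal()
        M = sp.diags(1.0 / np.where(d > 0, d, 1.0))
        sol, info = cg(C, rhs, M=M, rtol=tol, maxiter=max_iter)
        if info != 0:
            res = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
            raise ModelError(f"PCG did not converge after {max_iter} iterations "
                             f"(relative residual {res:.3e})")
    else:
        raise ValueError(f"unknown method {method!r}")
    res = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if res > max(tol * 100, 1e-6):
        raise ModelError(f"MME solution residual {res:.3e} exceeds tolerance")
    return sol


def split_solutions(sol: np.ndarray, sys: MMESystem, offsets: dict) -> dict:
    """Slice the stacked solution vector into named effect blocks."""
    out = {"fixed": dict(zip(sys.x_labels, sol[: sys.X.shape[1]]))}
    for t in sys.terms:
        for name in t.effect_names:
            lo, hi = offsets[f"{t.name}:{name}"]
            key = name if name != "hys" else "hys"
            out[key] = sol[lo:hi]
    return out
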