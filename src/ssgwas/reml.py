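"""Restricted maximum likelihood for the animal models: EM warm-up
followed by average-information (AI) updates.

The engine works on the generic random-term structure of
:mod:`ssgwas.mme`.  Writing the MME in unscaled form,
C = W'W/s2e + blockdiag(0, K0^-1 (x) K^-1 per term), the inverse
coefficient matrix is the prediction-error covariance, and every trace
the EM and AI updates need reduces to T_ab = tr(K^-1 C^{ab}) over the
inverse blocks of each term.  Those traces are computed exactly by a
dense Cholesky inverse of C each round — the right tool at the problem
sizes this package fits (a few thousand equations), where it is both
exact and fast.

Identities used (t effects per term, structure K, q levels, Py the
projected data vector):
  f_i = (dV/dtheta_i) Py is assembled from the solutions alone,
  tr(P Z_a K Z_b') = [q K0^-1 - K0^-1 T K0^-1]_{ba},
  tr(P) = (n - dim(C) + sum_t tr(K0_t^-1 T_t)) / s2e,
  AI_ij = f_i' P f_j / 2,   with P f = (f - W C^-1 W' f / s2e) / s2e.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg.lapack import dpotrf, dpotri
from scipy.sparse.linalg import splu

from .mme import MMESystem, ModelError, stack_design


class RemlError(RuntimeError):
    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = trace


def logdet_sparse_spd(M: sp.spmatrix) -> float:
    """log-determinant of a sparse SPD matrix via LU."""
    lu = splu(M.tocsc())
    return float(np.sum(np.log(np.abs(lu.U.diagonal()))))


# ---------------------------------------------------------------------------
# variance components container

@dataclass
class VarianceComponents:
    """Named variance components of one trait's model.

    ``k0`` maps each random term to its (co)variance matrix: a 1x1
    [[sigma2_a]] for the direct genetic term, the 2x2
    [[sigma2_a, sigma_am], [sigma_am, sigma2_m]] for the maternal pair,
    [[sigma2_p]] for herd-year-season.  Standard errors (from the inverse
    AI matrix) follow the same layout.
    """

    k0: dict
    sigma2_e: float
    se: dict = field(default_factory=dict)
    se_sigma2_e: float | None = None

    @property
    def sigma2_a(self) -> float:
        return float(self.k0["genetic"][0, 0])

    @property
    def sigma2_m(self) -> float | None:
        g = self.k0["genetic"]
        return float(g[1, 1]) if g.shape[0] > 1 else None

    @property
    def sigma_am(self) -> float | None:
        g = self.k0["genetic"]
        return float(g[0, 1]) if g.shape[0] > 1 else None

    @property
    def sigma2_p(self) -> float:
        return float(self.k0["hys"][0, 0])

    def as_dict(self) -> dict:
        d = dict(self.k0)
        d["sigma2_e"] = self.sigma2_e
        return d

    def named(self) -> dict:
        out = {"sigma2_a": self.sigma2_a, "sigma2_p": self.sigma2_p,
               "sigma2_e": self.sigma2_e}
        if self.sigma2_m is not None:
            out["sigma2_m"] = self.sigma2_m
            out["sigma_am"] = self.sigma_am
        return out


@dataclass
class GeneticParameters:
    h2: float
    h2_mat: float | None = None
    r_a_mat: float | None = None

    def rounded(self, ndigits: int = 3) -> "GeneticParameters":
        r = lambda x: None if x is None else round(x, ndigits)
        return GeneticParameters(r(self.h2), r(self.h2_mat), r(self.r_a_mat))


def derive_parameters(vc: VarianceComponents, model_kind: str = None) -> GeneticParameters:
    """Heritabilities and the direct-maternal correlation.

    The phenotypic-variance denominator is the sum of the variance
    components and deliberately excludes the direct-maternal covariance:
    h2 = s2a / (s2a [+ s2m] + s2p + s2e), h2_mat analogous, and
    r_a,mat = s_am / sqrt(s2a * s2m).
    """
    if model_kind is None:
        model_kind = "maternal" if vc.sigma2_m is not None else "direct"
    denom = vc.sigma2_a + vc.sigma2_p + vc.sigma2_e
    if model_kind == "maternal":
        if vc.sigma2_m is None:
            raise ValueError("maternal parameters requested from a direct-model fit")
        denom += vc.sigma2_m
        if denom <= 0:
            raise ZeroDivisionError("non-positive phenotypic variance")
        return GeneticParameters(
            h2=vc.sigma2_a / denom,
            h2_mat=vc.sigma2_m / denom,
            r_a_mat=vc.sigma_am / np.sqrt(vc.sigma2_a * vc.sigma2_m),
        )
    if denom <= 0:
        raise ZeroDivisionError("non-positive phenotypic variance")
    return GeneticParameters(h2=vc.sigma2_a / denom)


# ---------------------------------------------------------------------------
# engine

def _theta_layout(sys: MMESystem):
    """Parameter vector layout: per term the lower triangle of K0 in row
    order, then the residual variance last."""
    layout = []
    for t in sys.terms:
        for a in range(t.n_effects):
            for b in range(a + 1):
                layout.append((t.name, a, b))
    layout.append(("residual", 0, 0))
    return layout


class RemlEngine:
    """EM / AI-REML on one assembled model structure."""

    def __init__(self, sys: MMESystem):
        self.sys = sys
        self.W, self.offsets = stack_design(sys)
        self.dim = self.W.shape[1]
        self.WtW = np.asarray((self.W.T @ self.W).todense())
        self.Wty = self.W.T @ sys.y
        self.yty = float(sys.y @ sys.y)
        self.n = sys.n_records
        self.rank_X = sys.rank_X
        if self.rank_X < sys.X.shape[1]:
            raise ModelError(
                f"fixed design is rank deficient ({self.rank_X} < {sys.X.shape[1]}); "
                "check for confounded factor levels")
        self.layout = _theta_layout(sys)
        self._kinv_dense = {t.name: np.asarray(t.Kinv.todense()) for t in sys.terms}
        self._slices = {}
        for t in sys.terms:
            for a, name in enumerate(t.effect_names):
                lo, hi = self.offsets[f"{t.name}:{name}"]
                self._slices[(t.name, a)] = slice(lo, hi)

    # -- parameter vector mapping ------------------------------------------
    def theta_from_vc(self, vc: dict) -> np.ndarray:
        th = []
        for name, a, b in self.layout:
            if name == "residual":
                th.append(float(vc["sigma2_e"]))
            else:
                th.append(float(np.atleast_2d(vc[name])[a, b]))
        return np.asarray(th)

    def vc_from_theta(self, theta: np.ndarray) -> dict:
        vc = {}
        for val, (name, a, b) in zip(theta, self.layout):
            if name == "residual":
                vc["sigma2_e"] = float(val)
                continue
            t = self.sys.term(name)
            K0 = vc.setdefault(name, np.zeros((t.n_effects, t.n_effects)))
            K0[a, b] = K0[b, a] = val
        return vc

    def in_parameter_space(self, vc: dict) -> bool:
        if vc["sigma2_e"] <= 0:
            return False
        for t in self.sys.terms:
            if np.linalg.eigvalsh(np.atleast_2d(vc[t.name])).min() <= 0:
                return False
        return True

    # -- one inner evaluation ----------------------------------------------
    def _decompose(self, vc: dict):
        """Dense C, its Cholesky inverse, solutions and per-term traces."""
        s2e = vc["sigma2_e"]
        C = self.WtW / s2e
        k0inv = {}
        for t in self.sys.terms:
            K0 = np.atleast_2d(vc[t.name])
            k0inv[t.name] = np.linalg.inv(K0)
            kd = self._kinv_dense[t.name]
            for a in range(t.n_effects):
                sa = self._slices[(t.name, a)]
                for b in range(t.n_effects):
                    sb = self._slices[(t.name, b)]
                    C[sa, sb] += k0inv[t.name][a, b] * kd
        L, info = dpotrf(C, lower=1, overwrite_a=1)
        if info != 0:
            raise RemlError(f"coefficient matrix not positive definite (dpotrf info={info})")
        logdet_C = 2.0 * float(np.sum(np.log(np.diag(L))))
        Cinv, info = dpotri(L, lower=1, overwrite_c=1)
        if info != 0:
            raise RemlError(f"inversion failed (dpotri info={info})")
        Cinv = np.tril(Cinv) + np.tril(Cinv, -1).T
        sol = Cinv @ (self.Wty / s2e)
        traces = {}
        for t in self.sys.terms:
            kd = self._kinv_dense[t.name]
            T = np.zeros((t.n_effects, t.n_effects))
            for a in range(t.n_effects):
                sa = self._slices[(t.name, a)]
                for b in range(a + 1):
                    sb = self._slices[(t.name, b)]
                    T[a, b] = T[b, a] = float(np.sum(kd * Cinv[sa, sb].T))
            traces[t.name] = T
        return dict(C_chol_logdet=logdet_C, Cinv=Cinv, sol=sol, traces=traces,
                    k0inv=k0inv, s2e=s2e)

    def reml_loglik(self, vc: dict, state=None) -> float:
        """REML log-likelihood up to an additive constant."""
        state = state or self._decompose(vc)
        ypy = (self.yty - state["sol"] @ self.Wty) / state["s2e"]
        val = self.n * np.log(state["s2e"]) + state["C_chol_logdet"] + ypy
        for t in self.sys.terms:
            q = t.n_levels
            val += q * float(np.linalg.slogdet(np.atleast_2d(vc[t.name]))[1])
            val += t.n_effects * t.logdet_K
        return -0.5 * float(val)

    # -- EM ----------------------------------------------------------------
    def em_step(self, vc: dict, state=None) -> dict:
        state = state or self._decompose(vc)
        sol, traces = state["sol"], state["traces"]
        new = {}
        for t in self.sys.terms:
            q = t.n_levels
            kd = self._kinv_dense[t.name]
            K0n = np.zeros((t.n_effects, t.n_effects))
            u = [sol[self._slices[(t.name, a)]] for a in range(t.n_effects)]
            for a in range(t.n_effects):
                for b in range(a + 1):
                    K0n[a, b] = K0n[b, a] = (u[a] @ (kd @ u[b]) + traces[t.name][a, b]) / q
            new[t.name] = K0n
        new["sigma2_e"] = float((self.yty - sol @ self.Wty) / (self.n - self.rank_X))
        return new

    # -- AI ----------------------------------------------------------------
    def _score_and_ai(self, vc: dict, state):
        sol, traces, k0inv, s2e = state["sol"], state["traces"], state["k0inv"], state["s2e"]
        y = self.sys.y
        resid = y - self.W @ sol
        Py = resid / s2e

        fvecs, tr_pv = [], []
        for name, a, b in self.layout:
            if name == "residual":
                fvecs.append(Py)
                tr_p = self.n - self.dim
                for t in self.sys.terms:
                    tr_p += float(np.sum(k0inv[t.name] * traces[t.name]))
                tr_pv.append(tr_p / s2e)
                continue
            t = self.sys.term(name)
            u = [sol[self._slices[(name, c)]] for c in range(t.n_effects)]
            s_vec = [sum(k0inv[name][c, d] * u[d] for d in range(t.n_effects))
                     for c in range(t.n_effects)]
            Q = t.n_levels * k0inv[name] - k0inv[name] @ traces[name] @ k0inv[name]
            if a == b:
                fvecs.append(t.incidence[a] @ s_vec[a])
                tr_pv.append(Q[a, a])
            else:
                fvecs.append(t.incidence[a] @ s_vec[b] + t.incidence[b] @ s_vec[a])
                tr_pv.append(2.0 * Q[a, b])

        F = np.column_stack(fvecs)
        B = state["Cinv"] @ (self.W.T @ F / s2e)
        PF = (F - self.W @ B) / s2e
        AI = 0.5 * (F.T @ PF)
        AI = 0.5 * (AI + AI.T)
        score = -0.5 * (np.asarray(tr_pv) - F.T @ Py)
        return score, AI

    # -- driver ------------------------------------------------------------
    def default_start(self) -> dict:
        vy = float(np.var(self.sys.y))
        vc = {"sigma2_e": 0.5 * vy}
        for t in self.sys.terms:
            if t.n_effects == 2:
                vc[t.name] = vy * np.array([[0.2, -0.05], [-0.05, 0.1]])
            elif t.name == "genetic":
                vc[t.name] = np.array([[0.3 * vy]])
            else:
                vc[t.name] = np.array([[0.1 * vy]])
        return vc

    def fit(self, start: dict = None, em_rounds: int = 100, tol: float = 1e-8,
            max_iter: int = 50, floor_frac: float = 1e-8, verbose: bool = False):
        """EM warm-up then AI iterations until the largest relative
        parameter change falls below ``tol``.  Returns a
        :class:`RemlFit`."""
        vy = float(np.var(self.sys.y))
        floor = floor_frac * vy
        vc = dict(start) if start else self.default_start()
        history = []

        for _ in range(em_rounds):
            state = self._decompose(vc)
            history.append(self.reml_loglik(vc, state))
            vc = self._floor(self.em_step(vc, state), floor)

        converged, n_ai = False, 0
        se_theta = None
        for it in range(max_iter):
            state = self._decompose(vc)
            ll = self.reml_loglik(vc, state)
            history.append(ll)
            score, AI = self._score_and_ai(vc, state)
            theta = self.theta_from_vc(vc)
            try:
                delta = np.linalg.solve(AI, score)
                ai_ok = True
            except np.linalg.LinAlgError:
                ai_ok = False
            if not ai_ok or not np.all(np.isfinite(delta)):
                vc = self._floor(self.em_step(vc, state), floor)
                n_ai += 1
                continue
            step = 1.0
            for _ in range(30):
                cand = self.vc_from_theta(theta + step * delta)
                if self.in_parameter_space(cand):
                    break
                step *= 0.5
            else:
                cand = self._floor(self.em_step(vc, state), floor)
            new_theta = self.theta_from_vc(cand)
            rel = np.max(np.abs(new_theta - theta) / (np.abs(theta) + floor + 1e-12))
            vc = self._floor(cand, floor)
            n_ai = it + 1
            if verbose:
                print(f"AI iter {n_ai}: loglik={ll:.6f} max-rel-change={rel:.3e}")
            if rel < tol:
                converged = True
                try:
                    se_theta = np.sqrt(np.maximum(np.diag(np.linalg.inv(AI)), 0.0))
                except np.linalg.LinAlgError:
                    se_theta = np.full(len(theta), np.nan)
                break
        if not converged:
            raise RemlError(
                f"AI-REML did not converge in {max_iter} iterations", trace=history)
        return self._package(vc, se_theta, history, n_ai)

    def _floor(self, vc: dict, floor: float) -> dict:
        vc = dict(vc)
        vc["sigma2_e"] = max(vc["sigma2_e"], floor)
        for t in self.sys.terms:
            K0 = np.atleast_2d(np.array(vc[t.name], dtype=float))
            for a in range(K0.shape[0]):
                K0[a, a] = max(K0[a, a], floor)
            # keep covariance inside the PD cone
            if K0.shape[0] == 2:
                lim = 0.999 * np.sqrt(K0[0, 0] * K0[1, 1])
                K0[0, 1] = K0[1, 0] = np.clip(K0[0, 1], -lim, lim)
            vc[t.name] = K0
        return vc

    def _package(self, vc, se_theta, history, n_iter):
        se = {}
        se_e = None
        if se_theta is not None:
            for val, (name, a, b) in zip(se_theta, self.layout):
                if name == "residual":
                    se_e = float(val)
                else:
                    t = self.sys.term(name)
                    S = se.setdefault(name, np.zeros((t.n_effects, t.n_effects)))
                    S[a, b] = S[b, a] = val
        comp = VarianceComponents(
            k0={t.name: np.atleast_2d(vc[t.name]) for t in self.sys.terms},
            sigma2_e=vc["sigma2_e"], se=se, se_sigma2_e=se_e)
        return RemlFit(components=comp, loglik=history[-1], history=history,
                       n_iter=n_iter, converged=True)


@dataclass
class RemlFit:
    components: VarianceComponents
    loglik: float
    history: list
    n_iter: int
    converged: bool


def em_reml_iterate(sys: MMESystem, start: dict = None, n_rounds: int = 10):
    """Run pure EM-REML and return the trace of iterates (list of vc dicts)."""
    eng = RemlEngine(sys)
    vc = dict(start) if start else eng.default_start()
    trace = [vc]
    for _ in range(n_rounds):
        vc = eng.em_step(vc)
        trace.append(vc)
    return trace


def ai_reml(sys: MMESystem, start: dict = None, em_rounds: int = 3,
            tol: float = 1e-8, max_iter: int = 50) -> RemlFit:
    """Convenience wrapper: EM warm-up then AI-REML to convergence."""
    return RemlEngine(sys).fit(start=start, em_rounds=em_rounds, tol=tol,
                               max_iter=max_iter)
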