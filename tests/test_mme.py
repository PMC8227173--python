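"""Mixed-model equations: incidence structure, assembly, solving."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ssgwas.mme import (ModelError, TraitModelSpec, assemble_mme, build_incidence,
                        solve_mme, split_solutions, stack_design)
from ssgwas.pedigree import build_A_inverse, renumber, tabular_A
from ssgwas.reml import logdet_sparse_spd
from conftest import random_pedigree


def tiny_records(ped, rows):
    return pd.DataFrame(rows)


def build_sys(ped, records, maternal=False, factors=("sex",), covariates=()):
    ainv = build_A_inverse(ped)
    return build_incidence(records, TraitModelSpec(trait="y", factors=factors,
                                                   covariates=covariates,
                                                   maternal=maternal),
                           ped, ainv, -logdet_sparse_spd(ainv))


class TestIncidence:
    def test_reference_level_fixed_design(self, trio):
        rec = pd.DataFrame({"individual": ["A", "B"], "y": [1.0, 2.0],
                            "sex": [1, 2], "hys": ["h1", "h1"]})
        sys = build_sys(trio, rec)
        # one factor only: both its levels present (intercept absorbed)
        assert sys.X.shape == (2, 2)
        np.testing.assert_allclose(sys.X, [[1, 0], [0, 1]])

    def test_second_factor_drops_first_level(self, trio):
        rec = pd.DataFrame({"individual": ["A", "B", "C"], "y": [1., 2., 3.],
                            "sex": [1, 2, 1], "grp": [1, 2, 2],
                            "hys": ["h1"] * 3})
        sys = build_sys(trio, rec, factors=("sex", "grp"))
        assert sys.x_labels == ["sex:1", "sex:2", "grp:2"]

    def test_animal_incidence_single_one(self, trio):
        rec = pd.DataFrame({"individual": ["C"], "y": [1.0], "sex": [1],
                            "hys": ["h1"]})
        sys = build_sys(trio, rec)
        V = sys.term("genetic").incidence[0].toarray()
        assert V.shape == (1, 3)
        assert V[0, trio.id_of("C") - 1] == 1.0 and V.sum() == 1.0

    def test_maternal_T_points_at_dams(self):
        ped = renumber([("S", 0, 0), ("D1", 0, 0), ("D2", 0, 0),
                        ("K1", "S", "D1"), ("K2", "S", "D2")])
        rec = pd.DataFrame({"individual": ["K1", "K2"], "y": [1., 2.],
                            "sex": [1, 2], "hys": ["h1", "h2"]})
        sys = build_sys(ped, rec, maternal=True)
        T = sys.term("genetic").incidence[1].toarray()
        assert T[0, ped.id_of("D1") - 1] == 1.0
        assert T[1, ped.id_of("D2") - 1] == 1.0

    def test_maternal_unknown_dam_lists_record(self, trio):
        rec = pd.DataFrame({"individual": ["A", "C"], "y": [1., 2.],
                            "sex": [1, 2], "hys": ["h1", "h1"]})
        with pytest.raises(ModelError, match="A"):
            build_sys(trio, rec, maternal=True)


class TestAssembly:
    def test_single_animal_u_diagonal(self):
        """One founder with one record, s2a = s2e = 1: the u equation's
        diagonal is Z'Z + A^-1 = 2."""
        ped = renumber([("A", 0, 0)])
        rec = pd.DataFrame({"individual": ["A"], "y": [1.0], "sex": [1],
                            "hys": ["h1"]})
        sys = build_sys(ped, rec)
        C, rhs, off = assemble_mme(sys, {"genetic": [[1.0]], "hys": [[1.0]],
                                         "sigma2_e": 1.0})
        lo, _ = off["genetic:additive"]
        assert C.toarray()[lo, lo] == pytest.approx(2.0)

    def test_zero_covariance_decouples_u_and_m(self):
        ped = renumber([("S", 0, 0), ("D", 0, 0), ("K", "S", "D")])
        rec = pd.DataFrame({"individual": ["K"], "y": [1.0], "sex": [1],
                            "hys": ["h1"]})
        sys = build_sys(ped, rec, maternal=True)
        C, _, off = assemble_mme(sys, {"genetic": [[1.0, 0.0], [0.0, 1.0]],
                                       "hys": [[1.0]], "sigma2_e": 1.0})
        u = slice(*off["genetic:additive"])
        m = slice(*off["genetic:maternal"])
        block = C.toarray()[u, m]
        # with s_am = 0 the only u-m coupling comes through the records
        V = sys.term("genetic").incidence[0].toarray()
        T = sys.term("genetic").incidence[1].toarray()
        np.testing.assert_allclose(block, V.T @ T, atol=1e-12)

    def test_non_pd_genetic_covariance_raises(self, trio):
        rec = pd.DataFrame({"individual": ["C"], "y": [1.0], "sex": [1],
                            "hys": ["h1"]})
        sys = build_sys(trio, rec, maternal=True)
        with pytest.raises(ModelError, match="positive definite"):
            assemble_mme(sys, {"genetic": [[1.0, 1.5], [1.5, 1.0]],
                               "hys": [[1.0]], "sigma2_e": 1.0})

    def test_matches_gls_oracle(self, rng):
        """MME solutions equal dense GLS/BLUP on a small random system."""
        ped = random_pedigree(rng, 25)
        rec = pd.DataFrame({
            "individual": [ped.labels[i] for i in rng.integers(1, 26, size=40)],
            "y": rng.normal(10, 3, size=40),
            "sex": rng.integers(1, 3, size=40),
            "hys": [f"h{h}" for h in rng.integers(0, 4, size=40)],
        })
        sys = build_sys(ped, rec)
        vc = {"genetic": [[2.0]], "hys": [[1.5]], "sigma2_e": 3.0}
        C, rhs, off = assemble_mme(sys, vc)
        sol = solve_mme(C, rhs)
        # dense oracle: V = Z A Z' s2a + W W' s2p + I s2e
        A = tabular_A(ped)
        Z = sys.term("genetic").incidence[0].toarray()
        W = sys.term("hys").incidence[0].toarray()
        X, y = sys.X, sys.y
        V = 2.0 * Z @ A @ Z.T + 1.5 * W @ W.T + 3.0 * np.eye(len(y))
        Vi = np.linalg.inv(V)
        b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        u = 2.0 * A @ Z.T @ Vi @ (y - X @ b)
        p = 1.5 * W.T @ Vi @ (y - X @ b)
        np.testing.assert_allclose(sol[:X.shape[1]], b, atol=1e-6)
        np.testing.assert_allclose(sol[slice(*off["genetic:additive"])], u, atol=1e-6)
        np.testing.assert_allclose(sol[slice(*off["hys:hys"])], p, atol=1e-6)

    def test_unrecorded_animal_gets_parent_average(self, rng):
        """An animal with no record and no descendants solves to the mean
        of its parents' breeding values."""
        ped = random_pedigree(rng, 20)
        # append a childless, recordless offspring of 1 x 2
        import numpy as np
        sire = np.append(ped.sire, 1)
        dam = np.append(ped.dam, 2)
        labels = np.append(ped.labels, "tail")
        from ssgwas.pedigree import Pedigree
        ped2 = Pedigree(sire=sire, dam=dam, labels=labels)
        rec = pd.DataFrame({
            "individual": [ped2.labels[i] for i in rng.integers(1, 21, size=30)],
            "y": rng.normal(0, 2, size=30),
            "sex": rng.integers(1, 3, size=30),
            "hys": ["h1"] * 30,
        })
        sys = build_sys(ped2, rec)
        C, rhs, off = assemble_mme(sys, {"genetic": [[1.0]], "hys": [[0.5]],
                                         "sigma2_e": 1.0})
        sol = solve_mme(C, rhs)
        u = sol[slice(*off["genetic:additive"])]
        assert u[-1] == pytest.approx(0.5 * (u[0] + u[1]), abs=1e-8)


class TestSolve:
    def test_identity_system(self):
        C = sp.identity(5, format="csc")
        r = np.arange(5.0)
        np.testing.assert_allclose(solve_mme(C, r), r)

    def test_direct_vs_pcg_agree(self, rng):
        n = 200
        B = rng.random((n, n))
        C = sp.csc_matrix(B @ B.T + n * np.eye(n))
        r = rng.normal(size=n)
        d = solve_mme(C, r, method="direct")
        p = solve_mme(C, r, method="pcg", tol=1e-10)
        np.testing.assert_allclose(d, p, atol=1e-6)

    def test_fixed_only_equals_ols(self, rng):
        """With huge random-effect variance ratios suppressed, b-hat from a
        fixed-effects-only design matches least squares."""
        X = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = X @ [2.0, -1.0] + rng.normal(0, 0.5, size=30)
        C = sp.csc_matrix(X.T @ X)
        sol = solve_mme(C, X.T @ y)
        np.testing.assert_allclose(sol, np.linalg.lstsq(X, y, rcond=None)[0],
                                   atol=1e-8)

    def test_record_order_invariance(self, rng, trio):
        rec = pd.DataFrame({"individual": ["A", "B", "C", "C"],
                            "y": [1., 2., 3., 2.5], "sex": [1, 2, 1, 1],
                            "hys": ["h1", "h2", "h1", "h2"]})
        vc = {"genetic": [[1.0]], "hys": [[1.0]], "sigma2_e": 1.0}
        sols = []
        for order in ([0, 1, 2, 3], [3, 1, 0, 2]):
            sys = build_sys(trio, rec.iloc[order].reset_index(drop=True))
            C, rhs, off = assemble_mme(sys, vc)
            sols.append(solve_mme(C, rhs)[slice(*off["genetic:additive"])])
        np.testing.assert_allclose(sols[0], sols[1], atol=1e-10)
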