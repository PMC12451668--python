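"""Charge-conserving density fitting: metric, fits, factored integrals."""

import numpy as np
import pytest
import scipy.optimize as sopt

from sqmkit import coulomb_factor as cf
from sqmkit import gauss_oracle as go
from sqmkit import sk_core as sk


def s_aux_pair(d, U=0.9, Vee=0.5):
    aux = [
        cf.AuxFunction((0, 0, 0), "H", 0, 0, 1.0),
        cf.AuxFunction((0, 0, d), "H", 0, 0, 1.0),
    ]
    tab = sk.SlaterKosterTable(kernel_kind="ee_coulomb")
    tab.add(
        sk.RadialChannel(
            ("H", "H"), (0, 0), 0, cutoff=1e9, tail="monopole", func=lambda r: Vee
        )
    )
    return cf.build_metric(aux, tab, {"H": U})


class TestMetric:
    def test_two_aux_closed_form(self):
        U, Vee = 0.9, 0.5
        m = s_aux_pair(1.4, U, Vee)
        assert np.allclose(m.V, [[U, Vee], [Vee, U]])
        lam = m.pair_lambda[(0, 1)]
        det = U * U - Vee * Vee
        assert np.allclose(lam, np.array([[U, -Vee], [-Vee, U]]) / det, atol=1e-14)

    def test_degenerate_block_raises(self):
        with pytest.raises(ValueError, match="singular"):
            s_aux_pair(1.4, U=0.7, Vee=0.7)

    def test_three_atom_blocks_invert(self):
        d = 1.2
        aux = [cf.AuxFunction((0, 0, i * d), "H", 0, 0, 1.0) for i in range(3)]
        tab = sk.SlaterKosterTable(kernel_kind="ee_coulomb")
        tab.add(
            sk.RadialChannel(
                ("H", "H"), (0, 0), 0, cutoff=1e9, tail="monopole",
                func=lambda r: 1.0 / (1.0 + r),
            )
        )
        m = cf.build_metric(aux, tab, {"H": 0.8})
        for (ia, ja), lam in m.pair_lambda.items():
            idx = m.pair_indices(ia, ja)
            block = m.V[np.ix_(idx, idx)]
            assert np.abs(lam @ block - np.eye(len(idx))).max() < 1e-10

    def test_empty_basis_rejected(self):
        with pytest.raises(ValueError):
            cf.build_metric([], None, {})


class TestOneCenterFit:
    def test_single_aux_fully_constrained(self):
        X = cf.one_center_X(np.array([[1.0]]), np.array([1.0]), np.array([[0.7]]))
        assert X[0, 0, 0] == pytest.approx(1.0)

    def test_zero_charge_function_carries_nothing_by_default(self):
        V = np.array([[0.9, 0.1], [0.1, 0.8]])
        X = cf.one_center_X(np.array([[1.0]]), np.array([1.0, 0.0]), V)
        s = X[0, 0, 0] * 1.0 + X[1, 0, 0] * 0.0
        assert s == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_charges_infeasible(self):
        with pytest.raises(ValueError, match="infeasible"):
            cf.one_center_X(np.array([[1.0]]), np.array([0.0, 0.0]), np.eye(2))

    def test_kkt_against_brute_force_qp(self, rng):
        # p.p product fit onto a larger aux set: KKT solve must match a
        # generic constrained quadratic program
        n = 5
        A = rng.normal(size=(n, n))
        V = A @ A.T + n * np.eye(n)
        Q = rng.normal(size=n)
        b = rng.normal(size=n)
        s = 0.37
        x = cf._kkt_solve(V, Q, s, b)
        res = sopt.minimize(
            lambda y: 0.5 * y @ V @ y - b @ y,
            Q * s / (Q @ Q),
            constraints=[{"type": "eq", "fun": lambda y: Q @ y - s}],
            method="SLSQP",
            options={"ftol": 1e-14, "maxiter": 500},
        )
        assert np.abs(x - res.x).max() < 1e-6
        # and the constraint is exact, not approximate
        assert Q @ x - s == pytest.approx(0.0, abs=1e-12)

    def test_constrained_residual_bounded_by_unconstrained(self, rng):
        n = 4
        A = rng.normal(size=(n, n))
        V = A @ A.T + n * np.eye(n)
        Q = rng.normal(size=n)
        b = rng.normal(size=n)
        s = 0.2
        x = cf._kkt_solve(V, Q, s, b)
        x_free = np.linalg.solve(V, b)
        obj = lambda y: 0.5 * y @ V @ y - b @ y
        assert obj(x) >= obj(x_free) - 1e-12


class TestProjectionZ:
    def test_single_sample_single_function_ratio(self):
        T = np.array([[[0.6]]])
        S = np.array([[0.3]])
        Z = cf.projection_Z(1, 1, [(T, S)])
        assert Z[0, 0, 0] == pytest.approx(0.6 / 0.3)

    def test_least_squares_over_samples_matches_oracle(self):
        # s-only atom: fitted scalar reproduces the oracle ratio in LS sense
        p = go.SGaussian.normalized((0, 0, 0), 0.8)
        gamma = 1.6
        rho = go.SGaussian((0, 0, 0), gamma, (gamma / np.pi) ** 1.5)
        samples = []
        rows_T, rows_S = [], []
        for d in np.linspace(1.0, 3.0, 5):
            q = go.SGaussian.normalized((0, 0, d), 0.8)
            t = go.three_center_potential_ss(rho, p, q)
            s = go.pair_integrals_ss(p, q)[0]
            samples.append((np.array([[[t]]]), np.array([[s]])))
            rows_T.append(t)
            rows_S.append(s)
        Z = cf.projection_Z(1, 1, samples)
        expected = np.dot(rows_T, rows_S) / np.dot(rows_S, rows_S)
        assert Z[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        # fit residual is small relative to the values themselves
        resid = np.abs(np.array(rows_T) - Z[0, 0, 0] * np.array(rows_S)).max()
        assert resid < 0.05 * max(abs(t) for t in rows_T)

    def test_rank_deficiency_warns(self):
        T = np.zeros((1, 2, 1))
        S = np.array([[0.5], [0.0]])  # second primary never overlaps
        with pytest.warns(UserWarning, match="rank"):
            cf.projection_Z(1, 2, [(T, S)])


class TestTwoCenterFit:
    def test_mulliken_halves_for_symmetric_dimer(self):
        m = s_aux_pair(1.4, U=0.9, Vee=0.5)
        lam = m.pair_lambda[(0, 1)]
        Spq = 0.37
        X, W, w = cf.two_center_X(np.array([[Spq]]), m.Q, lam)
        assert np.allclose(X[:, 0, 0], Spq / 2)
        assert np.allclose(W, 0.0)

    def test_sum_rule_exact_with_random_Z(self, rng):
        nA, nB = 2, 2
        naux = 4
        A = rng.normal(size=(naux, naux))
        V = A @ A.T + naux * np.eye(naux)
        lam = np.linalg.inv(V)
        Q = rng.uniform(0.5, 1.5, size=naux)
        S = rng.normal(size=(nA, nB))
        ZA = rng.normal(size=(2, nA, nA))
        ZB = rng.normal(size=(2, nB, nB))
        X, _, _ = cf.two_center_X(S, Q, lam, Z_A=ZA, Z_B=ZB)
        err = np.abs(np.einsum("mpq,m->pq", X, Q) - S).max()
        assert err < 1e-12

    def test_zero_overlap_gives_zero_tensor(self):
        m = s_aux_pair(1.0)
        X, _, _ = cf.two_center_X(np.array([[0.0]]), m.Q, m.pair_lambda[(0, 1)])
        assert np.abs(X).max() == 0.0

    def test_annihilated_charges_raise(self):
        lam = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="annihilated"):
            cf.two_center_X(np.array([[0.5]]), np.array([1.0, -1.0]), lam)


class TestFactoredIntegrals:
    def test_identity_fit_recovers_model_integrals(self):
        U, Vee, Sd = 0.9, 0.5, 0.4
        m = s_aux_pair(1.4, U, Vee)
        S = np.array([[1.0, Sd], [Sd, 1.0]])
        fit = cf.build_fit_tensor(S, [0, 1], m)
        eri = cf.factored_eri(fit, m)
        assert eri[0, 0, 0, 0] == pytest.approx(U)
        assert eri[0, 0, 1, 1] == pytest.approx(Vee)

    def test_bridge_integral_contraction(self):
        U, Vee, Sd = 0.9, 0.5, 0.4
        m = s_aux_pair(1.4, U, Vee)
        S = np.array([[1.0, Sd], [Sd, 1.0]])
        fit = cf.build_fit_tensor(S, [0, 1], m)
        eri = cf.factored_eri(fit, m)
        # (ij|kk) = S_ij (V_ik + V_jk) / 2 with Mulliken splitting
        assert eri[0, 1, 0, 0] == pytest.approx(Sd * (U + Vee) / 2, rel=1e-12)

    def test_eightfold_symmetry_random_system(self, rng):
        d = 1.2
        aux = [cf.AuxFunction((0, 0, i * d), "H", 0, 0, 1.0) for i in range(3)]
        tab = sk.SlaterKosterTable(kernel_kind="ee_coulomb")
        tab.add(
            sk.RadialChannel(
                ("H", "H"), (0, 0), 0, cutoff=1e9, tail="monopole",
                func=lambda r: 0.6 / (1 + 0.5 * r),
            )
        )
        m = cf.build_metric(aux, tab, {"H": 0.8})
        S = np.eye(3)
        for (i, j), v in zip([(0, 1), (1, 2), (0, 2)], rng.uniform(0.1, 0.4, 3)):
            S[i, j] = S[j, i] = v
        fit = cf.build_fit_tensor(S, np.arange(3), m)
        e = cf.factored_eri(fit, m)
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1), (3, 2, 1, 0)]:
            assert np.abs(e - e.transpose(perm)).max() < 1e-12
        assert cf.charge_conservation_error(fit, m.Q, S) < 1e-12


class TestNDDOLimit:
    def test_orthogonal_dimer_cross_integrals_vanish_exactly(self):
        m = s_aux_pair(1.4)
        S = np.array([[1.0, 0.4], [0.4, 1.0]])
        rep = cf.nddo_limit_check(S, [0, 1], m)
        assert rep["passed"]
        assert rep["max_two_center_X"] == 0.0
        assert rep["max_cross_differential_integral"] == 0.0

    def test_one_center_integrals_unchanged_by_orthogonality(self):
        U, Vee = 0.9, 0.5
        m = s_aux_pair(1.4, U, Vee)
        for Sd in (0.0, 0.4):
            S = np.array([[1.0, Sd], [Sd, 1.0]])
            fit = cf.build_fit_tensor(S, [0, 1], m)
            eri = cf.factored_eri(fit, m)
            assert eri[0, 0, 0, 0] == pytest.approx(U)
            assert eri[0, 0, 1, 1] == pytest.approx(Vee)

    def test_nddo_error_on_gaussian_dimer_decreases_with_distance(self):
        # the oracle bridge integral (ij|kk) is nonzero while NDDO gives 0;
        # the neglected quantity shrinks as the overlap decays
        errs = []
        for d in (1.4, 2.4, 3.4):
            a = go.SGaussian.normalized((0, 0, 0), 0.8)
            b = go.SGaussian.normalized((0, 0, d), 0.8)
            errs.append(abs(go.eri_ssss(a, b, a, a)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.05


class TestSystematicImprovability:
    def primaries(self, d):
        A, B = (0, 0, 0.0), (0, 0, float(d))
        prims, atom_of = [], []
        for ia, c in enumerate((A, B)):
            for e in (0.8, 0.3):
                prims.append(go.SGaussian.normalized(c, e))
                atom_of.append(ia)
        return prims, np.array(atom_of), (A, B)

    def factored_error(self, d, aux_exps):
        prims, atom_of, (A, B) = self.primaries(d)
        n = len(prims)
        eri = np.array(
            [[[[go.eri_ssss(prims[i], prims[j], prims[k], prims[l])
                for l in range(n)] for k in range(n)] for j in range(n)]
             for i in range(n)]
        )
        S = np.array([[go.pair_integrals_ss(a, b)[0] for b in prims] for a in prims])
        aux = [(c, g) for c in (A, B) for g in aux_exps]
        V = np.array(
            [[go.coulomb_two_densities((gi / np.pi) ** 1.5, gi, ci,
                                       (gj / np.pi) ** 1.5, gj, cj)
              for cj, gj in aux] for ci, gi in aux]
        )
        atom_aux = np.array([0] * len(aux_exps) + [1] * len(aux_exps))
        auxf = [cf.AuxFunction(tuple(c), "H", 0, 0, 1.0) for c, _ in aux]
        metric = cf.CoulombMetric(V=V, aux=auxf, atom_of=atom_aux)
        metric.pair_lambda[(0, 1)] = np.linalg.inv(V)
        B_one = {}
        for ia in (0, 1):
            pidx = np.where(atom_of == ia)[0]
            axi = np.where(atom_aux == ia)[0]
            bmat = np.zeros((len(axi), len(pidx), len(pidx)))
            for k, mu in enumerate(axi):
                c, g = aux[mu]
                rho = go.SGaussian(tuple(c), g, (g / np.pi) ** 1.5)
                for x, p in enumerate(pidx):
                    for y, q in enumerate(pidx):
                        bmat[k, x, y] = go.three_center_potential_ss(
                            rho, prims[p], prims[q]
                        )
            B_one[ia] = bmat
        # projection tensor fitted on atom 0 and reused by symmetry
        axi = np.where(atom_aux == 0)[0]
        pidx = np.where(atom_of == 0)[0]
        samples = []
        for ds in np.linspace(0.8, 4.0, 9):
            qorbs = [go.SGaussian.normalized((0, 0, ds), e) for e in (0.8, 0.3)]
            T = np.zeros((len(axi), len(pidx), len(qorbs)))
            for k, mu in enumerate(axi):
                c, g = aux[mu]
                rho = go.SGaussian(tuple(c), g, (g / np.pi) ** 1.5)
                for x, p in enumerate(pidx):
                    for y, q in enumerate(qorbs):
                        T[k, x, y] = go.three_center_potential_ss(rho, prims[p], q)
            Ss = np.array(
                [[go.pair_integrals_ss(prims[p], q)[0] for q in qorbs] for p in pidx]
            )
            samples.append((T, Ss))
        Z0 = cf.projection_Z(len(axi), len(pidx), samples)
        fit = cf.build_fit_tensor(S, atom_of, metric, Z={0: Z0, 1: Z0}, B_one=B_one)
        assert cf.charge_conservation_error(fit, np.ones(len(aux)), S) < 1e-11
        return np.abs(cf.factored_eri(fit, metric) - eri).max()

    @pytest.mark.parametrize("d", [1.4, 2.0, 3.0])
    def test_error_decreases_with_nested_aux_sets(self, d):
        # aux sets grow toward spanning the one-center product space
        sets = ([1.6], [1.6, 0.6], [1.6, 0.6, 1.1])
        errs = [self.factored_error(d, ae) for ae in sets]
        assert errs[0] > errs[1] > errs[2]

    def test_one_center_metric_residual_monotone(self, rng):
        # nesting argument: enlarging the aux set cannot worsen the
        # constrained metric residual of a one-center product fit
        p = go.SGaussian.normalized((0, 0, 0), 0.8)
        target_norm = go.eri_ssss(p, p, p, p)

        def residual(aux_exps):
            naux = len(aux_exps)
            V = np.array(
                [[go.coulomb_two_densities((gi / np.pi) ** 1.5, gi, (0, 0, 0),
                                           (gj / np.pi) ** 1.5, gj, (0, 0, 0))
                  for gj in aux_exps] for gi in aux_exps]
            )
            b = np.array(
                [go.three_center_potential_ss(
                    go.SGaussian((0, 0, 0), g, (g / np.pi) ** 1.5), p, p)
                 for g in aux_exps]
            )
            x = cf._kkt_solve(V, np.ones(naux), 1.0, b)
            return target_norm - 2 * b @ x + x @ V @ x

        res = [residual(ae) for ae in ([1.0], [1.0, 2.5], [1.0, 2.5, 0.5])]
        assert res[0] >= res[1] - 1e-12 >= res[2] - 1e-12
        assert all(r > -1e-10 for r in res)
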