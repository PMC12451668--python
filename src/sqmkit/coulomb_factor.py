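"""Charge-conserving, atom-local density fitting of Coulomb integrals.

Four-center Coulomb integrals are approximated in the factored form

    V_{pq,rs} ~= sum_{mu,nu} X^mu_{p,q} V_{mu,nu} X^nu_{r,s}

with an auxiliary basis of atom-centered charge distributions rho_mu
carrying total charges Q_mu, the auxiliary Coulomb metric V_{mu,nu}, and
fit tensors X restricted to the atoms of p and q.  The single hard
constraint is exact conservation of electronic charge,

    sum_mu X^mu_{p,q} Q_mu = S_{p,q},

imposed exactly (KKT equality constraints for one-center fits, the
closed-form two-center expression below for pairs).  For p, q on
different atoms the two-center tensor is

    X^mu_{p,q} = sum_nu Lambda_{mu,nu} (Q_nu w_{p,q} + W^nu_{p,q})
    W^mu_{p,q} = sum_r (Z^mu_{p,r} S_{r,q} + Z^mu_{q,r} S_{r,p})
    w_{p,q}    = (S_{p,q} - sum_{mu,nu} Q_mu Lambda_{mu,nu} W^nu_{p,q})
                 / (sum_{mu,nu} Q_mu Lambda_{mu,nu} Q_nu)

where Lambda is the inverse of the two-atom metric block and Z is a
one-center projection tensor fitted against oracle three-center
integrals.  With orthogonal orbitals (two-center S = 0) and Z = 0 every
cross-atom fit coefficient vanishes and the model reduces to the NDDO
approximation; with nonzero S it degrades gracefully to symmetric
(Mulliken-like) charge splitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import sk_core

__all__ = [
    "AuxFunction",
    "CoulombMetric",
    "FitTensorX",
    "build_metric",
    "one_center_X",
    "projection_Z",
    "two_center_X",
    "build_fit_tensor",
    "factored_eri",
    "charge_conservation_error",
    "nddo_limit_check",
]


@dataclass(frozen=True)
class AuxFunction:
    """Auxiliary charge distribution rho_mu with total charge Q."""

    center: tuple[float, float, float]
    tau: str
    l: int
    m: int
    Q: float

    def label(self) -> sk_core.OrbitalLabel:
        return sk_core.OrbitalLabel(self.center, self.tau, self.l, self.m)


def _group_atoms(aux: list[AuxFunction], tol: float = 1e-9):
    centers: list[np.ndarray] = []
    atom_of = []
    for f in aux:
        c = np.asarray(f.center, float)
        for ia, ref in enumerate(centers):
            if np.linalg.norm(c - ref) < tol:
                atom_of.append(ia)
                break
        else:
            centers.append(c)
            atom_of.append(len(centers) - 1)
    return centers, np.asarray(atom_of)


@dataclass
class CoulombMetric:
    """Auxiliary metric V_{mu,nu} with per-pair inverse blocks Lambda."""

    V: np.ndarray
    aux: list[AuxFunction]
    atom_of: np.ndarray
    pair_lambda: dict = field(default_factory=dict)

    @property
    def Q(self) -> np.ndarray:
        return np.asarray([f.Q for f in self.aux])

    def pair_indices(self, ia: int, ja: int) -> np.ndarray:
        return np.where((self.atom_of == ia) | (self.atom_of == ja))[0]


def build_metric(
    aux: list[AuxFunction],
    coulomb_table: sk_core.SlaterKosterTable | None,
    self_energies,
    cond_limit: float = 1e12,
) -> CoulombMetric:
    """Assemble V_{mu,nu} and the per-pair inverse blocks Lambda.

    One-center diagonal entries come from ``self_energies`` (a mapping from
    aux type tag to the self-Coulomb energy, or a callable on the
    AuxFunction); same-atom off-diagonal entries are zero.  Two-center
    entries are Slater-Koster assembled from ``coulomb_table``.  A singular
    two-atom block raises with the offending pair and condition number.
    """
    if not aux:
        raise ValueError("auxiliary basis is empty")
    n = len(aux)
    centers, atom_of = _group_atoms(aux)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if atom_of[i] == atom_of[j]:
                if i == j:
                    V[i, i] = (
                        self_energies(aux[i])
                        if callable(self_energies)
                        else self_energies[aux[i].tau]
                    )
            else:
                V[i, j] = sk_core.sk_element(
                    aux[i].label(), aux[j].label(), coulomb_table
                )
    metric = CoulombMetric(V=V, aux=list(aux), atom_of=atom_of)
    n_atoms = len(centers)
    for ia in range(n_atoms):
        for ja in range(ia + 1, n_atoms):
            idx = metric.pair_indices(ia, ja)
            block = V[np.ix_(idx, idx)]
            w = np.linalg.eigvalsh(block)
            if w.min() <= 0 or w.max() / w.min() > cond_limit:
                raise ValueError(
                    f"singular auxiliary metric block for atom pair "
                    f"({ia}, {ja}): eigenvalues [{w.min():.3e}, {w.max():.3e}]"
                )
            metric.pair_lambda[(ia, ja)] = np.linalg.inv(block)
    return metric


# ---------------------------------------------------------------------------
# one-center fits


def _kkt_solve(V, Q, s, b):
    """min (1/2) x^T V x - b^T x  subject to  Q^T x = s."""
    n = len(Q)
    KKT = np.zeros((n + 1, n + 1))
    KKT[:n, :n] = V
    KKT[:n, n] = Q
    KKT[n, :n] = Q
    rhs = np.concatenate([b, [s]])
    try:
        sol = np.linalg.solve(KKT, rhs)
    except np.linalg.LinAlgError:
        warnings.warn(
            "rank-deficient KKT system in one-center fit; using the "
            "smallest-norm (pseudoinverse) solution",
            stacklevel=2,
        )
        sol = np.linalg.lstsq(KKT, rhs, rcond=None)[0]
    x = sol[:n]
    if abs(Q @ x - s) > 1e-9 * max(1.0, abs(s)):
        raise ValueError("charge constraint could not be satisfied exactly")
    return x


def one_center_X(
    S_one: np.ndarray,
    Q: np.ndarray,
    V_block: np.ndarray,
    B: np.ndarray | None = None,
) -> np.ndarray:
    """One-center fit tensor X^mu_{p,q} for a single atom.

    For each orbital product (p, q) on the atom the expansion coefficients
    minimize the Coulomb-metric residual (1/2) x V x - b x subject to the
    exact charge constraint sum_mu x_mu Q_mu = S_{p,q}.  ``B`` holds the
    oracle three-center projections b_mu = (rho_mu | phi_p phi_q); omitted,
    the fit returns the minimum-metric-norm charge-conserving solution.
    Returns an array of shape (n_aux, n, n).
    """
    S_one = np.atleast_2d(np.asarray(S_one, float))
    Q = np.asarray(Q, float)
    if np.all(Q == 0):
        raise ValueError(
            "charge constraint infeasible: all auxiliary charges vanish"
        )
    n = S_one.shape[0]
    naux = len(Q)
    X = np.empty((naux, n, n))
    for p in range(n):
        for q in range(n):
            b = np.zeros(naux) if B is None else np.asarray(B[:, p, q], float)
            X[:, p, q] = _kkt_solve(V_block, Q, float(S_one[p, q]), b)
    return X


def projection_Z(n_aux: int, n_primary: int, samples, ridge: float = 0.0):
    """Fit the one-center projection tensor Z^mu_{p,r} by least squares.

    Each sample is a pair ``(T, S)`` from one partner placement: ``T`` of
    shape (n_aux, n_primary, n_partner) holds the oracle integrals
    int V_mu phi_p phi_q, and ``S`` of shape (n_primary, n_partner) the
    overlaps of this atom's primaries r with the partner orbitals q.  The
    model T[mu, p, q] ~= sum_r Z[mu, p, r] S[r, q] is solved in least
    squares over all samples; rank-deficient normal equations fall back to
    the smallest-norm solution (reported).
    """
    A = np.vstack([S.T for _, S in samples])  # (sum nq, n_primary)
    gram = A.T @ A
    rank = np.linalg.matrix_rank(gram, tol=1e-12 * max(1.0, np.trace(gram)))
    if rank < n_primary:
        warnings.warn(
            f"projection fit normal equations rank {rank} < {n_primary}; "
            "regularized smallest-norm solution used",
            stacklevel=2,
        )
    Z = np.empty((n_aux, n_primary, n_primary))
    for mu in range(n_aux):
        for p in range(n_primary):
            rhs = np.concatenate([T[mu, p, :] for T, _ in samples])
            if ridge > 0:
                sol = np.linalg.solve(
                    gram + ridge * np.eye(n_primary), A.T @ rhs
                )
            else:
                sol = np.linalg.lstsq(A, rhs, rcond=None)[0]
            Z[mu, p, :] = sol
    return Z


# ---------------------------------------------------------------------------
# two-center fits


def two_center_X(
    S_cross: np.ndarray,
    Q_pair: np.ndarray,
    Lambda: np.ndarray,
    Z_A: np.ndarray | None = None,
    Z_B: np.ndarray | None = None,
):
    """Charge-conserving two-center fit tensor for one atom pair.

    ``S_cross`` is the (nA, nB) overlap block between the primaries of the
    two atoms; ``Q_pair`` and ``Lambda`` belong to the pair's auxiliary
    block (A functions first).  Returns (X, W, w) with X of shape
    (nauxA + nauxB, nA, nB).
    """
    S_cross = np.atleast_2d(np.asarray(S_cross, float))
    Q = np.asarray(Q_pair, float)
    nA, nB = S_cross.shape
    naux = len(Q)
    W = np.zeros((naux, nA, nB))
    if Z_A is not None and Z_A.size:
        W[: Z_A.shape[0]] = np.einsum("mpr,rq->mpq", Z_A, S_cross)
    if Z_B is not None and Z_B.size:
        W[naux - Z_B.shape[0] :] = np.einsum("mqr,pr->mpq", Z_B, S_cross)
    LQ = Lambda @ Q
    denom = float(Q @ LQ)
    if abs(denom) < 1e-14:
        raise ValueError(
            "auxiliary charges are annihilated by the pair metric "
            "(denominator of the charge-conservation closure vanishes)"
        )
    QLW = np.einsum("m,mpq->pq", LQ, W)
    w = (S_cross - QLW) / denom
    # X^mu = sum_nu Lambda_{mu,nu} (Q_nu w + W^nu)
    X = np.einsum("mn,n,pq->mpq", Lambda, Q, w) + np.einsum(
        "mn,npq->mpq", Lambda, W
    )
    return X, W, w


@dataclass
class FitTensorX:
    """Assembled fit tensor over a whole cluster.

    ``X`` has shape (n_aux, n_orb, n_orb); entries are nonzero only for mu
    on the atoms of p and q.  The two-center intermediates W and w are kept
    per atom pair for inspection.
    """

    X: np.ndarray
    W: dict = field(default_factory=dict)
    w: dict = field(default_factory=dict)


def build_fit_tensor(
    S: np.ndarray,
    atom_of_orb: np.ndarray,
    metric: CoulombMetric,
    Z: dict | None = None,
    B_one: dict | None = None,
) -> FitTensorX:
    """Assemble the full X tensor from one- and two-center fits.

    ``S`` is the primary overlap matrix, ``atom_of_orb`` maps each orbital
    to its atom.  ``Z`` optionally maps atom index to its projection
    tensor (Z = 0, i.e. Mulliken-like splitting, when absent); ``B_one``
    optionally maps atom index to one-center oracle projections.
    """
    S = np.asarray(S, float)
    atom_of_orb = np.asarray(atom_of_orb)
    naux = len(metric.aux)
    n = S.shape[0]
    X = np.zeros((naux, n, n))
    out = FitTensorX(X=X)
    atoms = np.unique(np.concatenate([atom_of_orb, metric.atom_of]))
    for ia in atoms:
        orb = np.where(atom_of_orb == ia)[0]
        axi = np.where(metric.atom_of == ia)[0]
        if len(orb) == 0 or len(axi) == 0:
            raise ValueError(f"atom {ia} lacks primary or auxiliary functions")
        Vb = metric.V[np.ix_(axi, axi)]
        Qb = metric.Q[axi]
        B = None if B_one is None else B_one.get(int(ia))
        Xone = one_center_X(S[np.ix_(orb, orb)], Qb, Vb, B=B)
        X[np.ix_(axi, orb, orb)] = Xone
    for ia in atoms:
        for ja in atoms:
            if ja <= ia:
                continue
            orbA = np.where(atom_of_orb == ia)[0]
            orbB = np.where(atom_of_orb == ja)[0]
            axA = np.where(metric.atom_of == ia)[0]
            axB = np.where(metric.atom_of == ja)[0]
            idx = metric.pair_indices(int(ia), int(ja))
            Lam = metric.pair_lambda[(int(ia), int(ja))]
            Scross = S[np.ix_(orbA, orbB)]
            ZA = None if Z is None else Z.get(int(ia))
            ZB = None if Z is None else Z.get(int(ja))
            if ZA is None:
                ZA = np.zeros((len(axA), len(orbA), len(orbA)))
            if ZB is None:
                ZB = np.zeros((len(axB), len(orbB), len(orbB)))
            Xp, W, w = two_center_X(
                Scross, metric.Q[idx], Lam, Z_A=ZA, Z_B=ZB
            )
            out.W[(int(ia), int(ja))] = W
            out.w[(int(ia), int(ja))] = w
            # scatter: pair aux order is A block then B block
            X[np.ix_(idx, orbA, orbB)] = Xp
            X[np.ix_(idx, orbB, orbA)] = Xp.transpose(0, 2, 1)
    return out


def factored_eri(fit: FitTensorX | np.ndarray, metric: CoulombMetric) -> np.ndarray:
    """Factored four-index tensor V_{pq,rs} = X V X (chemists' notation)."""
    X = fit.X if isinstance(fit, FitTensorX) else np.asarray(fit, float)
    return np.einsum("mpq,mn,nrs->pqrs", X, metric.V, X, optimize=True)


def charge_conservation_error(
    fit: FitTensorX | np.ndarray, Q: np.ndarray, S: np.ndarray
) -> float:
    """Max |sum_mu X^mu_{p,q} Q_mu - S_{p,q}| over all orbital pairs."""
    X = fit.X if isinstance(fit, FitTensorX) else np.asarray(fit, float)
    return float(np.abs(np.einsum("mpq,m->pq", X, np.asarray(Q, float)) - S).max())


def nddo_limit_check(
    S: np.ndarray,
    atom_of_orb: np.ndarray,
    metric: CoulombMetric,
    tol: float = 0.0,
) -> dict:
    """Verify the NDDO reduction: orthogonal orbitals + Z = 0.

    The cross-atom overlap blocks of ``S`` are zeroed, the fit tensor is
    rebuilt, and every two-center fit coefficient and every integral with
    differential overlap across atoms must vanish identically.
    """
    S = np.asarray(S, float).copy()
    atom_of_orb = np.asarray(atom_of_orb)
    cross = atom_of_orb[:, None] != atom_of_orb[None, :]
    S[cross] = 0.0
    fit = build_fit_tensor(S, atom_of_orb, metric, Z=None)
    eri = factored_eri(fit, metric)
    max_x = 0.0
    for mu in range(len(metric.aux)):
        max_x = max(max_x, float(np.abs(fit.X[mu][cross]).max()))
    max_int = float(np.abs(eri[cross]).max())
    return {
        "max_two_center_X": max_x,
        "max_cross_differential_integral": max_int,
        "passed": max_x <= tol and max_int <= tol,
    }
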