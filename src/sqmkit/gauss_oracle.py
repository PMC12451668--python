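"""Brute-force Gaussian integral engine and internal FCI reference data.

This module provides closed-form integrals over primitive Gaussians used in
two roles: as the independent oracle that validates the Slater-Koster
rotation assembly and the factored Coulomb model against direct integration,
and as the generator of sector-resolved FCI reference spectra for hydrogen
clusters in a large even-tempered s basis.  The reference basis is a
reduced-scale, fully internal substitute for a quadruple-zeta atomic basis:
10 even-tempered s primitives per atom reach the isolated-atom energy to a
few 1e-4 hartree, which is sufficient to exercise the fitting protocol.

s-type integrals (overlap, kinetic, nuclear attraction, two-electron) use
the textbook closed forms through the Boys function.  Cartesian p support
is included for the rotation-equivalence tests via Obara-Saika/Hermite
recursions; higher angular momenta raise ``NotImplementedError``.

All quantities are in atomic units (hartree, bohr).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf, gammainc, gammaln

from . import mb_solver

__all__ = [
    "SGaussian",
    "ContractedS",
    "OracleBasis",
    "boys0",
    "boys",
    "pair_integrals_ss",
    "eri_ssss",
    "coulomb_two_densities",
    "three_center_potential_ss",
    "direct_two_center",
    "even_tempered_basis",
    "reference_spectrum",
]


# ---------------------------------------------------------------------------
# Boys function


def boys0(x):
    """F_0(x) = (1/2) sqrt(pi/x) erf(sqrt(x)), with the series branch at 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("Boys function argument must be nonnegative")
    out = np.empty_like(x)
    small = x < 1e-13
    out[small] = 1.0 - x[small] / 3.0
    xs = x[~small]
    out[~small] = 0.5 * np.sqrt(np.pi / xs) * erf(np.sqrt(xs))
    if out.ndim == 0:
        return float(out)
    return out


def boys(n: int, x):
    """F_n(x) via the regularized lower incomplete gamma function."""
    if n == 0:
        return boys0(x)
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = x < 1e-13
    out[small] = 1.0 / (2 * n + 1) - x[small] / (2 * n + 3)
    xs = x[~small]
    out[~small] = (
        gammainc(n + 0.5, xs)
        * np.exp(gammaln(n + 0.5))
        / (2.0 * xs ** (n + 0.5))
    )
    if out.ndim == 0:
        return float(out)
    return out


# ---------------------------------------------------------------------------
# primitives


def s_norm(alpha: float) -> float:
    """Normalization of exp(-alpha r^2) to unit self-overlap."""
    return (2.0 * alpha / np.pi) ** 0.75


def cart_norm(alpha: float, i: int, j: int, k: int) -> float:
    """Normalization of x^i y^j z^k exp(-alpha r^2)."""

    def dfact(m):
        return 1 if m < 2 else m * dfact(m - 2)

    L = i + j + k
    return (
        (2.0 * alpha / np.pi) ** 0.75
        * np.sqrt((4.0 * alpha) ** L / (dfact(2 * i - 1) * dfact(2 * j - 1) * dfact(2 * k - 1)))
    )


@dataclass(frozen=True)
class SGaussian:
    """A single s primitive: coefficient * exp(-exponent * |r - center|^2).

    The coefficient includes normalization; ``SGaussian.normalized`` builds a
    unit-self-overlap primitive.
    """

    center: tuple[float, float, float]
    exponent: float
    coefficient: float = 1.0

    def __post_init__(self):
        if self.exponent <= 0:
            raise ValueError("Gaussian exponent must be positive")

    @staticmethod
    def normalized(center, exponent) -> "SGaussian":
        return SGaussian(tuple(map(float, center)), float(exponent), s_norm(exponent))

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.center, float)


@dataclass(frozen=True)
class ContractedS:
    """Contracted s function: sum of normalized primitives times weights."""

    center: tuple[float, float, float]
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]

    def primitives(self) -> list[SGaussian]:
        return [
            SGaussian(self.center, a, c * s_norm(a))
            for a, c in zip(self.exponents, self.coefficients)
        ]


# ---------------------------------------------------------------------------
# s-type closed forms


def _overlap_prims(a: SGaussian, b: SGaussian) -> float:
    p = a.exponent + b.exponent
    mu = a.exponent * b.exponent / p
    R2 = float(np.sum((a.r - b.r) ** 2))
    return a.coefficient * b.coefficient * (np.pi / p) ** 1.5 * np.exp(-mu * R2)


def _kinetic_prims(a: SGaussian, b: SGaussian) -> float:
    p = a.exponent + b.exponent
    mu = a.exponent * b.exponent / p
    R2 = float(np.sum((a.r - b.r) ** 2))
    S = _overlap_prims(a, b)
    return mu * (3.0 - 2.0 * mu * R2) * S


def _nuclear_prims(a: SGaussian, b: SGaussian, nuclei) -> float:
    """Attraction integral <a| sum_A Z_A / |r - R_A| |b> (positive for Z>0)."""
    p = a.exponent + b.exponent
    mu = a.exponent * b.exponent / p
    R2 = float(np.sum((a.r - b.r) ** 2))
    P = (a.exponent * a.r + b.exponent * b.r) / p
    pref = a.coefficient * b.coefficient * 2.0 * np.pi / p * np.exp(-mu * R2)
    val = 0.0
    for Z, C in nuclei:
        val += Z * pref * boys0(p * float(np.sum((P - np.asarray(C, float)) ** 2)))
    return val


def pair_integrals_ss(a: SGaussian, b: SGaussian, nuclei=()) -> tuple[float, float, float]:
    """(overlap, kinetic, nuclear-attraction) for two s primitives.

    ``nuclei`` is a list of (charge, center); the attraction integral is
    returned with a positive sign for positive charges.
    """
    return (
        _overlap_prims(a, b),
        _kinetic_prims(a, b),
        _nuclear_prims(a, b, nuclei),
    )


def coulomb_two_densities(c1, a1, A, c2, a2, B) -> float:
    """Coulomb energy of two spherical Gaussian charge clouds.

    Each cloud is ``c * exp(-a |r - R|^2)``; the result is the double
    integral of cloud1(r) cloud2(r') / |r - r'|.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    pref = c1 * c2 * 2.0 * np.pi**2.5 / (a1 * a2 * np.sqrt(a1 + a2))
    theta = a1 * a2 / (a1 + a2)
    return float(pref * boys0(theta * float(np.sum((A - B) ** 2))))


def _gaussian_product(a: SGaussian, b: SGaussian):
    """Product of two s primitives as (coefficient, exponent, center)."""
    p = a.exponent + b.exponent
    mu = a.exponent * b.exponent / p
    R2 = float(np.sum((a.r - b.r) ** 2))
    P = (a.exponent * a.r + b.exponent * b.r) / p
    return a.coefficient * b.coefficient * np.exp(-mu * R2), p, P


def eri_ssss(a: SGaussian, b: SGaussian, c: SGaussian, d: SGaussian) -> float:
    """Two-electron integral (ab|cd) in chemists' notation, s primitives."""
    c1, p1, P1 = _gaussian_product(a, b)
    c2, p2, P2 = _gaussian_product(c, d)
    return coulomb_two_densities(c1, p1, P1, c2, p2, P2)


def three_center_potential_ss(rho: SGaussian, p: SGaussian, q: SGaussian) -> float:
    """Integral of V_rho(r) phi_p(r) phi_q(r), V_rho the potential of rho."""
    c1, pp, P = _gaussian_product(p, q)
    return coulomb_two_densities(
        c1, pp, P, rho.coefficient, rho.exponent, rho.r
    )


# ---------------------------------------------------------------------------
# Cartesian s/p machinery (Obara-Saika 1-D recursions, Hermite Coulomb)


def _os_overlap_1d(i: int, j: int, p: float, XPA: float, XPB: float) -> float:
    """1-D overlap polynomial factor by Obara-Saika upward recursion.

    Excludes the Gaussian prefactor sqrt(pi/p) exp(-mu X_AB^2), which is
    applied once for all three dimensions by the caller.
    """
    if i < 0 or j < 0:
        return 0.0
    if i == 0 and j == 0:
        return 1.0
    if i > 0:
        return (
            XPA * _os_overlap_1d(i - 1, j, p, XPA, XPB)
            + ((i - 1) * _os_overlap_1d(i - 2, j, p, XPA, XPB)
               + j * _os_overlap_1d(i - 1, j - 1, p, XPA, XPB)) / (2.0 * p)
        )
    return (
        XPB * _os_overlap_1d(i, j - 1, p, XPA, XPB)
        + ((j - 1) * _os_overlap_1d(i, j - 2, p, XPA, XPB)
           + i * _os_overlap_1d(i - 1, j - 1, p, XPA, XPB)) / (2.0 * p)
    )


def _cart_overlap(la, A, alpha, lb, B, beta) -> float:
    """Overlap of two unnormalized Cartesian Gaussians x^i y^j z^k exp(..)."""
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    p = alpha + beta
    mu = alpha * beta / p
    P = (alpha * A + beta * B) / p
    pref = (np.pi / p) ** 1.5 * np.exp(-mu * float(np.sum((A - B) ** 2)))
    val = pref
    for d in range(3):
        val *= _os_overlap_1d(la[d], lb[d], p, P[d] - A[d], P[d] - B[d])
    return val


def _cart_kinetic(la, A, alpha, lb, B, beta) -> float:
    """Kinetic energy integral via the S(i, j +/- 2) relation per dimension."""

    def t1d(d):
        j = lb[d]
        lbp = list(lb)
        lbp[d] = j + 2
        lbm = list(lb)
        lbm[d] = j - 2
        val = beta * (2 * j + 1) * _cart_overlap(la, A, alpha, lb, B, beta)
        val -= 2.0 * beta**2 * _cart_overlap(la, A, alpha, tuple(lbp), B, beta)
        if j >= 2:
            val -= 0.5 * j * (j - 1) * _cart_overlap(la, A, alpha, tuple(lbm), B, beta)
        return val

    # each per-dimension piece carries the full 3-D overlap of the other dims
    return sum(t1d(d) for d in range(3))


def _hermite_E(i: int, j: int, t: int, p: float, XPA: float, XPB: float) -> float:
    """Hermite expansion coefficient E_t^{ij} (McMurchie-Davidson)."""
    if t < 0 or t > i + j:
        return 0.0
    if i == 0 and j == 0:
        return 1.0 if t == 0 else 0.0
    if i > 0:
        return (
            _hermite_E(i - 1, j, t - 1, p, XPA, XPB) / (2.0 * p)
            + XPA * _hermite_E(i - 1, j, t, p, XPA, XPB)
            + (t + 1) * _hermite_E(i - 1, j, t + 1, p, XPA, XPB)
        )
    return (
        _hermite_E(i, j - 1, t - 1, p, XPA, XPB) / (2.0 * p)
        + XPB * _hermite_E(i, j - 1, t, p, XPA, XPB)
        + (t + 1) * _hermite_E(i, j - 1, t + 1, p, XPA, XPB)
    )


def _hermite_R(t: int, u: int, v: int, n: int, theta: float, X: np.ndarray) -> float:
    """Hermite Coulomb auxiliary R^n_{tuv}(theta, X)."""
    if t < 0 or u < 0 or v < 0:
        return 0.0
    if t == 0 and u == 0 and v == 0:
        return (-2.0 * theta) ** n * boys(n, theta * float(np.sum(X**2)))
    if t > 0:
        return (t - 1) * _hermite_R(t - 2, u, v, n + 1, theta, X) + X[0] * _hermite_R(
            t - 1, u, v, n + 1, theta, X
        )
    if u > 0:
        return (u - 1) * _hermite_R(t, u - 2, v, n + 1, theta, X) + X[1] * _hermite_R(
            t, u - 1, v, n + 1, theta, X
        )
    return (v - 1) * _hermite_R(t, u, v - 2, n + 1, theta, X) + X[2] * _hermite_R(
        t, u, v - 1, n + 1, theta, X
    )


def _cart_coulomb(la, A, alpha, lb, B, beta) -> float:
    """Two-center Coulomb kernel between two single Cartesian Gaussians:

    integral of g_a(r) g_b(r') / |r - r'| over r and r'.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    # expand each single Gaussian in Hermite functions about its own center
    Ea = [
        [_hermite_E(la[d], 0, t, alpha, 0.0, 0.0) for t in range(la[d] + 1)]
        for d in range(3)
    ]
    Eb = [
        [_hermite_E(lb[d], 0, t, beta, 0.0, 0.0) for t in range(lb[d] + 1)]
        for d in range(3)
    ]
    theta = alpha * beta / (alpha + beta)
    pref = 2.0 * np.pi**2.5 / (alpha * beta * np.sqrt(alpha + beta))
    X = A - B
    val = 0.0
    for t in range(la[0] + 1):
        for u in range(la[1] + 1):
            for v in range(la[2] + 1):
                ca = Ea[0][t] * Ea[1][u] * Ea[2][v]
                if ca == 0.0:
                    continue
                for t2 in range(lb[0] + 1):
                    for u2 in range(lb[1] + 1):
                        for v2 in range(lb[2] + 1):
                            cb = Eb[0][t2] * Eb[1][u2] * Eb[2][v2]
                            if cb == 0.0:
                                continue
                            sign = (-1.0) ** (t2 + u2 + v2)
                            val += ca * cb * sign * _hermite_R(
                                t + t2, u + u2, v + v2, 0, theta, X
                            )
    return pref * val


# real harmonic (l, m) -> Cartesian monomial for l <= 1; ordering m = -l..l
# follows the (y, z, x) convention for l = 1
_REAL_TO_CART = {
    (0, 0): (0, 0, 0),
    (1, -1): (0, 1, 0),
    (1, 0): (0, 0, 1),
    (1, 1): (1, 0, 0),
}


@dataclass(frozen=True)
class OracleOrbital:
    """Contracted s/p orbital with explicit primitives for direct integrals."""

    center: tuple[float, float, float]
    l: int
    m: int
    exponents: tuple[float, ...]
    coefficients: tuple[float, ...]  # multiply normalized primitives

    def __post_init__(self):
        if abs(self.m) > self.l:
            raise ValueError("|m| must not exceed l")
        if self.l > 1:
            raise NotImplementedError("oracle orbitals support l <= 1")

    def cart(self):
        return _REAL_TO_CART[(self.l, self.m)]


def direct_two_center(kernel: str, p: OracleOrbital, q: OracleOrbital) -> float:
    """Direct two-center matrix element <phi_p| K |phi_q>.

    ``kernel`` is one of ``overlap``, ``kinetic`` or ``coulomb`` (the 1/|r-r'|
    kernel acting between the two orbitals as charge densities).  This is the
    equivalence oracle for the rotation-based Slater-Koster assembly.
    """
    la, lb = p.cart(), q.cart()
    val = 0.0
    for aa, ca in zip(p.exponents, p.coefficients):
        na = cart_norm(aa, *la)
        for ab, cb in zip(q.exponents, q.coefficients):
            nb = cart_norm(ab, *lb)
            w = ca * cb * na * nb
            if kernel == "overlap":
                val += w * _cart_overlap(la, p.center, aa, lb, q.center, ab)
            elif kernel == "kinetic":
                val += w * _cart_kinetic(la, p.center, aa, lb, q.center, ab)
            elif kernel == "coulomb":
                val += w * _cart_coulomb(la, p.center, aa, lb, q.center, ab)
            else:
                raise ValueError(f"unknown kernel '{kernel}'")
    return val


# ---------------------------------------------------------------------------
# reference basis and FCI spectra


@dataclass
class OracleBasis:
    """Per-cluster list of contracted s functions (the reference basis)."""

    functions: list[ContractedS] = field(default_factory=list)

    def __len__(self):
        return len(self.functions)


def even_tempered_basis(n: int = 10, alpha0: float = 0.02, beta: float = 2.5):
    """Even-tempered s exponents alpha0 * beta^k, k = 0..n-1 (one atom)."""
    if n < 1 or alpha0 <= 0 or beta <= 1:
        raise ValueError("need n >= 1, alpha0 > 0, beta > 1")
    return tuple(alpha0 * beta**k for k in range(n))


def atom_basis(centers, exponents) -> OracleBasis:
    """Place one uncontracted normalized primitive per exponent per center."""
    funcs = [
        ContractedS(tuple(map(float, c)), (float(a),), (1.0,))
        for c in np.atleast_2d(np.asarray(centers, float))
        for a in exponents
    ]
    return OracleBasis(funcs)


def s_matrices(basis: OracleBasis, nuclei):
    """Overlap, core Hamiltonian (T - V_ne) for a contracted s basis."""
    funcs = basis.functions
    M = len(funcs)
    S = np.zeros((M, M))
    h = np.zeros((M, M))
    prims = [f.primitives() for f in funcs]
    for i in range(M):
        for j in range(i, M):
            s = t = v = 0.0
            for a in prims[i]:
                for b in prims[j]:
                    s += _overlap_prims(a, b)
                    t += _kinetic_prims(a, b)
                    v += _nuclear_prims(a, b, nuclei)
            S[i, j] = S[j, i] = s
            h[i, j] = h[j, i] = t - v
    return S, h


def s_eri(basis: OracleBasis) -> np.ndarray:
    """Full (pq|rs) tensor for a contracted s basis, vectorized over pairs."""
    funcs = basis.functions
    M = len(funcs)
    # flatten all primitive products of unique function pairs
    iu, ju = np.triu_indices(M)
    pre, exps, ctr, owner = [], [], [], []
    for k, (i, j) in enumerate(zip(iu, ju)):
        for a in funcs[i].primitives():
            for b in funcs[j].primitives():
                c, pexp, P = _gaussian_product(a, b)
                pre.append(c)
                exps.append(pexp)
                ctr.append(P)
                owner.append(k)
    pre = np.asarray(pre)
    exps = np.asarray(exps)
    ctr = np.asarray(ctr)
    owner = np.asarray(owner)
    npair = len(iu)
    nprod = len(pre)
    # Coulomb matrix between all primitive products
    pa = exps[:, None]
    pb = exps[None, :]
    pref = 2.0 * np.pi**2.5 / (pa * pb * np.sqrt(pa + pb))
    theta = pa * pb / (pa + pb)
    R2 = np.sum((ctr[:, None, :] - ctr[None, :, :]) ** 2, axis=2)
    Vprod = pre[:, None] * pre[None, :] * pref * boys0(theta * R2)
    # aggregate primitive products onto function pairs
    agg = np.zeros((npair, nprod))
    agg[owner, np.arange(nprod)] = 1.0
    Vpair = agg @ Vprod @ agg.T
    eri = np.zeros((M, M, M, M))
    i1, j1 = iu[:, None], ju[:, None]
    r1, s1 = iu[None, :], ju[None, :]
    for bi, bj in ((i1, j1), (j1, i1)):
        for kr, ks in ((r1, s1), (s1, r1)):
            eri[bi, bj, kr, ks] = Vpair
    return eri


def nuclear_repulsion(centers, charges=None) -> float:
    centers = np.atleast_2d(np.asarray(centers, float))
    n = len(centers)
    if charges is None:
        charges = np.ones(n)
    val = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            val += charges[i] * charges[j] / np.linalg.norm(centers[i] - centers[j])
    return val


def overlap_condition(basis: OracleBasis) -> tuple[float, float]:
    """(smallest eigenvalue, condition number) of the basis overlap matrix."""
    S, _ = s_matrices(basis, nuclei=())
    w = np.linalg.eigvalsh(S)
    return float(w.min()), float(w.max() / w.min())


def atom_ground_energy(exponents) -> float:
    """Ground-state energy of one hydrogen atom in the given s basis."""
    basis = atom_basis([(0.0, 0.0, 0.0)], exponents)
    S, h = s_matrices(basis, nuclei=[(1.0, (0.0, 0.0, 0.0))])
    from scipy.linalg import eigh

    w = eigh(h, S, eigvals_only=True)
    return float(w[0])


def reference_spectrum(
    centers,
    basis: OracleBasis,
    system: str = "cluster",
    ortho_threshold: float = 1e-9,
    cond_warn: float = 1e12,
) -> mb_solver.ReferenceSet:
    """Sector-resolved FCI spectra in the oracle basis, packaged per block.

    For every (N, Sz >= 0) block with a nonempty single-occupancy subspace
    in the minimal atomic basis, the k lowest total energies are computed,
    k being that subspace dimension.  Near-linear dependence in the large
    basis is removed by canonical orthogonalization with a relative
    eigenvalue threshold.
    """
    centers = np.atleast_2d(np.asarray(centers, float))
    n_sites = len(centers)
    nuclei = [(1.0, tuple(c)) for c in centers]
    S, h = s_matrices(basis, nuclei)
    w = np.linalg.eigvalsh(S)
    if w.max() / max(w.min(), 1e-300) > cond_warn:
        warnings.warn(
            f"reference overlap nearly singular (smallest eigenvalue "
            f"{w.min():.3e}); canonical orthogonalization will truncate",
            stacklevel=2,
        )
    eri = s_eri(basis)
    h2, eri2 = mb_solver.canonical_orthogonalize(S, h, eri, threshold=ortho_threshold)
    # rotate to the core-Hamiltonian eigenbasis: FCI-invariant, and gives the
    # Davidson solver an energy-ordered determinant diagonal
    _, C = np.linalg.eigh(h2)
    h2, eri2 = mb_solver.rotate_orbitals(C, h2, eri2)
    M = h2.shape[0]
    e_nuc = nuclear_repulsion(centers)
    spectra = {}
    for N, Sz in mb_solver.sector_keys(n_sites):
        k = mb_solver.single_occupancy_dim(n_sites, N, Sz)
        spectra[(N, Sz)] = mb_solver.sector_fci(h2, eri2, M, N, Sz, k=k)
    return mb_solver.select_single_occupancy(spectra, n_sites, system, e_nuc)
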