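"""Sector-resolved full configuration interaction for small orbital spaces.

The many-electron Hamiltonian is block diagonal in electron count ``N`` and
spin projection ``Sz``.  Each block is spanned by determinants built from
alpha/beta occupation strings, and the Hamiltonian action is evaluated with
the standard direct-CI sigma algorithm,

    H = sum_pq h'_pq E_pq + 1/2 sum_pqrs (pq|rs) E_pq E_rs ,
    h'_pq = h_pq - 1/2 sum_r (pr|rq) ,

where ``E_pq`` is the spin-summed excitation operator and ``(pq|rs)`` are
chemists'-notation two-electron integrals in an *orthogonal* orbital basis.
Nonorthogonal integral sets are first mapped through Loewdin or canonical
orthogonalization.

Everything here works in hartree; spin projections are half-integers stored
as floats (``Sz = (n_up - n_dn)/2``).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------------------
# configurations and combinatorics


@dataclass(frozen=True)
class Configuration:
    """One determinant: tuples of occupied spin-orbital indices per spin."""

    up: tuple[int, ...]
    dn: tuple[int, ...]

    @property
    def N(self) -> int:
        return len(self.up) + len(self.dn)

    @property
    def Sz(self) -> float:
        return (len(self.up) - len(self.dn)) / 2.0


def spin_counts(N: int, Sz: float) -> tuple[int, int] | None:
    """(n_up, n_dn) for a sector, or None if the sector is infeasible."""
    nup = N / 2.0 + Sz
    ndn = N / 2.0 - Sz
    if nup < 0 or ndn < 0 or nup != int(nup) or ndn != int(ndn):
        return None
    return int(nup), int(ndn)


def enumerate_configs(
    n_sites: int, N: int, Sz: float, single_occupancy: bool = False
) -> list[Configuration]:
    """All determinants of the (N, Sz) block on ``n_sites`` orbitals.

    With ``single_occupancy`` every site holds at most one electron (no site
    appears in both spin strings); infeasible sectors give an empty list.
    """
    if N < 0 or N > 2 * n_sites:
        return []
    counts = spin_counts(N, Sz)
    if counts is None:
        return []
    nup, ndn = counts
    if nup > n_sites or ndn > n_sites:
        return []
    out = []
    for up in itertools.combinations(range(n_sites), nup):
        for dn in itertools.combinations(range(n_sites), ndn):
            if single_occupancy and set(up) & set(dn):
                continue
            out.append(Configuration(up, dn))
    return out


def single_occupancy_dim(n_sites: int, N: int, Sz: float) -> int:
    return len(enumerate_configs(n_sites, N, Sz, single_occupancy=True))


def sector_keys(n_sites: int) -> list[tuple[int, float]]:
    """(N, Sz >= 0) blocks with a nonempty single-occupancy subspace."""
    keys = []
    for N in range(0, n_sites + 1):
        Sz = (N % 2) / 2.0
        while Sz <= N / 2.0 + 1e-9:
            if single_occupancy_dim(n_sites, N, Sz) > 0:
                keys.append((N, Sz))
            Sz += 1.0
    return keys


def count_task_targets(task_id: int, site_counts: tuple[int, ...] = (2, 3)) -> int:
    """Target bookkeeping for the two fitting tasks on H2 + symmetric H3.

    Task 1 counts the distinct (N, total spin S) sectors reachable with at
    most one electron per atom; task 2 counts all single-occupancy states
    over the (N, Sz >= 0) blocks.  Both are obtained by exhaustive
    determinant enumeration, using that the number of spin-S multiplets in a
    block is dim(Sz = S) - dim(Sz = S + 1).
    """
    if task_id not in (1, 2):
        raise ValueError(f"unknown task id {task_id}")
    total = 0
    for n_sites in site_counts:
        for N in range(0, n_sites + 1):
            if task_id == 2:
                for _, Sz in [k for k in sector_keys(n_sites) if k[0] == N]:
                    total += single_occupancy_dim(n_sites, N, Sz)
            else:
                S = (N % 2) / 2.0
                while S <= N / 2.0 + 1e-9:
                    mult = single_occupancy_dim(n_sites, N, S) - single_occupancy_dim(
                        n_sites, N, S + 1.0
                    )
                    if mult > 0:
                        total += 1
                    S += 1.0
    return total


def task_sectors(task_id: int, n_sites: int) -> list[tuple[int, float]]:
    """Sector labels for one cluster: (N, S) for task 1, (N, Sz) for task 2."""
    out = []
    for N in range(0, n_sites + 1):
        if task_id == 1:
            S = (N % 2) / 2.0
            while S <= N / 2.0 + 1e-9:
                if (
                    single_occupancy_dim(n_sites, N, S)
                    - single_occupancy_dim(n_sites, N, S + 1.0)
                ) > 0:
                    out.append((N, S))
                S += 1.0
        else:
            out.extend(k for k in sector_keys(n_sites) if k[0] == N)
    return out


# ---------------------------------------------------------------------------
# string tables


@lru_cache(maxsize=None)
def _strings(M: int, n: int) -> tuple[tuple[int, ...], ...]:
    return tuple(itertools.combinations(range(M), n))


@lru_cache(maxsize=None)
def _string_index(M: int, n: int) -> dict:
    return {s: i for i, s in enumerate(_strings(M, n))}


@dataclass(frozen=True)
class _ExcTables:
    """Symmetrized single-excitation action as gather/scatter index tables.

    The entries encode ``row = block(r<=s)*Ns + J``, ``col = I``, ``sign``
    for the operators ``a+_r a_s + a+_s a_r`` (r < s) and ``a+_r a_r``.
    Two sort orders are kept: by row (forward scatter) and by column
    (transpose application), each with ``reduceat`` segment boundaries.
    """

    n_rows: int
    fw_rows: np.ndarray  # unique target rows
    fw_starts: np.ndarray  # reduceat segment starts into fw_src/fw_sign
    fw_src: np.ndarray
    fw_sign: np.ndarray
    bw_cols: np.ndarray  # unique source columns
    bw_starts: np.ndarray
    bw_row: np.ndarray
    bw_sign: np.ndarray


def _group(keys, other, vals):
    order = np.argsort(keys, kind="stable")
    k, o, v = keys[order], other[order], vals[order]
    uniq, starts = np.unique(k, return_index=True)
    return uniq, starts, o, v


@lru_cache(maxsize=None)
def _excitation_tables(M: int, n: int) -> _ExcTables:
    strs = _strings(M, n)
    index = _string_index(M, n)
    Ns = len(strs)
    ru, su = _packed_pairs(M)
    block = {}
    for k, (r, s) in enumerate(zip(ru, su)):
        block[(int(r), int(s))] = k
        block[(int(s), int(r))] = k
    rows, cols, vals = [], [], []
    for I, occ in enumerate(strs):
        occ_set = set(occ)
        for qi, q in enumerate(occ):
            sign_q = (-1) ** qi
            rest = occ[:qi] + occ[qi + 1 :]
            for p in range(M):
                if p != q and p in occ_set:
                    continue
                pos = 0
                while pos < len(rest) and rest[pos] < p:
                    pos += 1
                new = rest[:pos] + (p,) + rest[pos:]
                sign = sign_q * ((-1) ** pos)
                rows.append(block[(p, q)] * Ns + index[new])
                cols.append(I)
                vals.append(float(sign))
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    vals = np.asarray(vals, dtype=np.float64)
    fw_rows, fw_starts, fw_src, fw_sign = _group(rows, cols, vals)
    bw_cols, bw_starts, bw_row, bw_sign = _group(cols, rows, vals)
    return _ExcTables(
        n_rows=len(ru) * Ns,
        fw_rows=fw_rows,
        fw_starts=fw_starts,
        fw_src=fw_src,
        fw_sign=fw_sign,
        bw_cols=bw_cols,
        bw_starts=bw_starts,
        bw_row=bw_row,
        bw_sign=bw_sign,
    )


def _apply_forward(tab: _ExcTables, C: np.ndarray, out: np.ndarray) -> None:
    """out[rows] = sum of sign * C[src] per target row (out pre-zeroed)."""
    if len(tab.fw_src) == 0:
        return
    P = tab.fw_sign[:, None] * C[tab.fw_src]
    out[tab.fw_rows] = np.add.reduceat(P, tab.fw_starts, axis=0)


def _apply_backward(tab: _ExcTables, G: np.ndarray, out: np.ndarray) -> None:
    """out[cols] += sum of sign * G[row] per source column."""
    if len(tab.bw_row) == 0:
        return
    Q = tab.bw_sign[:, None] * G[tab.bw_row]
    out[tab.bw_cols] += np.add.reduceat(Q, tab.bw_starts, axis=0)


@lru_cache(maxsize=None)
def _packed_pairs(M: int):
    ru, su = np.triu_indices(M)
    return ru, su


# ---------------------------------------------------------------------------
# sigma algorithm


class _SectorOperator:
    """Hamiltonian action on one (N, Sz) determinant block."""

    def __init__(self, h: np.ndarray, eri: np.ndarray, M: int, nup: int, ndn: int):
        self.M = M
        self.h, self.eri = h, eri
        self.nup, self.ndn = nup, ndn
        self.sa = _strings(M, nup)
        self.sb = _strings(M, ndn)
        self.Na, self.Nb = len(self.sa), len(self.sb)
        self.dim = self.Na * self.Nb
        self.ta = _excitation_tables(M, nup)
        self.tb = _excitation_tables(M, ndn)
        heff = h - 0.5 * np.einsum("prrq->pq", eri)
        ru, su = _packed_pairs(M)
        self.npair = len(ru)
        W = eri.reshape(M * M, M * M)
        pq_idx = ru * M + su
        # augmented kernel: last column carries the one-body term so the
        # half-transformed contraction and h'_pq c fuse into one dgemm
        self.Wp = np.empty((len(ru), len(ru) + 1))
        self.Wp[:, :-1] = 0.5 * W[np.ix_(pq_idx, pq_idx)]
        self.Wp[:, -1] = heff[ru, su]

    def sigma_block(self, Cb: np.ndarray) -> np.ndarray:
        """Hamiltonian action on a block of vectors, shape (dim, nvec).

        Large blocks are processed in chunks sized to keep the
        half-transformed intermediate near 1e7 doubles.
        """
        Na, Nb, npair = self.Na, self.Nb, self.npair
        nv = Cb.shape[1]
        nv_max = max(1, int(1.5e7 // ((npair + 1) * Na * Nb + 1)))
        if nv > nv_max:
            out = np.empty_like(Cb)
            for lo in range(0, nv, nv_max):
                out[:, lo : lo + nv_max] = self.sigma_block(Cb[:, lo : lo + nv_max])
            return out
        # vectors side by side: alpha excitations act on the leading string
        # index, so a batch just widens the trailing dimension
        C = np.ascontiguousarray(Cb.T.reshape(nv, Na, Nb).transpose(1, 2, 0))
        T = np.zeros((npair + 1, Na * Nb * nv))
        _apply_forward(
            self.ta, C.reshape(Na, Nb * nv), T[:npair].reshape(npair * Na, Nb * nv)
        )
        if self.ndn and len(self.tb.fw_src):
            Ct = np.ascontiguousarray(C.transpose(1, 0, 2)).reshape(Nb, Na * nv)
            Tb = np.zeros((npair * Nb, Na * nv))
            _apply_forward(self.tb, Ct, Tb)
            T[:npair] += (
                Tb.reshape(npair, Nb, Na, nv)
                .transpose(0, 2, 1, 3)
                .reshape(npair, -1)
            )
        T[npair] = C.reshape(-1)
        G = self.Wp @ T  # (npair, Na*Nb*nv)
        out = np.zeros((Na, Nb * nv))
        _apply_backward(self.ta, G.reshape(npair * Na, Nb * nv), out)
        out = out.reshape(Na, Nb, nv)
        if self.ndn and len(self.tb.bw_row):
            Gt = np.ascontiguousarray(
                G.reshape(npair, Na, Nb, nv).transpose(0, 2, 1, 3)
            ).reshape(npair * Nb, Na * nv)
            outT = np.zeros((Nb, Na * nv))
            _apply_backward(self.tb, Gt, outT)
            out += outT.reshape(Nb, Na, nv).transpose(1, 0, 2)
        return out.transpose(2, 0, 1).reshape(nv, -1).T

    def sigma(self, c: np.ndarray) -> np.ndarray:
        return self.sigma_block(c.reshape(-1, 1)).reshape(-1)

    def diagonal(self) -> np.ndarray:
        """Slater-Condon diagonal of the block Hamiltonian."""
        M = self.M
        h = self.h
        J = np.einsum("ppqq->pq", self.eri)
        K = np.einsum("pqqp->pq", self.eri)
        Oa = np.zeros((self.Na, M))
        for i, s in enumerate(self.sa):
            Oa[i, list(s)] = 1.0
        Ob = np.zeros((self.Nb, M))
        for i, s in enumerate(self.sb):
            Ob[i, list(s)] = 1.0
        hd = np.diag(h)
        ea = Oa @ hd + 0.5 * np.einsum("ip,pq,iq->i", Oa, J - K, Oa)
        eb = Ob @ hd + 0.5 * np.einsum("ip,pq,iq->i", Ob, J - K, Ob)
        cross = Oa @ J @ Ob.T
        return (ea[:, None] + eb[None, :] + cross).reshape(-1)

    def dense(self) -> np.ndarray:
        H = self.sigma_block(np.eye(self.dim))
        return 0.5 * (H + H.T)


def _davidson(
    op: _SectorOperator,
    k: int,
    tol: float = 1e-8,
    maxiter: int = 300,
) -> tuple[np.ndarray, np.ndarray]:
    """Block Davidson with diagonal preconditioning for the lowest k states.

    The FCI Hamiltonian is strongly diagonally dominant in the determinant
    basis, so the classic Davidson correction converges in a few dozen
    sigma builds even when the one-particle spectrum spans hundreds of
    hartree (which cripples plain Lanczos).  Deterministic: the start block
    consists of unit vectors on the lowest diagonal entries.
    """
    dim = op.dim
    diag = op.diagonal()
    nb = min(dim, k + min(k, 3) + 2)
    max_space = min(dim, max(6 * nb, 40))
    start = np.argsort(diag, kind="stable")[:nb]
    V = np.zeros((dim, nb))
    V[start, np.arange(nb)] = 1.0
    W = op.sigma_block(V)
    for _ in range(maxiter):
        Hs = V.T @ W
        Hs = 0.5 * (Hs + Hs.T)
        theta, U = np.linalg.eigh(Hs)
        theta, U = theta[:nb], U[:, :nb]
        X = V @ U
        WX = W @ U
        R = WX - X * theta
        rnorm = np.linalg.norm(R, axis=0)
        if np.all(rnorm[:k] < tol):
            return theta[:k], X[:, :k]
        # preconditioned corrections for the unconverged vectors
        new = []
        for i in range(nb):
            if rnorm[i] < tol:
                continue
            denom = theta[i] - diag
            denom = np.where(np.abs(denom) < 1e-8, np.copysign(1e-8, denom), denom)
            t = R[:, i] / denom
            new.append(t)
        if not new:
            return theta[:k], X[:, :k]
        if V.shape[1] + len(new) > max_space:
            V, W = X, WX  # thick restart from current Ritz vectors
        cand = np.column_stack(new)
        # orthogonalize candidates against the subspace (twice, for safety)
        for _ in range(2):
            cand -= V @ (V.T @ cand)
        q, rdiag = np.linalg.qr(cand)
        keep = np.abs(np.diag(rdiag)) > 1e-10
        if not keep.any():
            return theta[:k], X[:, :k]
        q = q[:, keep]
        V = np.column_stack([V, q])
        W = np.column_stack([W, op.sigma_block(q)])
    raise ValueError(
        f"Davidson failed to converge block (nup={op.nup}, ndn={op.ndn}) "
        f"within {maxiter} iterations (residuals {rnorm[:k]})"
    )


def _splus(C: np.ndarray, M: int, nup: int, ndn: int) -> np.ndarray:
    """Apply the spin-raising operator S+ = sum_p a+_{p,up} a_{p,dn}."""
    sa, sb = _strings(M, nup), _strings(M, ndn)
    sa2, sb2 = _strings(M, nup + 1), _strings(M, ndn - 1)
    ia2, ib2 = _string_index(M, nup + 1), _string_index(M, ndn - 1)
    out = np.zeros((len(sa2), len(sb2)))
    # alpha creation passes through the whole alpha block only; beta
    # annihilation anticommutes through the nup alpha operators first
    cross = (-1) ** nup
    for Ib, occb in enumerate(sb):
        for qi, p in enumerate(occb):
            signb = (-1) ** qi
            Jb = ib2[occb[:qi] + occb[qi + 1 :]]
            for Ia, occa in enumerate(sa):
                if p in occa:
                    continue
                pos = 0
                while pos < len(occa) and occa[pos] < p:
                    pos += 1
                Ja = ia2[occa[:pos] + (p,) + occa[pos:]]
                out[Ja, Jb] += cross * signb * ((-1) ** pos) * C[Ia, Ib]
    return out


def s2_expectation(vec: np.ndarray, M: int, nup: int, ndn: int) -> float:
    """<S^2> of a normalized CI vector: Sz(Sz+1) + |S+ psi|^2."""
    Sz = (nup - ndn) / 2.0
    val = Sz * (Sz + 1.0)
    if ndn > 0:
        C = vec.reshape(len(_strings(M, nup)), len(_strings(M, ndn)))
        val += float(np.sum(_splus(C, M, nup, ndn) ** 2))
    return val


# ---------------------------------------------------------------------------
# orthogonalization


def lowdin_orthogonalize(S, h, eri):
    """Map (S, h, eri) to an orthogonal basis with X = S^(-1/2).

    Raises ``ValueError`` if the overlap is not positive definite, which
    signals unphysical model parameters.
    """
    S = np.asarray(S, float)
    w, U = np.linalg.eigh(S)
    if w.min() <= 1e-14:
        raise ValueError(
            f"overlap not positive definite (min eigenvalue {w.min():.3e})"
        )
    X = U @ np.diag(w**-0.5) @ U.T
    return _congruence(X, h, eri)


def canonical_orthogonalize(S, h, eri, threshold=1e-9):
    """Canonical orthogonalization X = U s^(-1/2), dropping near-null space.

    Eigenvectors of S with eigenvalue below ``threshold * max`` are removed;
    the returned integrals may therefore live in a smaller orbital space.
    """
    S = np.asarray(S, float)
    w, U = np.linalg.eigh(S)
    keep = w > threshold * w.max()
    X = U[:, keep] * w[keep] ** -0.5
    return _congruence(X, h, eri)


def rotate_orbitals(C, h, eri):
    """Congruence transform of an integral set by an orbital matrix C.

    For orthogonal C the FCI spectrum is invariant; rotating to the
    eigenbasis of the core Hamiltonian makes the determinant diagonal
    energy-ordered, which the Davidson preconditioner relies on.
    """
    return _congruence(np.asarray(C, float), h, eri)


def _congruence(X, h, eri):
    h2 = X.T @ np.asarray(h, float) @ X
    e = np.asarray(eri, float)
    e = np.tensordot(e, X, axes=([3], [0]))  # pqr s -> pqr l
    e = np.tensordot(e, X, axes=([2], [0]))  # pq r l -> pq lk? axes order
    e = np.tensordot(e, X, axes=([1], [0]))
    e = np.tensordot(e, X, axes=([0], [0]))
    # tensordot appends new axes at the end; after four contractions the
    # axis order is reversed relative to (i,j,k,l)
    e = e.transpose(3, 2, 1, 0)
    return h2, e


# ---------------------------------------------------------------------------
# sector spectra


@dataclass
class SectorSpectrum:
    key: tuple[int, float]  # (N, Sz)
    energies: np.ndarray  # ascending, hartree (electronic only)
    s2: np.ndarray  # <S^2> per state
    vectors: np.ndarray | None = None


@dataclass
class ReferenceEntry:
    system: str
    N: int
    Sz: float
    index: int
    energy: float  # total (electronic + nuclear), hartree
    s2: float

    @property
    def spin_label(self) -> str:
        names = {0: "singlet", 1: "doublet", 2: "triplet", 3: "quartet"}
        twoS = int(round(np.sqrt(4.0 * self.s2 + 1.0) - 1.0))
        return names.get(twoS, f"2S={twoS}")


@dataclass
class ReferenceSet:
    """Sector-blocked total energies used as fitting targets/predictions."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    def block(self, system: str, N: int, Sz: float) -> list[ReferenceEntry]:
        sel = [
            e
            for e in self.entries
            if e.system == system and e.N == N and abs(e.Sz - Sz) < 1e-9
        ]
        return sorted(sel, key=lambda e: e.index)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "system": e.system,
                    "N": e.N,
                    "twoSz": int(round(2 * e.Sz)),
                    "index": e.index,
                    "energy_hartree": e.energy,
                    "s2_label": e.spin_label,
                }
                for e in self.entries
            ]
        )


_DENSE_CUTOFF = 150


def sector_fci(
    h: np.ndarray,
    eri: np.ndarray,
    n_orb: int,
    N: int,
    Sz: float,
    k: int | None = None,
    restrict_single_occupancy: bool = False,
    n_sites: int | None = None,
    keep_vectors: bool = False,
) -> SectorSpectrum:
    """Diagonalize one (N, Sz) block of the Hamiltonian.

    ``h`` and ``eri`` must be in an orthogonal orbital basis.  Electronic
    energies are returned ascending with <S^2> labels.  With
    ``restrict_single_occupancy`` the determinant space is projected onto
    configurations with at most one electron per site (orbitals are then
    identified with sites); this is the projected-subspace variant used for
    comparison with the default lowest-k selection.
    """
    counts = spin_counts(N, Sz)
    if counts is None:
        raise ValueError(f"infeasible sector N={N}, Sz={Sz}")
    nup, ndn = counts
    if nup > n_orb or ndn > n_orb:
        raise ValueError(f"infeasible sector N={N}, Sz={Sz} for {n_orb} orbitals")
    op = _SectorOperator(np.asarray(h, float), np.asarray(eri, float), n_orb, nup, ndn)
    dim = op.dim
    if dim > 1e5:
        raise ValueError(
            f"sector (N={N}, Sz={Sz}) dimension {dim} too large; split the problem"
        )
    if k is None:
        # in the projected-subspace mode only the single-occupancy states exist
        k = (
            single_occupancy_dim(n_sites if n_sites is not None else n_orb, N, Sz)
            if restrict_single_occupancy
            else dim
        )

    sub = None
    if restrict_single_occupancy:
        sites = n_sites if n_sites is not None else n_orb
        if sites != n_orb:
            raise ValueError("single-occupancy restriction needs orbitals == sites")
        sub = [
            ia * op.Nb + ib
            for ia, a in enumerate(op.sa)
            for ib, b in enumerate(op.sb)
            if not (set(a) & set(b))
        ]
        H = op.dense()[np.ix_(sub, sub)]
        w, V = np.linalg.eigh(H)
        full = np.zeros((dim, V.shape[1]))
        full[sub] = V
        V = full
    elif dim <= _DENSE_CUTOFF or k >= dim - 2:
        H = op.dense()
        w, V = np.linalg.eigh(H)
    else:
        w, V = _davidson(op, k)

    if len(w) < k:
        raise ValueError(
            f"sector (N={N}, Sz={Sz}): requested {k} states, solver produced {len(w)}"
        )
    w, V = w[:k], V[:, :k]
    s2 = np.array([s2_expectation(V[:, i], n_orb, nup, ndn) for i in range(len(w))])
    return SectorSpectrum(
        key=(N, Sz),
        energies=w,
        s2=s2,
        vectors=V if keep_vectors else None,
    )


def select_single_occupancy(
    spectra: dict[tuple[int, float], SectorSpectrum],
    n_sites: int,
    system: str,
    e_nuc: float,
) -> ReferenceSet:
    """Keep the k lowest states per (N, Sz >= 0) block, k = single-occupancy
    dimension, and package them with total energies and spin labels."""
    out = ReferenceSet()
    for (N, Sz), spec in sorted(spectra.items()):
        kdim = single_occupancy_dim(n_sites, N, Sz)
        if kdim == 0:
            continue
        if len(spec.energies) < kdim:
            raise ValueError(
                f"block (N={N}, Sz={Sz}) solved for {len(spec.energies)} states, "
                f"needs {kdim}"
            )
        for i in range(kdim):
            out.entries.append(
                ReferenceEntry(
                    system=system,
                    N=N,
                    Sz=Sz,
                    index=i,
                    energy=float(spec.energies[i] + e_nuc),
                    s2=float(spec.s2[i]),
                )
            )
    return out


def distinct_levels(energies, tol: float) -> list[float]:
    """Merge energies closer than ``tol`` into single levels (block-local)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    es = sorted(float(e) for e in energies)
    if not es:
        return []
    levels = [[es[0]]]
    for e in es[1:]:
        if e - levels[-1][-1] < tol:
            levels[-1].append(e)
        else:
            levels.append([e])
    return [float(np.mean(g)) for g in levels]
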