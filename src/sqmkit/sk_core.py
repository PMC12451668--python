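"""Two-center matrix elements from radial channels and harmonic rotations.

Any matrix element of a translationally and rotationally invariant
two-center kernel between atomic orbitals factorizes into radial channel
functions ``K_m(r)`` evaluated in a standard pose (bond along +z) and
rotation matrices between real spherical harmonics:

    K_pq = sum_{M=-L..L} R^l_{m,M}(u) K^{tt'}_{|M|}(|r-r'|) R^{l'}_{m',M}(u)

with ``L = min(l, l')`` and ``u`` the unit bond vector.  The rotation
matrices are generated by the stable recursion of Ivanic and Ruedenberg
from the l = 1 block.

Conventions (fixed throughout the package):
  * real spherical harmonics with the Condon-Shortley-derived real forms,
    m ordered -l..l; for l = 1 this is (y, z, x);
  * ``R^l_{m,M}(u)`` is the coefficient of the u-aligned harmonic M in the
    expansion of the standard (z-aligned) harmonic m;
  * the anti-parallel alignment u = -z is resolved by a rotation of pi
    about the x axis (fixed tie-break).

Atomic units everywhere: distances in bohr, energy kernels in hartree,
overlap dimensionless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "OrbitalLabel",
    "RotationBlock",
    "RadialChannel",
    "SlaterKosterTable",
    "rotation_block",
    "rotation_matrix_to",
    "real_rotation_matrices",
    "radial_value",
    "sk_element",
    "assemble_two_center",
    "check_symmetry",
]


# ---------------------------------------------------------------------------
# labels


@dataclass(frozen=True)
class OrbitalLabel:
    """Atomic-orbital label p = (center, type tag, l, m)."""

    center: tuple[float, float, float]
    tau: str
    l: int
    m: int

    def __post_init__(self):
        if self.l < 0:
            raise ValueError("angular quantum number l must be nonnegative")
        if abs(self.m) > self.l:
            raise ValueError(f"|m| = {abs(self.m)} exceeds l = {self.l}")
        if not np.all(np.isfinite(self.center)):
            raise ValueError("orbital center must be finite")

    @property
    def r(self) -> np.ndarray:
        return np.asarray(self.center, float)


# ---------------------------------------------------------------------------
# real-spherical-harmonic rotations


def rotation_matrix_to(u: np.ndarray) -> np.ndarray:
    """3x3 rotation R with R z = u (Rodrigues about z x u).

    For u anti-parallel to z the axis is degenerate; the fixed convention
    is a rotation of pi about the x axis.
    """
    u = np.asarray(u, float)
    nu = np.linalg.norm(u)
    if abs(nu - 1.0) > 1e-10:
        raise ValueError(f"direction vector must be unit length (|u| = {nu})")
    z = np.array([0.0, 0.0, 1.0])
    c = float(u @ z)
    if c > 1.0 - 1e-14:
        return np.eye(3)
    if c < -1.0 + 1e-14:
        return np.diag([1.0, -1.0, -1.0])  # pi about x
    axis = np.cross(z, u)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


# index permutation mapping harmonic order (m=-1,0,1) = (y,z,x) onto (x,y,z)
_P1 = np.array([1, 2, 0])


def _d1_from_R(R: np.ndarray) -> np.ndarray:
    """l = 1 real-harmonic block for rotation R in the package convention.

    With Y_m linear in the direction vector, Y_m(R s) = sum_M D_{m,M} Y_M(s)
    gives D_{m,M} = R[axis(m), axis(M)] in the (y, z, x) index permutation.
    """
    D = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            D[i, j] = R[_P1[i], _P1[j]]
    return D


def _ir_recursion(l: int, D1: np.ndarray, Dprev: np.ndarray) -> np.ndarray:
    """One step of the Ivanic-Ruedenberg recursion: D^l from D^(l-1)."""

    def r1(i, j):  # D^1 with indices in -1..1
        return D1[i + 1, j + 1]

    def prev(mu, m):  # D^(l-1) with indices in -(l-1)..(l-1)
        if abs(mu) > l - 1 or abs(m) > l - 1:
            return 0.0
        return Dprev[mu + l - 1, m + l - 1]

    def P(i, l_, mu, m_):
        if m_ == l_:
            return r1(i, 1) * prev(mu, l_ - 1) - r1(i, -1) * prev(mu, -(l_ - 1))
        if m_ == -l_:
            return r1(i, 1) * prev(mu, -(l_ - 1)) + r1(i, -1) * prev(mu, l_ - 1)
        return r1(i, 0) * prev(mu, m_)

    D = np.empty((2 * l + 1, 2 * l + 1))
    for m in range(-l, l + 1):
        for mp in range(-l, l + 1):
            if abs(mp) < l:
                denom = (l + mp) * (l - mp)
            else:
                denom = (2 * l) * (2 * l - 1)
            uu = np.sqrt((l + m) * (l - m) / denom)
            vv = (
                0.5
                * np.sqrt(
                    (1.0 + (m == 0)) * (l + abs(m) - 1) * (l + abs(m)) / denom
                )
                * (1.0 - 2.0 * (m == 0))
            )
            ww = -0.5 * np.sqrt((l - abs(m) - 1) * (l - abs(m)) / denom) * (
                1.0 - (m == 0)
            )
            U = P(0, l, m, mp)
            if m == 0:
                V = P(1, l, 1, mp) + P(-1, l, -1, mp)
                W = 0.0
            elif m > 0:
                V = P(1, l, m - 1, mp) * np.sqrt(1.0 + (m == 1)) - P(
                    -1, l, -m + 1, mp
                ) * (1.0 - (m == 1))
                W = P(1, l, m + 1, mp) + P(-1, l, -m - 1, mp)
            else:
                V = P(1, l, m + 1, mp) * (1.0 - (m == -1)) + P(
                    -1, l, -m - 1, mp
                ) * np.sqrt(1.0 + (m == -1))
                W = P(1, l, m - 1, mp) - P(-1, l, -m + 1, mp)
            D[m + l, mp + l] = uu * U + vv * V + ww * W
    return D


def real_rotation_matrices(R: np.ndarray, lmax: int) -> list[np.ndarray]:
    """Real-harmonic rotation blocks D^0 .. D^lmax for a 3x3 rotation R."""
    mats = [np.array([[1.0]])]
    if lmax >= 1:
        mats.append(_d1_from_R(R))
    for l in range(2, lmax + 1):
        mats.append(_ir_recursion(l, mats[1], mats[l - 1]))
    return mats


@dataclass(frozen=True)
class RotationBlock:
    """(2l+1)x(2l+1) orthogonal block R^l_{m,M}(u), rows/cols m = -l..l."""

    l: int
    u: tuple[float, float, float]
    matrix: np.ndarray


def rotation_block(l: int, u) -> RotationBlock:
    """Expansion of standard z-aligned harmonics in u-aligned harmonics."""
    if l < 0:
        raise ValueError("l must be nonnegative")
    u = np.asarray(u, float)
    R = rotation_matrix_to(u)
    D = real_rotation_matrices(R, l)[l]
    return RotationBlock(l=l, u=tuple(u), matrix=D)


# ---------------------------------------------------------------------------
# radial channels


_TAILS = ("zero", "monopole")


@dataclass
class RadialChannel:
    """One radial channel K_m^{tau tau'}(r) with cutoff and tail rules.

    Either an analytic callable ``func`` or a cubic-spline grid
    representation (``r_grid``, ``values``) must be supplied.  Beyond the
    cutoff the declared tail applies exactly: zero for local kernels, the
    monopole interaction q q'/r for Coulomb kernels.
    """

    tau_pair: tuple[str, str]
    l_pair: tuple[int, int]
    m: int
    cutoff: float
    tail: str = "zero"
    charges: tuple[float, float] = (1.0, 1.0)
    func: object = None
    r_grid: np.ndarray | None = None
    values: np.ndarray | None = None
    _spline: object = field(default=None, repr=False)

    def __post_init__(self):
        if self.m < 0 or self.m > min(self.l_pair):
            raise ValueError("channel index m must satisfy 0 <= m <= min(l, l')")
        if self.tail not in _TAILS:
            raise ValueError(f"tail must be one of {_TAILS}, got '{self.tail}'")
        if self.func is None:
            if self.r_grid is None or self.values is None:
                raise ValueError("supply either func or (r_grid, values)")
            r = np.asarray(self.r_grid, float)
            v = np.asarray(self.values, float)
            if len(r) < 4 or np.any(np.diff(r) <= 0):
                raise ValueError("grid must be increasing with >= 4 knots")
            self.r_grid, self.values = r, v
            self._spline = CubicSpline(r, v)
            tail_val = self._tail_value(self.cutoff)
            if abs(v[-1] - tail_val) > 1e-8:
                warnings.warn(
                    f"channel {self.key()}: last knot {v[-1]:.3e} does not "
                    f"match tail value {tail_val:.3e} at the cutoff; the "
                    "kernel is discontinuous there",
                    stacklevel=2,
                )

    def key(self):
        return (*self.tau_pair, *self.l_pair, self.m)

    def _tail_value(self, r: float) -> float:
        if self.tail == "zero":
            return 0.0
        return self.charges[0] * self.charges[1] / r

    def __call__(self, r: float) -> float:
        return radial_value(self, r)


def radial_value(channel: RadialChannel, r: float) -> float:
    """Evaluate a channel at distance r, honoring cutoff and tail rules."""
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    if r > channel.cutoff:
        return channel._tail_value(r)
    if channel.func is not None:
        return float(channel.func(r))
    if r < channel.r_grid[0] - 1e-12:
        raise ValueError(
            f"distance {r} below grid start {channel.r_grid[0]} "
            f"for channel {channel.key()}"
        )
    return float(channel._spline(r))


DEFAULT_GRID_START = 0.5
DEFAULT_GRID_STEP = 0.1
DEFAULT_CUTOFF = 10.0


def default_grid(
    start: float = DEFAULT_GRID_START,
    step: float = DEFAULT_GRID_STEP,
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    n = int(round((cutoff - start) / step)) + 1
    return start + step * np.arange(n)


# ---------------------------------------------------------------------------
# tables


KERNEL_KINDS = ("overlap", "one_body", "ee_coulomb", "eH_coulomb", "HH_coulomb")


@dataclass
class SlaterKosterTable:
    """A set of radial channels for one kernel kind.

    Channels are stored for the independent set and auto-completed through
    the symmetry K_m^{tt'}(r) = (-1)^(l+l') K_m^{t't}(r); a lookup of the
    swapped pair returns the stored channel with the sign applied.
    """

    kernel_kind: str
    channels: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kernel_kind not in KERNEL_KINDS:
            raise ValueError(
                f"kernel_kind must be one of {KERNEL_KINDS}, got "
                f"'{self.kernel_kind}'"
            )

    def add(self, channel: RadialChannel) -> None:
        self.channels[channel.key()] = channel

    def value(self, tau, taup, l, lp, m, r) -> float:
        """K_m^{tt'}(r) with automatic symmetry completion."""
        key = (tau, taup, l, lp, m)
        ch = self.channels.get(key)
        if ch is not None:
            return radial_value(ch, r)
        swapped = self.channels.get((taup, tau, lp, l, m))
        if swapped is not None:
            return ((-1.0) ** (l + lp)) * radial_value(swapped, r)
        raise KeyError(
            f"no channel for (tau={tau}, tau'={taup}, l={l}, l'={lp}, m={m}) "
            f"in {self.kernel_kind} table"
        )

    def has(self, tau, taup, l, lp, m) -> bool:
        return (tau, taup, l, lp, m) in self.channels or (
            taup,
            tau,
            lp,
            l,
            m,
        ) in self.channels


def check_symmetry(table: SlaterKosterTable, r_sample=None, tol: float = 1e-10):
    """Verify the sign relation on a distance sample; returns violations.

    Each violation is (key, r, lhs, rhs) with lhs = K_m^{tt'}(r) and
    rhs = (-1)^(l+l') K_m^{t't}(r).
    """
    if r_sample is None:
        r_sample = np.linspace(0.6, 8.0, 16)
    violations = []
    for (tau, taup, l, lp, m), ch in table.channels.items():
        partner = table.channels.get((taup, tau, lp, l, m))
        if partner is None:
            continue
        sign = (-1.0) ** (l + lp)
        for r in r_sample:
            lhs = radial_value(ch, float(r))
            rhs = sign * radial_value(partner, float(r))
            if abs(lhs - rhs) > tol * max(1.0, abs(lhs)):
                violations.append(((tau, taup, l, lp, m), float(r), lhs, rhs))
    return violations


# ---------------------------------------------------------------------------
# assembly


def sk_element(p: OrbitalLabel, q: OrbitalLabel, table: SlaterKosterTable) -> float:
    """Two-center matrix element via the rotation decomposition."""
    d = p.r - q.r
    r = float(np.linalg.norm(d))
    if r < 1e-12:
        raise ValueError(
            "coincident centers: one-center elements are not Slater-Koster "
            "assembled; supply them directly"
        )
    u = d / r
    L = min(p.l, q.l)
    Dp = rotation_block(p.l, u).matrix
    Dq = rotation_block(q.l, u).matrix
    val = 0.0
    for M in range(-L, L + 1):
        val += (
            Dp[p.m + p.l, M + p.l]
            * table.value(p.tau, q.tau, p.l, q.l, abs(M), r)
            * Dq[q.m + q.l, M + q.l]
        )
    return val


def assemble_two_center(
    geometry,
    basis_spec: dict,
    table: SlaterKosterTable,
    one_center=None,
):
    """Full matrix of two-center elements over all orbitals of a cluster.

    ``geometry`` is a list of (tau, center); ``basis_spec`` maps tau to the
    list of shell l values.  Diagonal (one-center) blocks are delegated to
    the caller through ``one_center(atom_index, (l, m), (l', m'))``; they
    default to zero.  Returns (matrix, labels).
    """
    labels = []
    atom_of = []
    for ia, (tau, center) in enumerate(geometry):
        if tau not in basis_spec:
            raise KeyError(f"no shells declared for atom type '{tau}'")
        for l in basis_spec[tau]:
            for m in range(-l, l + 1):
                labels.append(OrbitalLabel(tuple(center), tau, l, m))
                atom_of.append(ia)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if atom_of[i] == atom_of[j]:
                if one_center is not None:
                    out[i, j] = one_center(
                        atom_of[i],
                        (labels[i].l, labels[i].m),
                        (labels[j].l, labels[j].m),
                    )
            else:
                out[i, j] = sk_element(labels[i], labels[j], table)
    return out, labels
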