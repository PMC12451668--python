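"""Minimal-basis hydrogen-cluster model Hamiltonian.

One s-type primary and one s-type auxiliary function per hydrogen atom.
The model has two one-center parameters -- the orbital energy ``eps``
(fixed to the exact isolated-atom value -1/2 hartree and never fitted)
and the electronic Coulomb self-energy ``U`` -- and five two-center
parameters at the working distance r: overlap S, one-body Hamiltonian H,
and the electron-electron (Vee), electron-proton (VeH) and proton-proton
(VHH) Coulomb interactions.

Matrix elements:
  * overlap: unit diagonal, S on bonded pairs;
  * one-body: diagonal eps - sum_{j != i} VeH(r_ij) (a positive VeH is an
    attraction and lowers the on-site energy; off-diagonal electron-proton
    terms are absorbed into the H channel), off-diagonal H(r_ij);
  * two-electron integrals from the charge-conserving factored Coulomb
    model with primary = auxiliary (Q = 1, V_mumu = U, V_munu = Vee, Z=0);
  * nuclear energy sum_{i<j} VHH(r_ij).

Beyond the nearest-neighbor distance (the second-neighbor pair of the
linear trimer) the local channels S and H truncate to zero while all
three Coulomb channels follow their parameter-free monopole tails 1/d,
so the parameters remain per-distance quantities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import coulomb_factor as cf
from . import mb_solver, sk_core

__all__ = ["HModelParameters", "HClusterGeometry", "model_integrals", "cluster_spectrum"]

EPS_EXACT = -0.5  # exact 1s orbital energy of an isolated hydrogen atom

ONE_CENTER_PARAMS = ("eps", "U")
TWO_CENTER_PARAMS = ("S", "H", "Vee", "VeH", "VHH")


@dataclass
class HModelParameters:
    """The hydrogen model's 2 one-center + 5 two-center parameters.

    Two-center entries are the channel values at the working distance
    (scalars); any of them may instead be a callable of distance or a
    :class:`sqmkit.sk_core.RadialChannel` for scans.
    """

    U: float
    S: object = 0.0
    H: object = 0.0
    Vee: object = 0.0
    VeH: object = 0.0
    VHH: object = 0.0
    eps: float = EPS_EXACT

    def validate(self, r: float) -> None:
        s = _pair_value(self.S, r, nearest=True, coulomb=False)
        if abs(s) >= 1.0:
            raise ValueError(f"|S(r)| = {abs(s)} >= 1: overlap not positive definite")
        vhh = _pair_value(self.VHH, r, nearest=True, coulomb=True)
        if vhh <= 0:
            raise ValueError(f"VHH(r) = {vhh} must be positive")

    def two_center_values(self, r: float) -> dict:
        return {
            name: _pair_value(
                getattr(self, name), r, nearest=True, coulomb=name.startswith("V")
            )
            for name in TWO_CENTER_PARAMS
        }


def _pair_value(v, d: float, nearest: bool, coulomb: bool) -> float:
    """Evaluate a two-center parameter at pair distance d.

    Scalars are per-distance values: they apply at the nearest-neighbor
    distance, while more distant pairs follow the truncation rules (zero
    for local channels, the monopole tail 1/d for Coulomb channels).
    Radial channels and callables are evaluated directly.
    """
    if isinstance(v, sk_core.RadialChannel):
        return sk_core.radial_value(v, d)
    if callable(v):
        return float(v(d))
    if nearest:
        return float(v)
    return 1.0 / d if coulomb else 0.0


GEOMETRY_KINDS = ("dimer", "linear_trimer", "equilateral_trimer")


@dataclass(frozen=True)
class HClusterGeometry:
    """Symmetric hydrogen cluster: dimer or trimer at spacing r (bohr)."""

    kind: str
    spacing: float

    def __post_init__(self):
        if self.kind not in GEOMETRY_KINDS:
            raise ValueError(f"kind must be one of {GEOMETRY_KINDS}")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_atoms(self) -> int:
        return 2 if self.kind == "dimer" else 3

    @property
    def system(self) -> str:
        return "H2" if self.kind == "dimer" else "H3"

    def positions(self) -> np.ndarray:
        r = self.spacing
        if self.kind == "dimer":
            return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
        if self.kind == "linear_trimer":
            return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r], [0.0, 0.0, 2 * r]])
        h = r * np.sqrt(3.0) / 2.0
        return np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r], [0.0, h, r / 2.0]])


def model_integrals(geom: HClusterGeometry, params: HModelParameters):
    """(overlap, one-body, two-electron, nuclear energy) for the cluster."""
    r = geom.spacing
    params.validate(r)
    pos = geom.positions()
    n = geom.n_atoms
    dist = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    near = np.abs(dist - r) < 1e-9 * max(r, 1.0)

    def pv(v, i, j, coulomb):
        return _pair_value(v, float(dist[i, j]), bool(near[i, j]), coulomb)

    S = np.eye(n)
    h = np.zeros((n, n))
    for i in range(n):
        h[i, i] = params.eps
        for j in range(n):
            if j == i:
                continue
            S[i, j] = pv(params.S, i, j, False)
            h[i, j] = pv(params.H, i, j, False)
            h[i, i] -= pv(params.VeH, i, j, True)
    w = np.linalg.eigvalsh(S)
    if w.min() <= 0:
        raise ValueError(
            f"overlap not positive definite (min eigenvalue {w.min():.3e})"
        )

    aux = [cf.AuxFunction(tuple(p), "H", 0, 0, 1.0) for p in pos]
    vee_tab = sk_core.SlaterKosterTable(kernel_kind="ee_coulomb")
    vee_tab.add(
        sk_core.RadialChannel(
            ("H", "H"),
            (0, 0),
            0,
            cutoff=1e9,  # distance logic (tails included) lives in _pair_value
            tail="monopole",
            func=lambda d: _pair_value(
                params.Vee, d, nearest=abs(d - r) < 1e-9 * max(r, 1.0), coulomb=True
            ),
        )
    )
    metric = cf.build_metric(aux, vee_tab, {"H": float(params.U)})
    fit = cf.build_fit_tensor(S, np.arange(n), metric)
    eri = cf.factored_eri(fit, metric)

    e_nuc = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e_nuc += pv(params.VHH, i, j, True)
    return S, h, eri, e_nuc


def cluster_spectrum(
    geom: HClusterGeometry,
    params: HModelParameters,
    selection: str = "lowest_k",
) -> mb_solver.ReferenceSet:
    """Sector-resolved model spectra with single-occupancy state counts.

    ``selection`` chooses between the default lowest-k selection from the
    full minimal-basis FCI of each (N, Sz) block and a projected FCI
    restricted to the single-occupancy configuration subspace.
    """
    if selection not in ("lowest_k", "restricted"):
        raise ValueError("selection must be 'lowest_k' or 'restricted'")
    S, h, eri, e_nuc = model_integrals(geom, params)
    h2, eri2 = mb_solver.lowdin_orthogonalize(S, h, eri)
    n = geom.n_atoms
    spectra = {}
    for N, Sz in mb_solver.sector_keys(n):
        k = mb_solver.single_occupancy_dim(n, N, Sz)
        spectra[(N, Sz)] = mb_solver.sector_fci(
            h2,
            eri2,
            n,
            N,
            Sz,
            k=k,
            restrict_single_occupancy=(selection == "restricted"),
        )
    return mb_solver.select_single_occupancy(spectra, n, geom.system, e_nuc)
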