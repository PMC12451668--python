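# Methods

This note documents the models, algorithms, numerical conventions and
deliberate design choices behind `sqmkit`. Everything is in atomic units
(hartree, bohr); spin projections are half-integers.

## Two-center matrix elements

Any matrix element of a translationally and rotationally invariant
two-center kernel `K` between real atomic orbitals factorizes as

    K_pq = sum_{M=-L}^{L} R^l_{m,M}(u) K^{tt'}_{|M|}(r) R^{l'}_{m',M}(u),
    L = min(l, l'),  u = (r_p - r_q)/|r_p - r_q|,

where `K_M(r)` are radial channel functions tabulated in the standard
pose (orbital p displaced by `r` along +z from orbital q) and `R^l(u)`
are rotation matrices between real spherical harmonics. The rotation
blocks are built once per direction by the stable Ivanic–Ruedenberg
recursion seeded from the l = 1 block; the conventions are

* real harmonics in Condon–Shortley-derived form, ordered m = −l..l
  (so l = 1 is y, z, x);
* `R^l_{m,M}(u)` is the coefficient of the u-aligned harmonic M in the
  expansion of the standard z-aligned harmonic m;
* the degenerate anti-parallel alignment u ≈ −z is resolved by a fixed
  auxiliary rotation of π about the x axis.

Orthogonality of every block is maintained to 1e-12 and the assembly is
validated against direct integration of s/p Gaussian orbitals to 1e-8.

Radial channels carry a cutoff radius and a declared tail: identically
zero beyond the cutoff for local kernels (overlap, one-body), or the
monopole interaction q·q′/r for Coulomb kernels. The grid representation
is a cubic spline on a uniform grid (default start 0.5 bohr, spacing
0.1 bohr, cutoff 10 bohr); analytic callables are accepted everywhere a
spline is. Continuity at the cutoff is enforced by requiring the last
knot to equal the tail value there; a violation is reported as a warning
because it produces an energy discontinuity in distance scans. The
channel symmetry `K_m^{tt'} = (−1)^{l+l'} K_m^{t't}` is applied
automatically on lookup, so only the independent set 0 ≤ m ≤ l ≤ l′ is
stored.

## Factored four-center Coulomb integrals

Four-center Coulomb integrals are approximated by atom-local density
fitting, `V_pqrs ≈ Σ_{μν} X^μ_pq V_{μν} X^ν_rs`, with auxiliary charge
distributions restricted to the atoms of p and q. The single hard
constraint is exact conservation of electronic charge,
`Σ_μ X^μ_pq Q_μ = S_pq`. One-center coefficients solve a Coulomb-metric
least-squares problem with the constraint imposed through a KKT system
(never a penalty), so the sum rule holds to machine precision; a
rank-deficient KKT system falls back to the smallest-norm solution and
reports it. Two-center coefficients use the closed-form
charge-conserving expression built from the pair-block inverse metric Λ,
the auxiliary charges, and a one-center projection tensor Z that
approximates products of the auxiliary potential with a primary orbital
on that atom's primary basis. Z is fitted by linear least squares over a
sample of partner placements (a uniform distance scan, 0.8–4 bohr by
default in the validation suite); the sampling is a package choice since
only the functional form of the projection is prescribed by the model
structure.

With two-center overlaps set to zero and Z = 0, all cross-atom fit
coefficients vanish identically and the factorization reduces exactly to
the NDDO approximation; with Z = 0 and nonzero overlap it reduces to
symmetric (Mulliken-like) charge splitting. Systematic improvability
holds in the intended sense: enlarging the auxiliary set monotonically
reduces the constrained one-center metric residual (a nesting argument),
and on an s-Gaussian dimer with an adequate primary basis the maximum
factored-integral error decreases as auxiliaries are added toward
spanning the orbital-product space. Adding auxiliaries alone, with a
single primary function per atom, does **not** improve the two-center
fits — the potential-product projection is then bottlenecked by the
primary expansion — which is why the validation enlarges both spaces together.

## The Gaussian integral oracle and the internal reference

The oracle evaluates closed-form integrals over primitive Gaussians:
overlap, kinetic and nuclear attraction for s (and, for the rotation
tests, Cartesian p) functions, s-type two-electron integrals through the
Boys function, and three-center potential integrals. The Boys function
uses the erf closed form with a series branch below 1e-13 and the
regularized incomplete gamma function for higher orders. All closed
forms are cross-checked against adaptive/grid quadrature in the test
suite.

Reference spectra for the hydrogen clusters are produced by
sector-resolved FCI in an even-tempered basis of 10 s primitives per
atom (exponents 0.02·2.5^k, k = 0..9). This basis reaches the isolated
atom to ~3e-5 hartree and is the package's internal, reduced-scale
stand-in for a large correlation-consistent reference; an adapter hook
(`fitkit.reference_sets(r, provider=...)`, any callable from geometry
kind and spacing to a `ReferenceSet`) lets an external engine supply
higher-quality data without touching downstream code. Near-linear
dependence in the cluster basis is removed by canonical orthogonalization
with a relative eigenvalue threshold of 1e-9 (a warning fires when the
overlap condition number exceeds 1e12), and the integrals are then
rotated to the core-Hamiltonian eigenbasis — an FCI-invariant
transformation that gives the Davidson solver an energy-ordered
determinant diagonal.

## Sector-resolved FCI

The many-electron Hamiltonian is block diagonal in (N, Sz). Each block
is spanned by alpha/beta occupation strings; the Hamiltonian action is
the direct-CI sigma algorithm with symmetrized single-excitation
generators held as precomputed gather/scatter tables, and the
two-electron contraction packed over orbital pairs. Small blocks
(dimension ≤ 150, or when essentially all states are requested) are
diagonalized densely; larger blocks use a block Davidson method with
diagonal (Slater–Condon) preconditioning, deterministic unit-vector
starts on the lowest diagonal entries, residual tolerance 1e-8 and thick
restarts. Plain Lanczos is avoided deliberately: the one-particle
spectrum of the even-tempered basis spans hundreds of hartree and makes
unpreconditioned iteration impractically slow. An unconverged block
raises an error naming the block.

Spin labels are attached as ⟨S²⟩ = Sz(Sz+1) + ‖S₊ψ‖², evaluated by
applying the spin-raising operator exactly in string space; states are
labelled singlet/doublet/triplet/quartet by rounding to the nearest
S(S+1). Spectra are computed only for Sz ≥ 0; the Sz < 0 blocks are
images under spin flip.

Nonorthogonal model bases enter through Löwdin symmetric
orthogonalization (`S^{-1/2}`); a non-positive-definite overlap raises
immediately, which is the signal that model parameters are unphysical.
The FCI spectrum is checked to be invariant (to 1e-10) under the choice
of orthogonalizer.

### Single-occupancy bookkeeping

The fitting targets are organized around the single-occupancy sector:
configurations with at most one electron per atom. For each (N, Sz ≥ 0)
block the retained state count k equals the dimension of that block's
single-occupancy configuration space in the minimal basis. Two selection
modes exist for the model side: the default keeps the k lowest states of
the full minimal-basis FCI; the alternative (`selection="restricted"`)
diagonalizes the Hamiltonian projected onto the single-occupancy
subspace. The default mirrors how the reference states are selected
(lowest-k from the full spectrum), treating model and reference
symmetrically. Energy degeneracy handling uses a merge tolerance of
1e-9 hartree for exact spectra and 1e-6 hartree when comparing fitted
to reference data.

The trimer is the **linear** symmetric arrangement. With that geometry
and (N, Sz ≥ 0) block counting, the dimer + trimer totals are exactly
4 + 6 = 10 distinct (N, S) ground-state sectors and 6 + 17 = 23
single-occupancy states, which fixes both conventions. An equilateral
variant is supported; its E-symmetry degeneracies merge levels and lower
the distinct-state count.

## The hydrogen-cluster model

One s primary and one s auxiliary function per atom. Parameters: the
orbital energy eps (fixed at the exact hydrogenic value −0.5 hartree,
never fitted) and the Coulomb self-energy U (one-center); overlap S,
one-body Hamiltonian H, and electron–electron, electron–proton,
proton–proton Coulomb interactions Vee, VeH, VHH (two-center, per
distance). Conventions worth stating:

* VeH enters only the one-body diagonal, as
  `h_ii = eps − Σ_{j≠i} VeH(r_ij)`; a positive VeH is an attraction.
  Off-diagonal electron–proton contributions are absorbed into the H
  channel. This partitioning affects parameter interpretation only, not
  model expressiveness.
* The auxiliary self-metric is identified with U and the intersite
  metric with Vee, with Z = 0, so the factored integrals reproduce
  `(ii|ii) = U` and `(ii|jj) = Vee(r)` exactly and the parameter count
  stays at 2 + 5.
* In the linear trimer the second-neighbor pair (distance 2r) uses the
  truncation rules: S and H vanish there, the three Coulomb channels
  follow their parameter-free monopole tails 1/(2r).

A structural consequence of that truncation: the trimer overlap matrix
[[1,S,0],[S,1,S],[0,S,1]] is positive definite only for |S| < 1/√2
≈ 0.707, while the physical 1s–1s overlap at 1.4 bohr is ≈ 0.75. Fits on
the dimer + trimer task sets therefore settle at small |S| and absorb
overlap effects into H and the Coulomb channels. Relatedly, flipping the
sign of one orbital maps (S, H) → (−S, −H) with all energies unchanged
(both shipped clusters are bipartite), so the pair is identifiable only
up to a joint sign; reported fits use the gauge S ≥ 0, with H ≤ 0
breaking a tie at S = 0.

## Fitting protocol

Two task sets define the targets: task 1, the 10 sector ground states
(one per distinct (N, S) sector of the dimer and trimer); task 2, all
23 single-occupancy states over the (N, Sz ≥ 0) blocks. Weights are
uniform. Model and reference states pair by (system, N, spin key,
ascending index) — energy-only pairing, no wavefunction overlap.

The protocol is two-staged: U is fitted jointly with the five two-center
values at 1.4 bohr (near the H2 equilibrium bond length) and then frozen;
the two-center parameters are refitted independently at each working
distance. The objective is the weighted RMS energy error. The optimizer
is a bounded Nelder–Mead simplex refined by trust-region least squares
with numerical Jacobians, run from a 20-start ensemble (seed 12345):
start 0 is the oracle initial guess — integrals of a three-Gaussian
expansion of the hydrogenic 1s orbital, with S clipped into the trimer
positive-definiteness region — and the rest are seeded Gaussian
perturbations of it. The ensemble stops early once a start reaches
RMS < 1e-10, which preserves determinism while making zero-residual
recovery runs cheap. Parameter bounds: |S| ≤ 0.99, U ∈ (1e-3, 5),
Vee, VeH ∈ (0, 5), VHH ∈ (1e-6, 5), |H| ≤ 5. Parameter sets that break
overlap positivity inside the bounds are handled by a large smooth
penalty on the residuals rather than an exception.

Zero-noise self-generated references are recovered to better than 1e-8
in all six free parameters (after gauge fixing), and parameter errors
scale linearly with small Gaussian noise added to the reference
energies.

## Problem sizes and costs

The shipped validation and acceptance runs use the study sizes directly:
10 even-tempered s functions per atom, so 20 orbitals for the dimer and
30 for the trimer. The largest FCI block (trimer, N = 3, Sz = 1/2) has
13 050 determinants; one full trimer reference takes tens of seconds on
one core with the Davidson solver, and the complete two-stage fitting
protocol at two distances runs in a few minutes. Model-side FCI blocks
have at most 9 determinants and are always dense.

## What the internal reference does and does not show

The internal oracle reproduces the structure of the study — sector-
resolved, spin-labelled FCI targets for two clusters per distance — at
reduced one-particle quality: the basis is s-only, so the reference
lacks angular correlation (the H2 ground state at 1.4 bohr is ~0.02
hartree above the exact value). Conclusions that survive this reduction
are structural: the task combinatorics, exact charge conservation, the
NDDO limit, parameter recoverability, and the failure of the fitted
minimal-basis model to reach chemical accuracy (0.0016 hartree) at
short separations. Absolute parameter values and RMS magnitudes would
shift under a higher-quality reference; the external-adapter hook
exists for exactly that substitution.

## Known limitations

* Shipped parameter handling covers s and p shells; the rotation and
  table machinery is l-generic but d and higher shells are untested
  beyond orthogonality properties.
* No periodic boundary conditions or Ewald-type electrostatics.
* Three-center density fitting (auxiliaries on a third atom) is out of
  scope by construction.
* The FCI solver targets few-electron blocks (≤ 3 electrons, ≤ 40
  orbitals); it has no symmetry adaptation and no excited-state-specific
  preconditioning beyond the Davidson defaults.
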