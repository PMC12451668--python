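# sqmkit

Model-Hamiltonian machinery for semiempirical quantum mechanics (SQM),
exercised end to end on minimal-basis hydrogen clusters.

Semiempirical models replace expensive *ab initio* integrals with
parameterized matrix elements. Two structures make that possible and are
implemented here in full generality:

1. **Slater–Koster two-center matrix elements.** Any rotationally
   invariant two-center integral factorizes into radial channels and
   real-spherical-harmonic rotation matrices,

       K_pq = Σ_{M=-L..L} R^l_{m,M}(u) K^{ττ'}_{|M|}(r) R^{l'}_{m',M}(u),

   with L = min(l, l′) and u the unit bond vector. `sqmkit.sk_core`
   provides the rotation recursion, spline/analytic radial channels with
   cutoff and tail rules, table symmetry completion
   (K_m^{ττ'} = (−1)^{l+l'} K_m^{τ'τ}), and full-matrix assembly.

2. **Charge-conserving, atom-local density fitting of four-center
   Coulomb integrals.** `sqmkit.coulomb_factor` builds
   V_pqrs ≈ Σ_{μν} X^μ_pq V_{μν} X^ν_rs with auxiliaries restricted to
   the atoms of p and q and the electronic charge conserved exactly,
   Σ_μ X^μ_pq Q_μ = S_pq. With orthogonal orbitals the factorization
   reduces exactly to the NDDO approximation; unlike NDDO it is
   systematically improvable by enlarging the primary and auxiliary
   spaces.

The worked example is the 7-parameter hydrogen model: one s primary and
one s auxiliary per atom, one-center parameters (ε, U) with ε fixed at
the exact atomic value −1/2, and five two-center parameters
(S, H, V_ee, V_eH, V_HH) per interatomic distance. Electron correlation
is treated exactly by sector-resolved full configuration interaction
(`sqmkit.mb_solver`), reference data come from an internal even-tempered
10s-per-atom FCI oracle (`sqmkit.gauss_oracle`), and the parameters are
fitted per distance to two task sets on the hydrogen dimer and the
symmetric linear trimer (`sqmkit.fitkit`): the 10 sector ground states,
or all 23 single-occupancy stationary states.

## Worked example

```python
from sqmkit import hmodel

params = hmodel.HModelParameters(U=0.62, S=0.35, H=-0.5,
                                 Vee=0.55, VeH=0.6, VHH=1.0)
geom = hmodel.HClusterGeometry("dimer", 1.4)
spectrum = hmodel.cluster_spectrum(geom, params)
print(spectrum.to_frame().to_string(index=False))
```

prints the model's single-occupancy states for H2 at 1.4 bohr — one
state per (electron count N, spin projection Sz ≥ 0) block up to that
block's single-occupancy dimension, as total energies including the
proton–proton term:

```
system  N  twoSz  index  energy_hartree s2_label
    H2  0      0      0        1.000000  singlet
    H2  1      1      0       -0.185185  doublet
    H2  1      1      1        0.076923  doublet
    H2  2      0      0       -0.788388  singlet
    H2  2      0      1       -0.563148  triplet
    H2  2      2      0       -0.563148  triplet
```

Reading it: the N = 0 entry is the bare proton repulsion V_HH = 1.0; the
two N = 1 doublets are the bonding/antibonding ion states; in the
neutral dimer the singlet lies below the triplet, whose Sz = 0 and
Sz = 1 components are degenerate — the FCI block structure and spin
labels coming out as they must.

The same objects drive the command line:

```sh
sqmkit counts --task 1        # -> 10 (ground-state targets, H2 + H3)
sqmkit counts --task 2        # -> 23 (single-occupancy states, H2 + H3)
sqmkit gen-ref --kind linear_trimer -r 1.4 --out ref_h3.csv
sqmkit fit --task 1 --rgrid 1.0:2.0:0.25 --seed 12345
sqmkit validate               # oracle-equivalence + sum-rule self-checks
```

## Layout

| module | contents |
| --- | --- |
| `sqmkit.sk_core` | rotation blocks, radial channels, two-center assembly |
| `sqmkit.coulomb_factor` | auxiliary metric, charge-conserving fit tensors, factored integrals, NDDO limit |
| `sqmkit.gauss_oracle` | closed-form Gaussian integrals, even-tempered FCI reference generator |
| `sqmkit.mb_solver` | determinant enumeration, direct-CI sigma, Davidson, spin labels, task combinatorics |
| `sqmkit.hmodel` | the 7-parameter hydrogen-cluster model |
| `sqmkit.fitkit` | task definitions, RMS objective, two-stage per-distance fitting protocol |
| `sqmkit.cli_io` | geometry/table/CSV formats, JSON run configs, the `sqmkit` CLI |

See `docs/methods.md` for the model conventions, numerical choices, and
what the internal reference does and does not demonstrate.
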