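# mrckit

Model Hamiltonians for nonadiabatic charge transfer (CT) and excitation
energy transfer (EET) in the condensed phase: the **multistate harmonic
(MSH) model**, its exact **multistate reaction coordinate (MRC)**
re-expression, and semiclassical trajectory dynamics on either.

## The problem

An F-state electronic system immersed in a condensed-phase environment has
F(F−1)/2 pairwise reorganization energies E_r^(XY) — more restrictions than
states — so a shared one-dimensional harmonic bath cannot satisfy them all,
and isolated-bath (Frenkel-exciton-type) models simply discard the
excited–excited correlations. The MSH model resolves this by extending each
of the N shared normal modes to F−1 spatial dimensions: the PES minima of
the F states become the vertices of a polyhedron in F−1 dimensions whose
squared edge lengths are the pairwise reorganization energies. Embedding
that polyhedron from a measured E_r matrix is a distance-geometry problem
solved through the Gram matrix anchored at state 1,

    G_XY = (E_r^(1X) + E_r^(1Y) − E_r^(XY)) / 2 ,   X, Y ≥ 2,

whose lower-triangular factor gives the vertex coordinates d_X.

The MSH model's delocalized normal modes lack a reaction coordinate. The
MRC construction supplies one exactly: in each subspace the unit direction
a_j ∝ ω_j² R_j^eq is mapped onto the first axis by a Householder reflection
P, the reflected Hessian K = PᵀΛP is block-diagonalized in its trailing
(N−1)×(N−1) block, and the result is a Caldeira–Leggett-form Hamiltonian —
one primary mode y per subspace with frequency

    Ω² = Σ_j ω_j⁴ (R_j^eq)² / Σ_j ω_j² (R_j^eq)²

(the Schur complement of K; the root-mean-square of the ω_j under
equal-reorganization discretization), bilinearly coupled to N−1 secondary
modes (ω_α, c_α). The primary coordinate carries the *entire*
reorganization energy of every state pair through shifts
S^(i,X) = √2·d_X[i]/Ω, and the transformation is exact: potentials, forces,
and trajectories agree with the MSH representation to machine precision.

Spectral densities enter through the classical energy-gap autocorrelation
conventions J(ω) = (βω/2)∫₀^∞ C(t)cos(ωt)dt, E_r = βC(0)/2, and are
discretized into N modes of equal reorganization share by solving
F(ω_j) = (j−½)/N · F(∞) for F(ω) = ∫₀^ω J/ω′ dω′.

Dynamics: Ehrenfest mean field and symmetrical quasi-classical (SQC)
triangle-window mapping dynamics, with Wigner-sampled harmonic initial
conditions, velocity-Verlet nuclei, and RK4 electronic propagation.

## Worked example

Build the packaged four-state molecular-triad model (π–π*, CT1, CT2,
ground; printed parameter table with a synthetic Debye stand-in bath,
N = 200 modes), transform it, and check the paired-trajectory equivalence:

```python
from mrckit import (SimConfig, equivalence_report, msh_to_mrc,
                    sqc_propagate, triad_fixture)
from mrckit.units import HARTREE_TO_CM1

model = triad_fixture("triad_conf3")          # 4 states, N=200 modes
mrc = msh_to_mrc(model)
print(f"total nuclear DOF: {model.n_dof}")
print(f"reaction-coordinate frequency Omega: "
      f"{mrc.omega_rc * HARTREE_TO_CM1:.2f} cm^-1")
print(f"Er(pi-pi*, CT1) from vertices: "
      f"{model.vertices.squared_distances()[0, 1] * 627.509474:.3f} kcal/mol")

cfg = SimConfig(method="sqc", dt_fs=0.1, t_final_fs=5.0, n_traj=1, seed=1,
                init_electronic=0, init_nuclear=3)
report = equivalence_report(model, mrc, cfg)
print(f"paired-trajectory agreement over 50 steps: "
      f">= {report.digits.min()} significant figures")
```

prints

```
total nuclear DOF: 600
reaction-coordinate frequency Omega: 410.53 cm^-1
Er(pi-pi*, CT1) from vertices: 7.880 kcal/mol
paired-trajectory agreement over 50 steps: >= 13 significant figures
```

— 600 = (F−1)×N nuclear degrees of freedom; the embedded vertex distance
reproduces the printed E_r^(12); and identical seeded trajectories on the
two representations agree far beyond visual coincidence (the difference is
double-precision roundoff, not the transformation). A short SQC ensemble on
the MRC model (200 trajectories, photoexcitation to π–π* with nuclei
equilibrated on the ground-state surface),

```python
cfg = SimConfig(method="sqc", dt_fs=0.1, t_final_fs=200.0, n_traj=200,
                seed=0, init_electronic=0, init_nuclear=3, output_stride=400)
trace = sqc_propagate(mrc, None, cfg)
```

shows the initial state decaying into both CT states within 0.2 ps
(populations π–π*, CT1, CT2, G):

```
t =    0.0 fs   populations: 1.000  0.000  0.000  0.000
t =   80.0 fs   populations: 0.667  0.216  0.118  0.000
t =  200.0 fs   populations: 0.667  0.256  0.077  0.000
```

`trace.rc_mean` carries the averaged reaction-coordinate trajectory
⟨y_i(t)⟩ — the nuclear picture of the same process. A `mrckit` console
script pipes model documents between `fixtures`, `discretize`, `build-msh`,
`to-mrc`, `to-msh`, `simulate`, and `equivalence` subcommands.

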