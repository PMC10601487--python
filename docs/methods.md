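# Methods

## Models

**MSH.** An F-state diabatic Hamiltonian H = Σ_X |X⟩(ε_X + H_n^(X))⟨X| +
Σ_{X≠Y} Γ_XY |X⟩⟨Y| on a shared bath of N normal modes, each extended to
F−1 spatial dimensions (subspaces i = 1..F−1, total nuclear DOF (F−1)N):

    V_X(R) = ε_X + Σ_{i,j} ½ ω_j² (R_{i,j} + S_j^(i,X))²,
    S_j^(i,X) = √(2/N) d_X[i] / ω_j,   S^(i,X) ≡ 0 for i ≥ X.

The vertices d_X ∈ R^(F−1) come from the Gram-matrix embedding of the
pairwise reorganization energies (lower-triangular factor, state 1 at the
origin, positive diagonal). Every mode then carries an equal share
E_r^(XY)/N of every pair's reorganization energy, and V_Y evaluated at
state X's minimum minus ε_Y equals E_r^(XY) identically.

**MRC.** Per subspace, the orthogonal map T = P·blockdiag(1, U) takes
normal-mode coordinates to (y, x_1..x_{N−1}): P is the Householder
reflection onto the reaction-coordinate direction a_j = ω_j²R_j^eq/κ, and U
diagonalizes the trailing block of K = PᵀΛP (Λ = diag ω_j²), giving
secondary frequencies ω_α and couplings c_α = (Uᵀd)_α, d = K[2:,1]. The
primary frequency is fixed by requiring the *relaxed* reaction coordinate
to carry the full reorganization energy,

    Ω² = Σ ω_j⁴(R_j^eq)² / Σ ω_j²(R_j^eq)²,

which algebraically equals the Schur complement K₁₁ − Σ_α c_α²/ω_α² of the
reflected Hessian. The potential is therefore written in completed-square
Caldeira–Leggett form (counterterm inside the bath square):

    V_X = ε_X + Σ_i [ ½Ω²(y_i + S^(i,X))²
          + Σ_α ½ω_α²(x_{i,α} + (c_α/ω_α²) y_i)² ],
    S^(i,X) = √2 d_X[i]/Ω.

This convention (`mrc.COUNTERTERM_IN_POTENTIAL`) makes the MSH↔MRC map
*exact*: potentials and gradients agree to roundoff under the coordinate
map, eigenvalues of the reconstructed per-subspace Hessian reproduce the
ω_j², and the correct trace identity is K₁₁ + Σω_α² = Σω_j² (note: not
Ω² + Σω_α², since K₁₁ = Ω² + Σc_α²/ω_α²). The eigenvector sign convention
(first nonzero component positive) and ascending ω_α ordering make the
transformation bit-reproducible; T is shared by all subspaces. A degenerate
direction (a within 1e−12 of e₁) returns the identity reflector. The sign
of c_α relative to d is representation-dependent; either choice is
physically equivalent, and the package fixes the one implied by the
sign-fixed U.

**Isolated-bath comparison.** `build_frenkel_model` gives each site its own
bath (total DOF F·N); excited–excited reorganization is then forced to
E_r^(Xg) + E_r^(Yg), which is exactly what the shared-bath models do *not*
assume.

## Spectral conventions

Centralized in `mrckit.spectral` (one-line change to adopt another
convention): J(ω) = (βω/2)∫₀^∞ C(t)cos(ωt)dt, E_r = βC(0)/2, hence
E_r = (2/π)∫₀^∞ J/ω dω. The Debye form is written
J = er·ω·ω_c/(ω² + ω_c²) so its `er` parameter *is* the reorganization
energy it carries; Ohmic is J = η·ω·e^(−ω/ω_c) with E_r = (2/π)η ω_c.
Discretization solves F(ω_j) = (j−½)/N·F(∞) (midpoint rule; j/(N+1)
available as `fraction="endpoint"`), with closed-form inversion for Ohmic
and Debye and monotone-interpolated inversion for tabulated input. Under
this rule Ω = rms(ω_j) exactly. The cosine transform of tabulated TCFs uses
trapezoidal quadrature on a 0–5000 cm⁻¹, 2048-point grid by default, with
an optional exponential damping window for series that have not decayed;
the window time constant is deliberately left configurable rather than
defaulted, since noisy inputs differ. Synthetic gap TCFs use the inverse
transform C(t) = (4/(πβ))∫(J/ω)cos(ωt)dω with C(0) pinned to the
closed-form reorganization integral, so TCF→J→E_r round trips close.

**Bath support.** All triad-scale synthetic Debye stand-in baths (packaged
fixtures and the random generator) truncate the discretization support at
1500 cm⁻¹. Molecular condensed-phase spectral densities have bounded
vibrational support (≲2000 cm⁻¹); the untruncated equal-share tan grid
would instead place its top modes near 5×10⁴ cm⁻¹, i.e. ω·dt ≈ 1 at the
0.1 fs nuclear step used throughout — an unphysical and numerically
under-resolved regime. The Leggett effective-density closed form is
implemented with the damping kernel Γ(ω) = 2J_b(ω)/ω implied by the
package's secondary-coupling convention c_α² = 2ω_α²·er_b/N and serves only
as a validation oracle for the two-state construction.

## Embedding degenerate or defective inputs

Gram eigenvalues below −tol·λ_max (default tol 1e−8) raise a hard error
with triangle-inequality diagnostics — no silent nearest-PSD projection.
`on_defect="clip"` instead clips negative Cholesky pivots with a warning.
This mode exists because reorganization matrices estimated from real,
anharmonic MD gap statistics need not be exactly Euclidean: the packaged
triad tables themselves carry a ~13% relative Gram defect through the
ground state (the printed E_r^(24) exceeds what the triangle inequality
through states 1 and 2 permits). Pivot clipping keeps all distances exact
among the states whose pivots stay positive — in particular the entire
excited-state triangle and the state-1/2 edge — while ground-state
distances absorb the defect. The anchor state is state 1; reordering states
changes coordinates but not physics.

## Dynamics

* Integrators: velocity-Verlet nuclei; RK4 electronic amplitudes with 20
  substeps per nuclear step (configurable) and the potential diagonal
  interpolated linearly across the step. The state-averaged potential is
  subtracted inside the electronic propagator — a pure global phase that
  leaves populations, coherences, and forces unchanged but removes the
  dominant stiffness (with it, a 1 ps mean-field run of the triad model at
  dt = 0.1 fs conserves total energy to ~4×10⁻⁶ hartree and the electronic
  norm to ~10⁻¹²).
* Default steps: 0.1 fs for triad-scale models, 1 fs appropriate for
  FMO-scale frequency ladders; both configurable.
* Ehrenfest mean field: force −Σ_XY ρ_YX ∇H_XY; under the Condon
  approximation the coupling gradients vanish, leaving the
  population-weighted diagonal forces.
* SQC: Meyer–Miller mapping variables with triangle windows. Initial
  actions are uniform over the occupied-state window {n_m ∈ (1,2),
  n_j ∈ (0,1), n_m + n_j < 2}; binning uses the same windows with ensemble
  renormalization; the zero-point parameter γ defaults to 1/3 and enters
  the force weights (n_X = |c_X|² − γ). These choices are standard but not
  uniquely determined by the sources this package follows; they are
  configurable and the MSH/MRC equivalence holds for any of them.
* Wigner sampling: per-mode Gaussians with position variance
  coth(βω/2)/(2ω) and momentum variance (ω/2)coth(βω/2), always drawn in
  the normal-mode basis and mapped through T for MRC targets, so paired
  MSH/MRC runs share bit-identical initial conditions. Trajectory k draws
  from `default_rng([seed, k])` and is reproducible independently of the
  ensemble size.
* Nonequilibrium starts: `init_nuclear` accepts a state index, a bare
  reaction-coordinate vector (secondary bath relaxed at that y), or a full
  explicit center.
* Populations are recorded every nuclear step by default (`output_stride`
  decimates); per-trajectory energy drift is monitored and excessive drift
  warns rather than aborts.
* The reaction free energy helper implements ΔE = ⟨U⟩ − E_r with the gap
  measured final-minus-initial on the initial surface ("forward"); the
  opposite sign convention is available as `direction="reverse"` because
  the gap-direction convention in the sources is ambiguous.

## Equivalence measurement

`equivalence_report` runs both representations with shared seeds and mapped
initial conditions and reports, per output step, the minimum over states
and trajectories of agreeing significant figures between the per-trajectory
electronic populations. On the triad-scale models this gives ≥13 figures
over the first tens of steps and 7–8 figures at 1 ps (10⁴ steps) — pure
double-precision roundoff divergence, since the two propagations perform
algebraically identical operations in rotated frames.

## What the synthetic data do and do not emulate

Generated reorganization matrices are squared distances of Gaussian point
clouds: always embeddable, with magnitudes (~10 kcal/mol) typical of CT in
polar solvents. The Debye stand-in bath reproduces the overdamped-solvent
envelope but not the discrete intramolecular peaks of MD-derived spectral
densities, and packaged triad electronic parameters are printed table
values, not recomputed ones. Passing tests therefore demonstrate the
mathematical correctness of construction, transformation, and propagation
— not the fidelity of any particular parameterization to a real molecule.
Semiclassical method *accuracy* is deliberately untested: only
representation equivalence and closed-form limits (Rabi oscillation,
uncoupled constancy, classical harmonic motion) are asserted.

## Numerical tolerances and limitations

* Embedding exactness for generated matrices: 1e−10 relative; shift/reorg
  consistency: 1e−8 relative; coordinate round trips: 1e−12.
* Hessian-eigenvalue round trips are compared at 1e−10 relative plus a
  spectral-scale floor of 1e−12·max(ω²): a double-precision symmetric
  eigensolve is backward stable to ~ε‖K‖, so the smallest eigenvalue of a
  three-decade bath cannot carry 1e−10 *relative* accuracy in principle.
* Test and acceptance problem sizes (N ≤ 200 modes, ensembles ≤ 3×10³,
  traces ≤ 1 ps) are chosen so the full suite completes in about a minute
  while still exercising the full triad-scale model shape (F=4, N=200,
  600 DOF); all quantities asserted are size-converged at those scales.
* Hierarchical (multi-layer) reaction-coordinate chains, effective-mode
  truncations, quantum-correction factors for classical TCFs, and the
  RI-LSC1/spin-mapping propagators are out of scope; the propagator
  interface (`potential_all`/`mean_force`) is the extension point.
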