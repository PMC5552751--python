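# Methods

This note records the models behind `egresslab`, the parameters that
matter, and the design decisions taken where the methodology leaves
choices open.

## Units and dynamics

Å, ps, kcal/mol, amu, K throughout; k_B = 0.0019872041 kcal/mol/K and
1 kcal/mol = 418.4 amu·Å²/ps².  Dynamics is Langevin in the BAOAB
splitting, chosen over a velocity-rescaling thermostat because it gives a
self-contained, exactly seedable NVT sampler with the same stationary
distribution.  The noise stream of every call is derived from
`(rng_seed, step_count)`, so trajectories are reproducible and successive
calls never reuse noise.  With friction = 0 the integrator reduces to
velocity Verlet (the energy-conservation tests rely on this).

The ligand is propagated as one rigid body: net force on the COM, net
torque about it, with an isotropic approximation to the inertia tensor
(mean moment).  For a compact, nearly spherical 5-atom ligand the
anisotropy correction is small, and orientational statistics are not a
target quantity of any analysis here.  Cage particles are independent
point particles.

Nonbonded terms act between ligand and environment atoms only
(Lennard-Jones 12-6 with Lorentz–Berthelot mixing, Coulomb with a
configurable dielectric, no cutoffs at these system sizes).  Pair
distances are clamped at 0.1 Å so overlaps give a large finite energy
with a warning, never NaN.  Restraints: harmonic position tethers
(default k = 10 kcal/mol/Å², a config default since no canonical value
exists for the tethered-site analog), a one-sided COM distance wall
(the analog of holding a ligand inside the protein matrix during biased
runs), and a CV upper wall applied by the biased-dynamics drivers.

## Fixtures

`make_double_well(b, a)` builds U(x) = b((x/a)²−1)²: minima at ±a,
barrier exactly b at x = 0.  The default benchmark (b = 4 kcal/mol,
a = 1 Å, particle mass 40 amu, friction 5 ps⁻¹, dt = 2 fs) has a ≈6.7 k_BT
barrier at 300 K — high enough that unbiased escape is rare on the test
timescale, low enough that metadynamics converges in seconds.

`make_cage_ligand` places `n_cage` Fibonacci-lattice points on a sphere
(default radius 10 Å), carves `n_tunnels` conical gaps (half-angle 30°,
pairwise-disjoint by construction; overlapping cones are a parameter
error), tethers the remaining atoms to their sites, puts an anchor atom
at the centre and a rigid tetrahedral 5-atom ligand at 0.3 R in a
seed-random direction at least 45° away from every tunnel axis (so the
search genuinely has to find the mouth).  The default lattice density
(n_cage = 110) makes the inter-atom slits impassable for the ligand at
the default pulling force, leaving the engineered mouths as the only
exits; at 80 points the soft wall can occasionally be squeezed through,
which shows up as spurious egress directions.  Cage LJ ε = 0.4 and
ligand ε = 0.25 kcal/mol set the wall stiffness; per-atom partial
volumes and solvation coefficients are 1.0 in the fixture so the
desolvation-like Λ term is active (the `AtomSpec` defaults are 1.0 and
0.0, i.e. opt-in).

`make_state_families` plants the clustering benchmark: "closed" frames
are the reference cage plus isotropic 0.3 Å noise, "open" frames
additionally push the atoms rimming the first tunnel mouth 3 Å radially
outward — a caricature of a gate opening, with a single deterministic
displacement direction per atom.

What the fixtures do **not** emulate: conformational coupling between
ligand and host beyond harmonic site relaxation, solvent friction
anisotropy, electrostatics (fixture charges are zero), or any secondary
structure.  Passing tests therefore demonstrate the correctness and
internal consistency of the machinery, not biological realism.

## Path search

The functional Λ (Gaussian desolvation-like term, width w, plus the
optional vdW+electrostatic γ) is evaluated over ligand × environment
pairs; the published form sums i < j but indexes i over ligand and j
over environment atoms, and the pair interpretation is the one
implemented.  Defaults: w = 3.5 Å (solvation-shell scale), sampling
sphere ρ = 2 Å, 16 candidates, ≤15° orientation perturbations, uniform-
in-volume COM sampling.  "Memetic" is instantiated as
best-of-candidates plus a deterministic coordinate-wise trust-region
descent on the six rigid-body coordinates — testable against an
exhaustive grid oracle, unlike a stochastic genetic loop.

Two structural facts about Λ on a closed cavity drive the build loop:
the functional has a local minimum *inside* the cavity (every direction
toward the shell raises contact density), and its global minimum lies
outside.  Minimization alone therefore never escapes.  `build_path`
adds a monotonic egress constraint — each target pose must increase the
ligand-COM distance from the cage centre by ≥ 0.1 ρ — so Λ chooses
*where* to cross the boundary while the constraint enforces *that* it is
crossed.  When the outward-best Λ rises more than 10 kcal/mol above the
current pose (pressed into the repulsive wall), the node instead takes a
tangential slide (non-decreasing radius), letting the search follow the
inner surface to the mouth.  If the node budget is exhausted the search
restarts from the bound state with a fresh proposal stream (≤2
restarts), the usual remedy for a local search trapped in a surface
dimple.  The pulling bias is a constant-magnitude (default
6 kcal/mol/Å) mass-distributed COM force toward the target, re-evaluated
every force call, plus a weak orienting torque; zero separation defines
a zero bias direction.

Raw search paths linger and loop while the ligand hunts along the inner
surface, so `reparameterize_path` first shortcut-prunes the polyline
(from each node, jump to the last later node within twice the median
consecutive spacing), applies a 3-node moving average to the interior,
then resamples to equal displacement-set arc length with endpoints
preserved exactly.  On the cage this yields near-uniform node MSDs and a
strictly increasing s along the nodes.

## Path collective variables

MSDs use Kabsch superposition (proper rotation via SVD with determinant
correction) on the alignment set, averaged over the displacement set.
Both sets are disjoint by construction (cage/protein vs ligand), which
makes the fixed-rotation gradients with respect to displacement atoms
*exact*, not approximate: the optimal rotation and translation depend
only on alignment atoms.  Gradients with respect to alignment atoms are
not needed for the bias forces used here and are not provided
analytically.  s and z are computed with log-sum-exp shifts so λ·MSD
products of hundreds do not overflow; when all MSDs are equal,
s = (N+1)/2 falls out of the formula.

λ defaults to 2.3/⟨MSD⟩ between consecutive nodes, the standard
heuristic making e^{−λ·MSD} ≈ 0.1 at one node spacing.  For reference
paths with node spacings of 13–14.4 Å² this rule gives λ ≈ 0.16–0.18 Å⁻²,
matching values used in production path-CV work at that spacing; it is a
default, not a law — published λ values for some paths (e.g. 0.36 at
16.31 Å² spacing) do not follow it, so the user override is always
respected verbatim.

## Well-tempered metadynamics

Kernels deposit every 0.25 ps with initial height 0.48 kcal/mol
(rate 1.92 kcal/mol/ps) and height damping exp(−V/k_BΔT) evaluated
before deposition; T = 300 K, ΔT = 3300 K (bias factor 12).  Adaptive
widths follow the time-domain scheme: the standard deviation of the CV
over a trailing 0.25 ps window, floored (0.02 in x on the double well,
0.05 in s on the path) to avoid spike kernels.  The 1D driver keeps the
bias and its derivative on a grid (default 1001 points over [−2.5, 2.5])
updated analytically at each deposit, with a numba inner loop; 5·10⁶
steps take seconds.  The path-CV driver applies bias forces through the
chain rule dV/ds·∂s/∂x + dW/dz·∂z/∂x and deposits on s only; the z wall
is one-sided harmonic with κ = 200 kcal/mol/Å⁴, placed 0.5 Å² *inside*
the stated z limit so the thermal penetration depth √(2k_BT/κ) ≈ 0.08 Å²
cannot carry the system past the constraint itself.

Free energy: F = −((T+ΔT)/ΔT)·V on the grid, shifted to min F = 0.  The
c(t) quadrature uses trapezoid weights with log-sum-exp stabilization;
frame weights exp(β(V(s_t,t) − c(t))) include exactly the kernels
deposited before each frame (one chronological pass over a cumulative
bias grid).  `reweighted_histogram` discards the leading 20% of frames
by default: before the bias first saturates a basin the trajectory is
far from the quasi-stationary regime the estimator assumes, and those
frames otherwise dominate the weights.  With the transient discarded the
reweighted double-well density matches the analytic Boltzmann density to
L1 ≈ 0.05.

Convergence diagnostics: the residual height fraction is the mean height
of the final 5% of kernels over h₀ (the tail window is a choice; no
canonical definition exists), with < 1% the conventional convergence
mark; block standard errors come from estimator snapshots at checkpoints
over the second half of the deposition history, each mean-centred to
remove the arbitrary offset.  On the converged double-well run the mean
block SE is ≈ 0.18 kcal/mol and the recovered barrier is within
0.05 kcal/mol of the analytic 4.0 (tolerance in the tests: 0.5 over
three seeds).

## State decomposition

Classical (Torgerson) MDS — double-centred squared-distance matrix,
top-2 eigenpairs, negative eigenvalues clipped — was chosen over
stress-minimizing variants because it is deterministic and
oracle-checkable (it reconstructs planted 2-D configurations to
stress < 10⁻⁶).  Clustering runs on the raw eigenvalue-scaled embedding:
min–max normalization to the unit square (the convention basin centres
are quoted in, and what `StateDecomposition.embedding` reports) would
inflate near-degenerate noise axes and break density estimates.  DBSCAN
eps defaults to 3× the median distance to the min_pts-th neighbour
(min_pts = 5) — above the intra-basin scale, below typical basin
separations — and is always overridable.  Medoids minimize summed
within-cluster RMSD with ties to the lowest frame index; external
structures are assigned to the basin of their nearest non-noise frame.

## Problem sizes

Defaults used by the test suite and the demo: 5·10⁶-step double-well
metadynamics runs (≈40 000 kernels), 3·10⁶-step runs for the three-seed
barrier recovery, 3000-step path-CV metadynamics on a 110-atom cage with
a 10-node path, five-seed egress sweeps, and 100-frame clustering
mixtures.  These sizes were chosen so each property is measured well
inside its stochastic tolerance while the whole suite stays
interactive-fast.

## Known limitations

- The isotropic-inertia rigid-body integrator is not a symplectic
  rigid-body scheme; it is adequate for thermalized sampling but not for
  microcanonical rotational dynamics.
- Λ-functional gradients are not exposed; the minimizer is derivative-free
  by design.
- The z wall acts on z while Gaussians act on s only; nothing prevents
  a path whose tube (z < limit) contains off-path metastability from
  mixing slowly.
- `reparameterize_path` interpolates conformations linearly between
  surviving nodes; for strongly curved paths in coordinate space the
  interpolated nodes are not themselves physical minima.
- DBSCAN parameter defaults are heuristics; for production analyses they
  should be chosen from the k-distance plot of the actual data.
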