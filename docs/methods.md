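# Methods

This note records the models, conventions and numerical choices behind each
module, what the synthetic fixtures do and do not emulate, and the known
limitations.

## Units

Everything internal is in Hartree atomic units: bohr, hartree, electron
masses, atomic time units.  Reporting converts with
1 hartree = 219474.6313632 cm^-1 and 1 amu = 1822.888486 m_e.  XYZ files
are Angstrom by convention unless the comment line says "bohr" or the
caller overrides; the plain-text dataset format is always bohr/hartree.
Atomic masses default to the most abundant isotope and can be overridden
per geometry.

## Symmetry and the PIP basis

A symmetry string such as `A5B2` declares classes of interchangeable atoms;
the symmetry group is the direct product of symmetric groups on the classes
(S5 × S2, order 240, for A5B2).  Atoms are numbered class-by-class and
pairs (i, j), i < j, lexicographically, which induces a permutation action
on the N(N−1)/2 pair variables.  The induced action is a homomorphic image
of the atom group: it is stored with exactly `group_order` elements,
including any repeats (for A2 both atom permutations fix the single pair).

A basis polynomial is the sum of the *distinct* monomials in one orbit of
the pair-permutation group (coefficients 1), which makes it exactly
invariant under every group element.  Exactness is integer bookkeeping, not
floating point; float evaluation then agrees under permutation to roundoff
(~1e-15 relative in practice, tested at 1e-12).

**Constant-term convention.**  The degree-0 constant polynomial is counted
as the first basis member.  This is the counting convention of the MSA
lineage of PIP software: with it, the A5B2 cumulative counts at orders
3–7 are 59, 218, 772, 2651, 8717; without it each count drops by one.  The
fitting layer therefore needs no separate intercept (one remains available
as an option, default off).  A corollary: a single-pair system `A1B1` at
order d has basis {1, y, …, y^d}, size d + 1.

**Enumeration.**  All C(n_var + M, M) exponent vectors of degree ≤ M are
generated; each is mapped to its canonical representative — the
lexicographically maximal exponent vector over the group orbit — by packing
vectors into base-(M+1) unsigned 64-bit keys (exact whenever
(M+1)^n_var ≤ 2^63, which covers A5B2 up to order 7; a big-integer fallback
handles anything wider).  Orbits are distinct canonical keys; polynomials
are ordered by total degree, then by canonical key.  A configurable
monomial cap (default 5·10^6) turns combinatorially infeasible requests
into an explicit `BasisResourceError`.  The A5B2 order-7 enumeration
(1,184,040 monomials, 8717 orbits) takes ~25 s on one CPU.

**Counting oracle.**  `count_invariants` computes per-degree orbit counts
with no enumeration: for each group element with pair-cycle lengths
l_1..l_k, the fixed monomials are generated by Π 1/(1 − t^l); averaging the
truncated series over the group (exact integer arithmetic) gives the orbit
count per degree.  Enumeration and counting are independent routes and are
cross-checked in the tests and in the acceptance script.

**Basis storage and evaluation.**  A basis is a flat array of monomial
exponent rows, an integer coefficient per row, and a row→polynomial index.
Evaluation works in log-Morse space: monomial values are exp(E · ln y) with
ln y = −r/a computed directly from distances (no cancellation, no
underflow-division), followed by a sparse scatter-sum onto polynomials.
Serialization stores orbit polynomials by their canonical representative
(the orbit is rebuilt from the group on load) and product-augmented
polynomials explicitly; files carry a format-version field and unknown
versions are rejected.

## Morse variables

y_ij = exp(−r_ij/a) maps [0, ∞) into (0, 1], with a = 3.0 bohr by default
(the range parameter used for the Zundel-cation fits).  Large separations
saturate to y → 0, which is what makes polynomial bases in y
dissociation-friendly.

## Gradients

Three routes, kept deliberately independent so they can cross-check each
other:

* **forward** — for each of the 3N Cartesian coordinates, a directional
  derivative through y(r(x)) (one monomial-matrix product per coordinate);
  total cost ∝ 3N energy calls.
* **reverse** — one forward evaluation records the monomial values; one
  backward sweep accumulates adjoints polynomials → monomials → Morse
  variables → distances → Cartesians.  Adjoints are accumulated in
  log-Morse space (dV/d ln y_k = y_k dV/dy_k), equivalent to the chain rule
  through dy/dr = −y/a but finite even where y underflows at 100+ bohr
  separations.  Operation counts derived from the array shapes put the full
  reverse gradient at ≈2.2× one energy call, independent of N, consistent
  with the 3–4× bound usually quoted for reverse differentiation of PIP
  graphs (verified as an op-count bound in the tests, not wall-clock).
* **finite differences** — central differences, step 1e-4 bohr, used only
  as an oracle.

Coincident atoms (r < 1e-8 bohr) raise an explicit error rather than
returning NaN: dr/dx is undefined there.  The Hessian is central finite
differences of reverse gradients (default step 1e-3 bohr), symmetrized as
(H + Hᵀ)/2.

## Fitting

The design matrix holds every basis polynomial at every training geometry.
Weights w(E) = Δ/(E + Δ), Δ = 0.1 hartree by default, with E the energy
above the dataset minimum (a supplied reference energy can override the
minimum).  The weighted problem is solved by SVD least squares
(`numpy.linalg.lstsq`, relative rcond 1e-12); rank deficiency is reported
with the effective rank, and under-determined systems return the
minimum-norm solution with a warning.  Normal equations are never used in
the implementation — they appear only in a test as the independent solver
cross-check.

Metrics: RMSE and MAE in cm^-1; weighted RMSE defined as
sqrt(Σ w r² / Σ w) so that uniform weights reduce it to the RMSE; R² =
1 − SS_res/SS_tot about the dataset mean.

**Augmentation.**  Since the product of two PIPs is a PIP, candidate
functions are pairwise products of basis polynomials with total degree
≤ (base order + 1) by default (the cap is configurable; the exact candidate
pool used to build production "6+"-type bases is not standardized, so the
augmented basis size is treated as a design choice, not a target).
Candidates are deduplicated by canonical polynomial form and ranked by
their maximum absolute value over the training geometries — Morse variables
grow as atoms approach, so large values single out the close-pair terms
that matter most — and the top candidates are appended.

## Diffusion Monte Carlo

Standard unbiased (unweighted-walker) protocol: diffuse each degree of
freedom by Gaussian noise of σ = sqrt(dt/m); branch with
n = floor(exp(−(V − E_ref) dt) + u), capped at 3 replicas; update
E_ref = ⟨V⟩ − α (N − N_target)/N_target over the post-branching ensemble
with α = 1/dt.  The replication cap and the feedback constant are not
uniquely fixed by the standard protocol, so the conventional choices are
adopted and both are exposed in `DmcConfig`.  Walkers start
exactly at the supplied minimum geometry, not thermally spread.
Per-trajectory ZPE is the post-equilibration mean of E_ref minus the
potential minimum; the reported uncertainty is the standard deviation of
the ZPE across replicate trajectories, which are seeded by spawning
independent streams from the master seed.  Production-scale defaults are
30,000 walkers × 55,000 steps (5,000 equilibration) × 10 trajectories at
dt = 5 a.u.; the test suite uses 2,000 × 20,000 × 5, which resolves the
analytic oscillator ZPEs to a few cm^-1.

Known systematics at finite dt: the branching scheme carries an O(dt) bias
(≈ −3 cm^-1 at dt = 20 for a 1097 cm^-1 harmonic ZPE, halving with dt —
this scaling is itself a test).  A 1.5 cm^-1 floor is added to the 3σ
acceptance band in the oscillator tests to cover the residual dt = 5 bias,
which is of that order.

The hole scan flags any walker whose potential drops below the known
minimum by more than a tolerance (default 10 cm^-1), recording the
offending geometries — the standard screen for unphysical pockets in a
fitted surface.

## Stationary points and frequencies

BFGS on Cartesians with analytic (reverse) gradients; convergence is
declared only when max |g| meets the requested gtol (default 1e-8
hartree/bohr), otherwise a `ConvergenceError` reports the last gradient
norm.  Saddle search is out of scope: saddle geometries must be supplied.
Normal modes are eigenpairs of the mass-weighted Hessian; frequencies are
sign(λ)√|λ| in cm^-1, so saddle directions appear as negative entries.
Near-zero modes (|ν| < 5 cm^-1) are counted but not projected out; the
`vibrational` accessor drops them for comparisons.  Frequency MAE between
two surfaces is the mean absolute difference of equal-length sorted lists.

## Minimum-energy paths

Velocity Verlet with analytic gradients.  Each step the velocities are
rescaled by sqrt(1 − loss) — "losing a fraction of the kinetic energy per
step" — and, after the loss, by sqrt(brake_factor) whenever the KE exceeds
the brake threshold.  Default parameters are the production outer-path
settings: 12 cm^-1 initial KE, dt = 5 a.u., 0.01% loss/step, brake at
100 cm^-1 halving the KE.  The initial KE is placed in the relative motion
of the designated reaction-coordinate pair (closing by default); the
trajectory terminates when the KE and the gradient norm fall below
tolerances.  The relaxed profile is the minimum energy per reaction-
coordinate bin (default width 0.05 bohr), recorded at the coordinate of the
minimum-energy sample rather than the bin center.  Overlapping paths merge
by re-binning; the maximum interpolated energy disagreement over the shared
range is reported.  The dissociation energy D_e is the mean energy of the
last bins minus the path minimum, accepted only if the tail slope is below
a tolerance (default 0.5 cm^-1/bohr) — otherwise the caller is told to
extend the path.

## Synthetic fixtures

The Morse-sum potential V = Σ_pairs De[(1 − e^{−a(r−r_e)})² − 1] with
parameters shared per pair class is exactly permutationally invariant, has
analytic gradients, a bound minimum and smooth dissociation — the
structural features the pipeline assumes of an ab initio training set.  The
dataset sampler draws Gaussian displacements about the optimized minimum
plus jittered configurations with a designated pair stretched along a
ladder of separations from 4 out to 300 bohr, mimicking how production
training sets cover dissociation, then discards energies above a cap.
Defaults: 0.35 bohr displacement scale, 3 geometries per stretch distance,
seeded and fully deterministic.

What the fixtures do **not** emulate: ab initio noise and method error,
electronic structure near bond breaking (a Morse sum is separable by
construction), many-body terms beyond pairs, and the sheer scale of a
48k-point training set.  Passing tests therefore demonstrate the machinery
— exact symmetry, correct linear algebra, correct gradient calculus,
convergent DMC and MEP protocols — not the physical accuracy any particular
fit would achieve on real data.  Toy systems are kept small (A2B1, A3,
A1B1) so order-4/5 bases stay at tens of terms and the full pipeline runs
in seconds.

## Problem sizes used in the tests

Basis work is exercised up to the full A5B2 order-7 enumeration (1.18M
monomials).  Gradient/invariance suites use an order-3 A5B2 basis (2,023
monomials, 59 polynomials) with random coefficients — the symmetry and
calculus being tested are order-independent.  DMC tests use 2,000 walkers ×
20,000 steps × 5 trajectories; MEP tests use the analytic Morse diatomic
with the production annealing parameters.

## Known limitations

* Purified (dissociation-factored) bases are not implemented; augmentation
  covers only products of existing PIPs.
* No fitting to gradient data; energies only.
* DMC has no importance sampling or trial wavefunction; excited states are
  out of scope.
* The optimizer handles minima only; transition states must be located
  elsewhere and supplied as geometries.
* Pair ordering, polynomial ordering and serialization formats are
  package-specific conventions; coefficient files from other PIP codes are
  not interchangeable.
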