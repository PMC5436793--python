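# Methods

This note records the models, numerical choices and design decisions behind
`mfepath`, and what the synthetic study conditions do and do not show.

## CV space and geometry

Collective variables are scalar functions of Cartesian coordinates:
interatomic distance (Å), IUPAC signed dihedral (radians, stored wrapped
into (−π, π]), the smooth hydrogen-bond count nHB = Σᵢ 1/(1+(d/d₀)⁶) with
reference length d₀ (3.5 Å by convention for backbone O···H bonds), and a
raw Cartesian component used by the toy particle systems.  All gradients
are analytic and are property-tested against central finite differences at
1e−5 relative tolerance.

Displacements between CV points wrap periodic components to the shortest
arc; the CV-space norm is plain Euclidean on the wrapped displacement,
deliberately mixing radians and Ångström without rescaling — step sizes
(s_g, s_op) are therefore in these mixed native units.  An optional per-CV
weight vector exists for users who want rescaled axes; it defaults to ones
and is used nowhere else in the package.

Hydrogen-bond distances are measured acceptor-oxygen to amide-hydrogen,
matching the usual ≤2.5 Å formation criterion for such bonds.

## Paths

A path is m snapshots, reactant anchored always, product anchored once the
path is complete.  The continuous curve behind arc-length operations is a
cubic spline through the snapshots parametrized by cumulative chord length
(piecewise linear below m = 4).  Not-a-knot end conditions are used rather
than natural ones: natural ends force zero curvature at the anchors and
bias Simpson arc lengths by ~1e−5 relative, an order above the refinement
stability the rest of the pipeline assumes.

Arc length integrates |dχ/dt| per segment by composite Simpson's rule with
a fixed 16 subdivisions — converged for smooth paths at the snapshot
densities used here (≈40 snapshots over ≈4 CV units).  Reparametrization
inverts a dense (64 samples/segment) cumulative arc-length table and moves
snapshots to equal fractions ξᵢ = (i−1)/(m−1) on the same curve; it is a
fixed point on even paths, idempotent to ~1e−6, and leaves endpoints
untouched by construction.  ξ is arc-length fraction, not index fraction;
the two agree after reparametrization, which is when profiles are reported.

Tangents are central differences of neighbouring snapshots (one-sided at
the ends), wrapped and normalized.

## Growth

Growth appends snapshots at arc step s_g along the normalized blend of
−∇F at the end and w times the unit pull toward the product.  The raw blend
is *not* normalized in its plain reading; we normalize it so that s_g is
the realized geometric step, which keeps the termination test
|χ_end − χ⁽ᵖ⁾| < s_g and the snapshot count consistent (a
`raw_direction` switch restores the literal blend).  When the end comes
within s_g of the product (with 1e−9 relative slack so an exact multiple
cannot land a duplicate snapshot on the product), the product is appended
and the path completes.

After each growth event the path is reparametrized and relaxed by
(default) two fixed-step perpendicular-descent sweeps over *all* current
snapshots including the newest — that inclusion is what makes the driver's
gradient-evaluation count match the k·Σᵢ₌₁..m i accounting of the growing
budget.  The gradient at the growing end is reused from the last sweep
rather than re-evaluated, again matching the accounting; after the product
is appended the complete path is relaxed once more (its share of the
ledger).  A degenerate growing direction (gradient exactly cancelling the
pull, norm < 1e−12) aborts with a diagnostic rather than applying a random
kick — reproducibility over robustness.

## Optimization

All optimizers move non-anchor snapshots along P_op = −∇F + (∇F·s)s (the
identity-metric perpendicular force; the full metric-tensor variant is out
of scope, the GradientField interface leaves room for it), then
reparametrize.  Within one sweep each snapshot's gradient is evaluated
exactly once; the ledger counts evaluations, which is what constrained-MD
time accounting counts.

* **sd_fixed** — χ ← χ + s_op·P_op.
* **sd_variable** — the step-size rule is implemented exactly as published:
  if the sum of snapshot free energies *decreased* since the last
  iteration the step is halved, otherwise reset to its initial value.
  That rule is unusual (it relaxes the step on failure); a
  `variable_inverted` flag provides the conventional halve-on-increase
  rule, but the published form is the default and the intent is not
  guessed.  The rule needs free-energy values, so this method requires a
  gradient source with `has_value`.
* **quasi_newton** — limited-memory BFGS (depth 5, a standard default) on
  the stacked n·m vector with −P_op in the gradient slot; the proposal is
  applied fractionally, χ ← χ + s_step·(χ_bfgs − χ), then the path is
  smoothed and reparametrized.  Curvature pairs with s·y ≤ 0 are skipped;
  a non-descent proposal falls back to one sd sweep (logged).  On the
  first iteration the recursion is exactly a scaled sd step.

**Smoothing.**  The angle objective f = Σᵢ(θᵢ − π)² over interior vertices
is reduced by steepest descent (default 1000 steps of 1e−4, with
monotonicity guarded by per-step backtracking; terms with undefined angle
derivative at folded vertices are skipped).  Its role is to keep aggressive
early quasi-Newton proposals from kinking the path.  Held at full strength
near convergence it instead *balances* the perpendicular force: on the
bundled fixture the equilibrium sits ≈0.02 CV units off the true minimum
path in the curved saddle region, and more iterations do not help.  The
quasi-Newton sweep therefore tapers the smoothing step size proportionally
to σ⊥ once σ⊥ falls below 25% of its initial value — full published
strength early, vanishing bias at convergence.  With the taper all four
standard runs (sd and quasi-Newton from both the straight and the grown
start) converge to within 0.007 CV units of the brute-force
steepest-descent oracle.

**Convergence metric.**  σ⊥ = √(Σᵢ P_op(i)·P_op(i)/(n·m)), an RMS
perpendicular gradient per CV dimension — dimensionally a gradient
magnitude, which is what "average size of the perpendicular free energy
gradients" should be.  The rootless mean-of-squares reading is available
behind `squared=True`.  Default stopping: σ⊥ below 5% of its initial
value, or an absolute threshold, or max iterations.

On the fixture the straight path's σ⊥ *rises* for the first ~45 sd
iterations before falling: the initial snapshots sit near the barrier crest
where the gradient is small, and move across the steep flank on their way
into the valley.  The trace is strictly monotone after that geometric
transient.

## Constrained dynamics (toy systems)

The estimator exists to validate the statistics of the mean-force route,
not to be a molecular-dynamics engine: point particles (amu masses) in
analytic potentials (harmonic wells, quartic double wells, bilinear-
quadratic couplings, sums thereof), integrated by Beeman's algorithm at a
1 fs step (velocity Verlet behind a switch — equilibrium results do not
depend on the integrator), thermostatted by Berendsen velocity rescaling,
with the CVs held fixed by a coupled matrix-SHAKE Newton iteration each
step (tolerance 1e−8 in CV units) and velocity components along the
constraint gradients projected out.  Initial coordinates are relaxed onto
the constraint manifold by damped Gauss–Newton descent before dynamics
begin.  Equilibration defaults to 20% of the production length and is
discarded before averaging.  Runs are bit-reproducible given the seed (the
only randomness is the Maxwell–Boltzmann velocity draw).

**Multiplier extraction and sign.**  SHAKE solves a displacement problem;
the mean force is a force.  Forces enter the position update of both
integrators with coefficient dt²/2 (exactly for velocity Verlet, in the
stationary mean for Beeman's (4aₜ − aₜ₋₁)/6), so
λ = γ_SHAKE/(0.5·dt²·c) with c the kcal/mol→amu·Å/fs² conversion.  The
sign convention is fixed so that ⟨λ⟩ = +∂F/∂χ; on a separable harmonic
well the multiplier is k(χ − χ₀) *exactly at every step* (no thermal
noise), which the tests exploit as a machine-precision oracle.

**Thermostat coupling.**  The Berendsen coupling time defaults to 1 ps,
above the oscillation periods of the toy systems.  Tight coupling
(τ ≈ 100 fs) is standard for large systems but measurably distorts
few-degree-of-freedom toys — rescaling pumps energy near turning points and
biased the coupled-bath amplitude statistics ~5% high in calibration runs;
at τ = 1 ps the canonical closed form is recovered within statistical
error.  (For fully constrained systems the thermostat is inert.)

**Fluctuating-multiplier fixture.**  A single constrained particle coupled
to a five-oscillator harmonic bath (spread spring constants 1.6–3.2
kcal/mol/Ų so the modes dephase) through g·x·zᵢ² terms.  Closed form:
⟨λ_x⟩ = k·c_x + g·Σᵢ k_BT/(kᵢ + 2g·c_x).  A single free oscillator cannot
thermalize under deterministic rescaling (its turning points are
coherent); the bath design is what makes the canonical average reachable.

**Correction term.**  Z_αβ = Σᵢ (1/mᵢ)(∂σ_α/∂xᵢ)(∂σ_β/∂xᵢ); the endpoint
correction is −k_BT ln⟨|Z|^(−1/2)⟩ with k_B = 0.0019872041 kcal/(mol·K).
Linearly dependent CV gradients are flagged (determinant may legitimately
be small), not raised.  On the toys the correction difference is zero or
small against the TI term, consistent with treating the multiplier alone
as the gradient during optimization while keeping both terms in profiles.

## Profiles

F(ξ) integrates the tangential projection g·s of the per-snapshot
gradients with respect to arc length, using the same central-difference
tangent operator as the optimizers (so at convergence, where P_op ≈ 0, the
projection captures the full gradient).  The default quadrature fits a
cubic spline to the nodal integrand in arc length and integrates it
exactly; plain trapezoid on the snapshot grid is available.  The switch
matters: at m = 40 on the fixture, trapezoid carries an O(h²) bias of
0.3–2% of the end-to-end ΔF, while the spline quadrature reproduces the
closed-form ΔF to 0.02% and keeps the state-function property (two
converged paths agreeing, ΔF matching F(χ⁽ᵖ⁾) − F(χ⁽ʳ⁾)) comfortably
inside half a percent.  The endpoint correction difference is applied at
the product end; per-snapshot corrections, when available, are attributed
along ξ.  F(0) = 0 exactly.

## Synthetic study conditions

`ala_like_2d` is a sum of Gaussians plus a weak quartic confinement: a
6 kcal/mol reactant well and 4 kcal/mol product well about 4 CV units
apart (so the end-to-end ΔF is ≈1.8 kcal/mol), a 9 kcal/mol barrier offset
from the straight interband line, and a 1.5 kcal/mol intermediate valley
below it.  The geometry makes the straight interpolation cross the barrier
(max F ≈ 6.8 kcal/mol) while the optimal path curves through the valley
(saddle ≈ 0.45 kcal/mol) — the qualitative situation the growing method is
built for.  With s_g = 0.102 and w = 10 the grown path has ≈46 snapshots.
All parameters are fixed constants in `fixtures.py`; the minima are refined
numerically at import.  Nothing about the fixture is claimed to match any
real molecular surface — passing tests on it demonstrates the machinery
(growth geometry, optimizer convergence, state-function integration), not
force-field realism, solvent effects, sampling error of real mean forces,
or CV quality on real molecules.

The steepest-descent oracle used for equivalence checks shares no code
with the optimizers: the saddle is located by Newton root-finding on the
gradient (verified first-order by a finite-difference Hessian) and the
path is traced by adaptive RK45 integration of dχ/dt = −∇F in both
unstable directions.

## Problem sizes

Default validation runs use 40-snapshot paths, 3000-iteration steepest
descent or 200-iteration quasi-Newton on analytic surfaces, and 10
constrained points × 30 ps at 1 fs for mean-force recovery — sizes chosen
so the full validation cycle completes in minutes on one CPU while leaving
each statistical check several standard errors of headroom.

## Known limitations

* The metric tensor is assumed diagonal (identity) in the perpendicular
  force; no full-metric propagation.
* Single-ended growth only; no two-fragment merge, climbing/freezing
  variants, or swarm updates.
* Grid surfaces are inputs; nothing here builds them.  Bicubic
  interpolation is 2-D only; no extrapolation outside grid bounds.
* Berendsen rescaling yields correct averages but not canonical
  fluctuations; the toys are designed so the quantities under test are
  means.
* The variable-step rule as published can oscillate (it halves on
  improvement); it is provided as specified, with the conventional rule
  behind a flag.
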