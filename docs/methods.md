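# Methods

## Model

The package works with the generalized Lotka–Volterra (LV) system for
*m* interacting types,

    ṅᵢ = nᵢ (rᵢ + Σⱼ aᵢⱼ nⱼ),   i = 1..m,

with interaction matrix `A` (row = affected type, column = acting type;
entries carry units 1/(time·abundance)) and intrinsic growth rates `r`
(1/time). The same matrix, read as a payoff matrix, drives the
replicator dynamics ẋᵢ = xᵢ(fᵢ − f̄) with fᵢ = (Ax)ᵢ and f̄ = x·f.
The change of variables xᵢ = nᵢ/N, N = Σnᵢ turns the LV system into the
exactly equivalent coupled system

    ẋᵢ = xᵢ[(rᵢ − r̄) + N(fᵢ − f̄)],   Ṅ = N(r̄ + N f̄),

whose frequency part is a time-rescaled replicator flow precisely when
all rᵢ are equal (then rᵢ − r̄ ≡ 0 and the factor N only reparametrizes
time). `check_equivalence` makes this operational: it integrates the LV
system, then integrates the replicator field under the non-autonomous
time change ẋ = N(t)·x∘(f − f̄1) with N(t) interpolated from the dense
LV solution, and reports the maximum pointwise deviation between the
two frequency trajectories (declared equivalent below 1e−6 — comfortably
above integration error at the default tolerances, far below any real
dynamical discrepancy).

A frequency-dependent variant ṅᵢ = nᵢ(rᵢ + (Ax)ᵢ) is provided for the
case where interactions respond to composition rather than density.
Its frequency dynamics is the replicator flow of the *effective* payoff
fᵢ + rᵢ at unrescaled time, so only the rate differences matter; equal
rates again recover the replicator prediction, and a sufficient rate
gap overturns it. Note this variant has no density regulation: the
total abundance grows or decays exponentially at the attractor, and
integration stops if it collapses to zero.

## Two-type outcome classification

A two-type system is *bounded* when each type is self-limiting
(a₁₁, a₂₂ < 0) and a₁₂a₂₁ < a₁₁a₂₂. `is_bounded` implements exactly
this product condition. For the outcome classifier the operative
question is whether trajectories can actually diverge, which requires
either a non-self-limiting type or a strong double-positive mutualism
(a₁₂, a₂₁ > 0 with a₁₂a₂₁ ≥ a₁₁a₂₂): strong *competition* also violates
the product condition but remains dynamically bounded (it is the
classic bistability regime), so `classify_outcome` returns UNBOUNDED
only for genuinely divergent matrices. For every system produced by
the bundled random sampler the two notions coincide.

With both rates positive, the verdict follows two invasion margins:

- g₂ = a₂₁ − a₁₁·r₂/r₁  (type 2 grows when rare at type 1's
  single-species equilibrium n̂₁ = −r₁/a₁₁),
- g₁ = a₁₂ − a₂₂·r₁/r₂  (type 1 grows when rare at n̂₂ = −r₂/a₂₂).

Both positive → coexistence; both negative → bistability; exactly one
positive → dominance of the successful invader. The identity
sign(r₂ + a₂₁n̂₁) = sign(g₂) (multiply by −r₁/a₁₁ > 0) is what ties the
geometric "shifted boundary" picture to mutual invasibility, and fixes
the dominance direction unambiguously. At equal rates the margins
reduce to the classic game quadrants (dilemma/harmony ↔ dominance,
coexistence game ↔ coexistence, coordination ↔ bistability).

With r₁ > 0 ≥ r₂ only type 1 can persist alone; the single remaining
invasion condition r₂ + a₂₁n̂₁ > 0 separates coexistence from dominance
of type 1 (and symmetrically when the signs are swapped). With both
rates nonpositive, only joint extinction is possible in the bounded
region. A type with rᵢ = 0 cannot persist alone (ṅ = aᵢᵢn² < 0) and is
handled by the nonpositive branch, flagged degenerate.

Comparisons within 1e−9 of a boundary are flagged DEGENERATE rather
than silently classified: these loci have measure zero and their
dynamics (algebraic rather than exponential relaxation) is not
meaningfully captured by a discrete label.

`critical_r1` returns the threshold r₂·a₁₂/a₂₂ at which g₁ changes
sign — the minimal intrinsic growth advantage that converts dominance
of type 2 into coexistence. `achievable_outcomes` scans the rate plane
symbolically: for positive rates the outcome depends on ρ = r₁/r₂ only,
with sign changes at ρ₁ = a₁₁/a₂₁ (finite only for a₂₁ < 0) and
ρ₂ = a₁₂/a₂₂ (positive only for a₁₂ < 0); dominance of either type is
always reachable through the mixed-sign regimes and joint extinction
through negative rates. Each witness pair is re-verified through the
classifier before being returned.

## Equilibria and stability

Fixed points are enumerated by support (2^m subsets, capped at m = 10;
the analyses here use m ≤ 3): on each support the linear system
r + A·n = 0 is solved and kept if strictly positive. Stability labels
come from the eigenvalues of the full Jacobian
Jᵢₖ = δᵢₖ(rᵢ + (An)ᵢ) + nᵢaᵢₖ with tolerance 1e−8 on real parts:
STABLE (all < −tol), NEUTRAL (max within ±tol), SADDLE (mixed signs),
UNSTABLE otherwise. The tolerance is what classifies the symmetric
Rock–Paper–Scissors interior — a conjugate purely-imaginary pair plus
one strongly negative eigenvalue — as neutral under floating-point
error. Invasion fitness of type *i* against a resident equilibrium n̂
is the rare-type per-capita rate rᵢ + (A n̂)ᵢ.

## Numerical integration

All integrators use scipy's adaptive DOP853 with rtol 1e−10 and
atol 1e−12 by default. The tolerances are deliberately tight: the
neutral RPS orbits drift at looser settings, and the closed-orbit and
conserved-product checks (relative drift of x_R·x_P·x_S below 1e−6 over
t = 100) fail otherwise.

Two numerical-stability choices deserve note:

- **Simplex stabilization.** The replicator and coupled fields are
  evaluated at x/Σx. On the simplex this changes nothing; off it, the
  raw field makes the total Σx dynamically unstable whenever the mean
  payoff is negative (Σẋ = (1 − Σx)(x·f)), and integration errors then
  grow exponentially — observed as outright blow-up for the RPS matrix.
  With in-field normalization the sum defect is exactly stationary and
  stays at rounding level (< 1e−9 enforced).
- **Extinction floor and ceiling.** Abundances below 1e−9 are clamped
  to zero in returned samples only, never mid-step (mid-step clamping
  distorts trajectories that pass close to boundaries, as
  heteroclinic-like cycles do). Abundances crossing 1e6 terminate
  integration with an "unbounded" error carrying the crossing time, so
  divergent mutualisms are diagnosed rather than crashing the solver.

Steady states are detected where the derivative stays below 1e−8 (sup
norm) over a trailing 5-time-unit window, evaluated at the solver's own
step nodes: dense-output interpolants carry derivative wiggle of order
ten times the tolerance and would mask genuinely flat solutions.

## Stepwise assembly

The assembly engine enforces a strict separation of timescales
(introductions are rare): each type arrives alone, at inoculum 1e−6
(well above the 1e−9 extinction floor, small enough that invasion
fitness governs establishment; verdicts are insensitive across
1e−4…1e−8), into a community previously relaxed to a fixed point or a
sustained cycle. Relaxation integrates for 500 time units — far beyond
every transient in the systems studied here, whose relaxation rates are
of order one — and inspects the trailing 100 units: if every surviving
type stays above the floor and oscillates with non-decaying amplitude
(second-half amplitude at least half the first-half amplitude, relative
amplitude above 1e−3), the regime is a CYCLE; a quiescent end state is
a FIXED_POINT; an empty support is EXTINCT. If neither is detected the
horizon is doubled once, then the step is reported INDETERMINATE rather
than guessed. Invasion fitness is recorded against fixed-point
residents and as missing against cycling ones, where the rare-invader
linearization does not apply and establishment is decided by direct
simulation.

For the symmetric RPS community (α = 1.3) this machinery reproduces the
assembly contrast: at equal rates every pairwise subgame is a dominance
relation, all six introduction orders end with a single survivor, and
the three-type cycle cannot be assembled; with Rock sped up to
r_R = 2.5 the R+P pair becomes a coexistence pair (both pairwise
invasion margins positive), Scissors invades their equilibrium
(fitness 1 − 2.3·(20/169) + 0.3·(175/169) ≈ 1.04), and the full
community establishes. The assembled community converges to its
feasible interior equilibrium (0.5, 23/26, 3/26), which is a stable
focus (eigenvalues ≈ −0.154 ± 0.792i, −1.193): the cyclic-dominance
community persists through damped oscillations onto a fixed point,
whereas the equal-rate community, once assembled by fiat, cycles
neutrally forever. "Cyclic" here describes the dominance structure of
the interactions, not necessarily the asymptotic regime.

`can_assemble` searches introduction orders exhaustively (all
permutations of every superset of the target within the pool, smallest
first), which is factorial and therefore capped at pools of 8.

## Random system generator

`sample_bounded_system` draws two-type systems with diagonal entries
uniform on [−5, −0.5], off-diagonals uniform on [−5, 5], rejecting draws
that violate the boundedness product condition, and reorders so
a₁₁ > a₂₂. The off-diagonal range spans all three ecological sign
quadrants (mutualism, exploitation, competition), so classifier
cross-checks exercise every outcome class; the diagonal range keeps
single-species equilibria at order-one abundances and relaxation times
of order one. Growth rates are drawn uniform on [0.2, 3] with a sign
pattern chosen by regime (both positive; r₁ > 0 > r₂; 0 > r₁ > r₂).
These ranges are a generator choice, not a constraint of the theory —
the classification is scale-covariant, and nothing in the analysis
bounds the coefficients.

What the generator emulates is the *structure* of the theory's object
of study — a bounded pairwise-interaction community with arbitrary sign
pattern — under conditions where every classification threshold is
crossed with substantial probability. What it does not emulate is any
empirical distribution of interaction strengths, measurement noise,
higher-order or time-varying interactions, or demographic
stochasticity. Passing the classifier-versus-simulation checks
therefore certifies the internal consistency of the algebraic
classification with the deterministic dynamics, not its robustness to
the noise structure of real community data.

## Verification strategy

The algebraic classifier is cross-checked against an independent
simulation oracle (long-run integration from four initial conditions:
each boundary equilibrium plus a rare invader at 1e−4, and two generic
interior starts) on 200 seeded random systems, excluding systems within
1e−3 of a classification threshold, where relaxation times diverge.
The oracle integrates in doubling time chunks until every type is
either vanishingly rare (< 1e−7) or per-capita settled (|rᵢ + (An)ᵢ| <
1e−7), so arbitrarily slow — but excluded-margin-bounded — approaches
still resolve. Agreement is required in 200/200 cases. The same
double-route pattern recurs throughout: critical thresholds are checked
algebraically and by bisection on equilibrium structure; hand-derived
equilibria and Jacobians against numerical solves and finite
differences; assembly fitness records against direct growth.

## Known limitations

- Closed-form outcome classification exists only for two types;
  larger communities are analyzed through equilibria, invasion fitness
  and simulation.
- The degenerate loci (exact threshold equalities, zero growth rates,
  zero off-diagonals) are flagged, not resolved; their dynamics is
  structurally unstable and any discrete label would be misleading.
- The assembly protocol assumes deterministic dynamics and strict
  timescale separation; demographic stochasticity at the inoculum
  scale, propagule pressure, and simultaneous arrivals are out of
  scope.
- Cycle detection is amplitude-based over a fixed window and tuned for
  the order-one frequencies of the systems studied here; extremely slow
  or extremely fast oscillations would require adjusting
  `cycle_window`/`relax_time`.
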