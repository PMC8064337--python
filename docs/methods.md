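# Methods

## The model

`togglekit` analyzes a two-gene toggle switch — repressors Y and Z, each
repressing the other's promoter as a dimer (Hill coefficient 2) — whose
expression draws on a shared, limited pool of transcription/translation
machinery.  In dimensionless form (concentrations scaled by the repressor
dissociation constant, time by the growth/dilution rate) the dynamics are

    dy/dt = (alpha_y / (1 + z^2)) / Delta - y
    dz/dt = (alpha_z / (1 + y^2)) / Delta - z

    Delta = 1 + beta_y / (1 + z^2) + beta_z / (1 + y^2) + beta_c .

`alpha_y`, `alpha_z` are effective production strengths (typically 1–100);
`beta_y`, `beta_z` measure the resource sequestration of each gene's
expression (typically 0.1–10; 0 means abundant resources); `beta_c` is the
load imposed by the rest of the genetic context.  The beta terms couple the
two genes through the shared denominator: each gene's expression deflates the
other's effective production.  The sequestration term of a gene carries its
own promoter-activity factor (`beta_y/(1+z^2)`: gene Y sequesters machinery
when its promoter is unrepressed, i.e. when z is low), following the
mechanistic resource-competition models this parameterization is lumped from.
`lump_constants` maps per-gene biophysical constants (transcription and
translation rates, DNA concentration, mRNA decay, RNAP/ribosome dissociation
constants) onto these lumped parameters; only the order-of-magnitude ranges
above are anchored — the absolute dimensionless alpha additionally requires a
growth rate (default ln 2 / 30 min) and repressor dissociation constant, and
the rendered lumping formula is not dimensionally closed, so the function
documents rather than enforces a unit system.

Context load is never a separate regime: with `alpha' = alpha/(1+beta_c)`,
`beta' = beta/(1+beta_c)` the vector field is identical with `beta_c = 0`
(`context_rescale`), so all analyses are run context-free.

The four-parameter reduction separates strength from asymmetry:
`alpha0 = sqrt(alpha_y alpha_z)` (geometric-mean strength),
`a = alpha_y/alpha_z >= 1` (expression asymmetry, labels swapped if needed),
`beta0 = (1+beta_y)(1+beta_z)` (total sequestration),
`b = (1+beta_y)/(1+beta_z)` (sequestration asymmetry, realizable with
nonnegative betas iff `1/beta0 <= b <= beta0`).

## Equilibria and stability

Every fixed point satisfies the one-dimensional constraint
`a z/(1+z^2) = y/(1+y^2)` (for `a = 1` it degenerates to the diagonal union
the hyperbola `y z = 1`).  `find_fixed_points` parametrizes this manifold by
z on a log-spaced grid (1200 points by default), solves the constraint
quadratic branch-wise for y, brackets sign changes of the remaining nullcline
residual and refines them with Brent's method, then classifies each root by
the eigenvalues of the analytic Jacobian.  Eigenvalues with |Re| below 1e-8
trigger a non-hyperbolicity warning.  This route is deterministic and, for
the Hill-2 switch, exhaustive in all parameter regimes we probed (cross-
checked against dense-lattice relaxation).

The Monte-Carlo classifier (`bistable_numeric`) reproduces the published
protocol: 100 random initial conditions uniform on
`[0, alpha_y] x [0, alpha_z]`, relaxed to steady state (fixed-step RK4,
dt = 0.02, horizon 200 with early stopping at vector-field norm 1e-7),
endpoints clustered with Euclidean threshold `0.05 max(1, alpha0)`.  The two
classifiers agree on ≥99% of random realizable parameter draws; the rare
disagreements sit at numeric mono/bistable boundaries, where either a basin
shrinks below the Monte-Carlo sampling resolution or a near-degenerate root
pair defeats the root counter.

A balanced switch (`a = 1`) is bistable exactly when `alpha0 > 2 sqrt(beta0)`
(discriminant of the `y z = 1` branch quadratic
`(1+beta_y) y^2 - alpha0 y + (1+beta_z) = 0`), independent of `b`.

**The monostability certificate.** `sufficient_monostable` certifies
monostability only when both (i) `alpha0 <= 2 sqrt(beta0)` and (ii) the
deterministic root analysis counts a unique equilibrium.  A closed-form bound
alone is not safe: random-draw testing uncovered a second bistability channel
at strong, one-sided loading of the weaker gene (`b << 1` at large `beta0`).
There, repressing the heavily loaded gene frees shared machinery for its
repressor — a resource-mediated positive feedback that supports two stable
states on the *same* side of the diagonal even below the balanced threshold
(e.g. alpha = (11.25, 6.86), beta = (0.26, 20.5): stable states near
(0.66, 0.31) and (6.33, 0.09)).  The certificate is therefore deliberately
conservative: a `True` is backed by an exhaustive equilibrium count, while
`False` makes no claim.

## Quasi-potential and barriers

The flow is not a gradient system, so a trajectory quasi-potential is used:
along solutions, `dV = -(fy^2 + fz^2) dt`, which equals `-f . dx` and makes V
a Lyapunov surface (strictly decreasing away from equilibria).
`quasipotential` integrates every node of a grid over
`[0, 1.2 alpha_y] x [0, 1.2 alpha_z]` (81^2 by default, RK4 with dt = 0.01
and an RK4-consistent quadrature for the accumulated drop), anchors each
basin at its stable state (V = 0), and aligns the two basins by integrating
from the saddle along both directions of its unstable manifold — the two
accumulated drops d_y, d_z pin the saddle height seen from either side.
Barriers are bottleneck (minimax) path costs on the 8-connected grid graph
between the two states; the saddle drop provides an independent cross-check
(agreement to within 5%, typically 0.1%).  Barriers are stable to within 5%
under grid refinement from 61^2 to 121^2.

**What the barrier does and does not predict.**  Escape statistics are
simulated with Euler–Maruyama (`simulate_langevin`): additive noise of
intensity eps in both coordinates (increment std `sqrt(2 eps dt)`,
dt = 0.005), reflection at the axes, and hysteresis-based dwell bookkeeping
(a transition is scored only on entering a disc of radius 0.1x the
state separation around the opposite state).  For switches whose barrier is
small enough that the asymptotic small-noise regime is reachable — e.g.
alpha = (3.5, 3.5), barrier 0.28 — the regression of ln(dwell time) on 1/eps
is linear and its slope matches the quasi-potential barrier within 25%, the
Eyring–Kramers picture.  For strong switches such as alpha = (10, 10)
(barrier 9.4) the reachable eps window (0.15–0.5) yields a linear regression
whose slope is only ~1.5: the flow is strongly non-gradient away from the
symmetric saddle path, noise exploits rotational escape routes whose
large-deviation cost is far below the trajectory-potential barrier, and the
true asymptotic regime (dwell times of order e^60) is unobservable.  The
trajectory quasi-potential therefore orders and compares barriers — all the
comparative statements about strength, loading and asymmetry rest on it —
but its absolute height is not the escape exponent of a strong switch.
Per-generation switching probabilities use exponential waiting:
`p = 1 - exp(-ln 2 / tau)` with tau in dimensionless (growth-rate) units.

## Population fate recursion

Generations alternate independent Bernoulli switching (a y-dominated cell
switches with probability `py`, a z-dominated one with `pz`) with exact
doubling.  Conditioned on the previous y-count, the pre-doubling count is the
convolution of two binomials (survivors and switchers); `evolve` iterates
this kernel exactly, with binomial pmfs computed in log space (robust down to
subnormal probabilities).  Distribution vectors grow as `2^i`, and the
convolution cost as `4^i`; generations are capped at 20 and the Monte-Carlo
oracle (`monte_carlo_population`, which tracks counts rather than cells)
covers anything longer.  The mean fraction obeys
`f_i = f_{i-1}(1-py) + (1-f_{i-1}) pz`, converging geometrically with ratio
`1 - py - pz` to the seed-independent stationary composition `pz/(py+pz)`;
`generations_to_steady` scans this recursion against a 0.1% relative band.

## Misclassification error and balancing

For a bistable switch, `mismatch_error` relaxes a lattice of initial
conditions on `[0, alpha_y] x [0, alpha_z]` (101^2 by default) and reports
the area fraction whose initial and final dominant coordinates disagree
(exact-diagonal nodes excluded as they have no dominant coordinate).  A
balanced switch has error 0 (the separatrix is the diagonal); the error
grows with `a` and reaches roughly 20–24% over `a` in [1, 2] at beta = 0,
peaking near the bistability boundary.

`optimize_competition` searches `(beta_y, beta_z)` in `[0, 5]^2` (step 0.25,
one 4x refinement around the best cell, bistability screened analytically
before each map evaluation; the search stage uses a 41^2 lattice and the
winner is re-scored at 101^2).  In this model the search consistently returns
the unloaded switch: every fixed point obeys the beta-independent constraint
manifold, whose z-dominant branch keeps the saddle far from the diagonal for
`a > 1`, and on that branch the fixed-point equation is strictly increasing
in both betas — loading can only shrink or annihilate the weaker basin, never
re-balance the switch or create bistability.  The optimizer is therefore a
certified negative result here: it demonstrates (rather than assumes) that
resource sequestration alone cannot restore functional balancedness for this
switch model, a genuinely open behavior we document rather than tune away.

## Coupled switches

N co-deployed switches share the resource pool: each experiences a context
load equal to the sum of the other switches' instantaneous sequestration
terms.  For identical switches at a common state this is exactly one switch
with `(N beta_y, N beta_z)` (the symmetric reduction), giving a fast
deterministic route to the capacity `N_crit` — the largest N that remains
collectively bistable.  The full route relaxes the 2N-dimensional system from
100 random initial conditions (each switch uniform on `[0, alpha0]^2`) and
labels the collective bistable iff switches are found resting on both sides
of the diagonal (margin 0.02 alpha0).  Both routes agree on the shipped
examples; capacity grows with `alpha0`, shrinks with `beta0` and with
expression asymmetry `a`.  Mild sequestration asymmetry `b` barely moves
`N_crit` for balanced switches, but for `a > 1` strong b-shifts act
directionally (loading the stronger side preserves capacity), consistent with
the single-switch stability analysis.

## Problem sizes and numerical defaults

| quantity | default | note |
| --- | --- | --- |
| RK4 relaxation step | 0.02 (0.01 for potentials) | relaxation rates are O(1) |
| relaxation horizon | 200 (400 for potentials) | early stop at \|f\| < 1e-7 |
| potential grid | 81^2 over [0, 1.2 alpha]^2 | 61^2 in sweeps |
| Langevin step | 0.005 | reflection at the axes |
| capture radius | 0.1 x state separation | hysteresis rule |
| MC classifier | 100 trajectories | threshold 0.05 max(1, alpha0) |
| error-map lattice | 101^2 (41^2 during search) | refinement-stable to 0.5 pp |
| beta search | [0, 5]^2, step 0.25, 4x refine | deterministic |
| exact generations | cap 20 | MC oracle beyond |

The shipped scenario suite (`togglekit scenario list`) runs all standard
analyses at these reduced resolutions in minutes on one CPU; all randomness
flows from explicit seeds, and reruns are bit-identical.

## What the synthetic scenarios do not capture

All inputs are model parameters; there is no external data.  The scenario
suite emulates the published parameter sweeps, not biology beyond the model:
constant growth rate (no host feedback), instantaneous resource binding,
dimer repression only (`theta = 2` enforced), additive state-independent
noise, synchronous doubling without division noise or death.  Passing tests
therefore validate the analysis machinery and the model's internal claims,
not the behavior of a wet-lab switch.
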