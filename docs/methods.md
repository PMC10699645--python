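# Methods

## Model structure and assumptions

The model couples three timescales:

* **minutes–hours** — the HPA hormones CRH (`x1`), ACTH (`x2`) and
  cortisol (`x3`), with removal rates of order 10⁻¹/min;
* **weeks** — the functional masses of the pituitary corticotrophs (`P`,
  turnover ≈ 0.05/day) and adrenal cortex (`A`, ≈ 0.1/day), each growing
  in proportion to its upstream hormone;
* **weeks** — a lumped CNS inhibitory activity `h` (turnover 0.047/day)
  that divides the hypothalamic stress drive and is itself suppressed when
  cortisol activates CNS glucocorticoid receptors (GR).

All variables are dimensionless, normalized so the healthy baseline of
every hormone and mass is 1.  The gland equations implement integral
feedback: at any steady state CRH and ACTH equal the turnover ratios
`bP/aP` and `bA/aA` independent of the stress input `u`; the gland masses
and cortisol absorb input changes instead (`x3 = (a1 aP)/(b1 bP) · u/h`).

Receptor logic: cortisol inhibits the hypothalamus through both MR
(non-cooperative, `MR(x) = 1 + x/KMR`) and GR (cooperative,
`GR(x) = 1 + (x/KGR)³`), but the pituitary through GR only.  In the
physiological regime `KMR ≪ x3 ≪ KGR` this reduces to the *simplified*
model (`MR ≈ x3/KMR`, `GR ≈ 1`) used for all phase-plane algebra.  The CNS
GR response is approximated by a step: the CNS production divisor is `a`
for `x3 ≤ T` and `a + b` for `x3 > T`.  A Hill-smoothed variant (exponent
`m`, default 50) is available everywhere and is used as an independent
numerical cross-check of the piecewise algebra; its fixed points converge
to the exact-step ones as `m` grows.

## Parameters

Canonical time unit: **days**.  Hormone rates are customarily quoted per
minute and are converted (×1440) at construction; the nominal set is

| group | values (per day unless noted) |
|---|---|
| hormones | a1 = b1 = 0.17/min, a2 = b2 = 0.035/min, a3 = b3 = 0.0086/min |
| glands | aP = bP = 0.049, aA = bA = 0.099 |
| CNS | ah = bh = 0.047, a = 1, b = 1, T = 1.5 |
| receptors | KMR = 0.1, KGR = 5, Hill exponent 3 |

`KMR` and `KGR` have no canonical normalized values; the defaults place
the baseline deep in the regime `KMR ≪ 1 ≪ KGR` while keeping GR effects
finite for the endocrine-test simulations, and both are config-exposed.
In the full model the CRH gain is rescaled internally to
`a1·MR(1)·GR(1)` so the euthymic baseline stays at hormone level 1; the
pituitary then self-consistently settles at `P = GR(1) ≈ 1.008`, which is
the full model's compensation pattern (`P_st ∝ GR(x3)`, `A_st ∝ x3` — the
adrenal grows more than the pituitary in the depressed state).

## Phase-plane analysis

With hormones at quasi-steady state and the pituitary fixed at its
cortisol-independent steady size, the slow system is two-dimensional.
Because the CNS drive is an exact step, `h` can only equilibrate at
`h_high = ah D/(bh a)` (valid while the point's cortisol ≤ `T`) or
`h_low = ah D/(bh (a+b))` (valid while cortisol > `T`); the adrenal
nullcline is `A ∝ u/h`.  Fixed points are therefore enumerated exactly:
euthymic, depressed, and — whenever both exist — a threshold (saddle)
point where the adrenal nullcline crosses the switching manifold
`x3 = T`.  The threshold point is classified unstable by construction
rather than by Filippov sliding-mode analysis; under Hill smoothing it
becomes a genuine saddle (one positive eigenvalue), which the test suite
verifies, and the smoothed-system root finder confirms all fixed-point
locations to 10⁻² or better.

Sensitivity scans bisect a multiplicative fold applied to one parameter
(tolerance 0.005 in the fold) until the fixed-point count drops from 3 to
1; scans run on the simplified reduced model, whose closed forms make them
exact and fast.  The stress thresholds follow in closed form:
`u1 = T h_high (b1 bP)/(a1 aP)` and `u2 = T h_low (b1 bP)/(a1 aP)`, giving
`(u1, u2) = (1.5, 0.75)` at nominal values.  Sensitivities for parameters
that enter only the fast equations' prefactor (a2, a3, b2, b3, aA, bA, aP,
bP in part) cancel out of the simplified closed forms; scans of those rows
are reported as informational only, since their fold-changes depend on the
full model's receptor constants.

## Numerical integration

The step makes the vector field piecewise smooth.  Trajectories are
integrated with LSODA (absolute tolerance 10⁻⁹, relative 10⁻⁷) with
solver event detection at cortisol-threshold crossings: the step branch is
frozen, integration stops at a crossing, the branch flips, and integration
restarts a nudge (10⁻¹⁰ relative) past the manifold.  In this model the
manifold is repulsive in `h` on both sides, so crossings are transversal
and no sliding/chattering occurs; a switch cap guards against pathology.
Protocols (piecewise-constant `u` and `D`, injection events) contribute
additional restart points.  The smoothed drive mode integrates without
events.

Basins of attraction are labelled by forward integration of the reduced
system until within 10⁻⁴ of a stable fixed point (cap 3000 days); the
separatrix is located by bisection on that label (tolerance 10⁻⁴ in `A`)
and passes through the threshold saddle.

## Reductions and their accuracy

Two reductions are provided.  The three-variable slow subsystem (`P`, `A`,
`h`, hormones at QSS) tracks the stiff 6-D simulation within a fraction of
a percent on multi-week stress protocols.  The 2-D phase plane
additionally pins `P` at its steady size; it is exact at steady states and
reproduces all fixed-point structure, but during a multi-week stress
transient the real pituitary temporarily grows ~20% (CRH is transiently
elevated until integral feedback restores it), so the 2-D trajectory can
deviate by ~15–20% in `A` mid-transient.  Phase-plane conclusions
(attractor identity, basins, thresholds) are unaffected; quantitative
transient work should use the slow subsystem or the full model.

## Scenario and endocrine-test conventions

Scenario runners start at the relevant fixed point, apply a
piecewise-constant protocol, and classify the final state's basin at
baseline conditions.  Durations of 3 versus 60 days at doubled stress
(or halved stress for relief, or D = 2 for treatment) straddle the
critical duration (≈ 2.5 weeks at nominal parameters), which scales
inversely with the slow turnover rates.

The CRH test adds an exogenous CRH bolus (default 5× baseline CRH) that
decays with the 43-minute half-life of synthetic CRH (a square-pulse mode
of 30 minutes is available; the clinical dose-to-concentration mapping is
unknown, so only directional and ratio claims are asserted).  Exogenous
CRH enters ACTH production additively with endogenous CRH and does not
feed back on its own secretion.  The DEX/CRH test holds a constant DEX
level (default 3·KGR, cortisol-equivalent GR units, no clearance over the
≤ 24 h window) that acts only on GR terms — DEX is GR-selective and never
engages MR — with the CRH bolus injected 15 hours later.  Gland masses and
`h` are frozen during these hours-long tests.  Under DEX the high
endogenous cortisol of the MDD subject is masked and the measured ACTH is
proportional to pituitary secretion capacity, so the MDD/control peak
ratio approaches the pituitary mass ratio as suppression becomes total.

## Degenerate inputs and tie-breaks

Cortisol exactly at the threshold belongs to the low branch (`drive = a`),
a measure-zero convention that keeps the dynamics deterministic.  States
with `x3 = 0` are rejected (the simplified CRH equation divides by
cortisol), as are non-positive rates, `KMR ≥ KGR`, stress `u ≤ 0` and
treatment `D < 1`.  Marginal stress `u = 0.75` sits exactly on the lower
bifurcation; it is treated as outside the bistable window (the depressed
branch requires cortisol strictly above threshold).

## Limitations

No circadian or ultradian cortisol rhythms; no pharmacokinetics beyond
first-order ligand decay; the CNS is a single lumped variable; the
step/Hill CNS response is a caricature of GR cooperativity; normalized
units mean quantitative comparison with assay data requires an external
calibration that the model does not supply.
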