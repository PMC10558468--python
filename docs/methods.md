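# Methods

## Model and assumptions

`plastidyn` integrates an *N*-compartment competitive Lotka–Volterra system
with state switching.  The compartments discretize the epithelial–
mesenchymal spectrum; all share one carrying capacity (equal competition),
so the competitive load on every phenotype is the plain total abundance
*X*.  Growth rates decrease linearly from the epithelial rate *r₁* to the
mesenchymal rate *r_N*; because the equilibrium distribution turns out to
be independent of the growth ladder, the linear choice is a convenience,
not a structural commitment.  Transitions are strictly nearest-neighbour
and phenotype-independent: every compartment switches mesenchymal-ward at
`c (1+λ) r₁` and epithelial-ward at `c (1−λ) r₁`, with the terminal
compartments transitioning in one direction only.  The bias λ is the
model's handle on transition-modulating factors in the microenvironment
(e.g. TGF-β levels): the factor's concentration is mapped onto λ rather
than modelled explicitly.  Treatment enters purely as extra per-capita
mortality — no pharmacokinetics, toxicity, or resistance mutations.

The right-hand side is written in flux form (each directed flux appears
once with opposite signs in source and target), so conservation of total
abundance by the transition terms holds to round-off by construction, and
the nonnegative orthant is forward-invariant (an empty compartment has
inflow-only dynamics).

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| N | number of phenotypes | 3 | – |
| r₁ | epithelial growth rate | 1 | per time (time is r₁-scaled) |
| r_N | mesenchymal growth rate | 0.2 | per time |
| K | carrying capacity | 1 | abundance |
| c | transition speed | 1 | relative to r₁ |
| λ | transition bias | 0 | in [−1, 1] |
| m_D | growth-dependent intensity | 1 | multiplier on rᵢ |
| m_I | growth-independent intensity | calibrated (0.6475) | per time |

`m_I` has no free default: it is fixed by requiring that a single
duration-10 block of either treatment type, applied to the equilibrium
tumor at (c = 1, λ = 0), leaves the same total abundance.  The endpoint gap
is monotone in the trial intensity, so the calibration is solved as
bracketed root finding (Brent, bracket [0, 10·m_D·r₁]) rather than generic
minimization; the residual endpoint mismatch is below 10⁻⁸.  The
calibration starting state is the coexistence equilibrium, consistent with
how all treatment experiments are initialized.

Two variant hooks extend the reference model: a general nonnegative
competition matrix (entry (i, j) weighting the load of phenotype j on i),
and `transition_scaling="own_rate"`, which scales each compartment's
*outflux* by its own growth rate `c rᵢ` instead of `c r₁` while keeping the
flux form (and hence conservation) intact.  The own-rate coupling
convention — outflux scaled at the source — is this package's assumption
for growth-coupled transition machinery.  Closed-form equilibrium and
decision-boundary routines refuse non-default competition matrices, since
the geometric profile below assumes a shared load; simulation and the
Jacobian support both hooks fully.

## Equilibria and moments

For c > 0 the coexistence equilibrium is the geometric profile
`xᵢ* ∝ (1−λ)^(N−i) (1+λ)^(i−1)` normalized to K, evaluated directly
(`0⁰ = 1` covers the unidirectional limits λ = ±1).  At c = 0 the phenotype
mix is frozen and every point on the simplex `X = K` is an equilibrium, so
the closed-form routine rejects c = 0 rather than return an arbitrary
member of that continuum.

Distribution summaries map compartments onto trait scores
`sᵢ = (i−1)/(N−1) ∈ [0, 1]` (0 = epithelial, 1 = mesenchymal) so moments
are comparable across N; the mean phenotype, variance (heterogeneity), and
third central moment (mismatched-phenotype tail) are computed over the
frequency vector.  The equilibrium inherits a mirror symmetry
`xᵢ*(λ) = x_{N+1−i}*(−λ)`: variance is even in λ and maximal at λ = 0,
the third central moment is odd and vanishes at λ = 0 and at the extremes.

Stability is assessed from the analytic Jacobian (growth, competition,
transition, and treatment derivatives assembled term by term and
cross-checked against central finite differences in the tests).  The
verdict uses a ±10⁻⁹ band on the leading real part of the spectrum, with
`marginal` returned inside the band.  Across the (λ, c) grids exercised in
the tests the coexistence equilibrium is uniformly stable and the origin
uniformly unstable; no global (Lyapunov) certificate is attempted —
global convergence is checked numerically by integrating scenario initial
conditions onto the closed form (agreement 10⁻⁶–10⁻⁸).

## Treatment schemes and the decision boundary

Schedules tile the fixed treatment duration (default 10 time units) with
equal blocks: `single_GD`, `single_GI`, `alternating_GD_first`,
`alternating_GI_first`, or `adaptive`.  Adaptive blocks choose, at block
start, the type with the higher instantaneous mortality on the current
state (`Σ m_D rᵢ xᵢ` vs `Σ m_I xᵢ`); exact ties — a measure-zero event —
break deterministically toward growth-dependent treatment.  For a tumor at
its equilibrium distribution, the adaptive one-block decision depends only
on λ; the switch point λ̃ solves `Σ (m_D rᵢ − m_I) xᵢ*(λ) = 0`, a
low-degree polynomial in λ with a monotone weighted-mean structure.  It is
solved by sign-change bracketing on a 1001-point grid with Brent polishing
(|f| ≲ 10⁻¹²); multiple sign changes raise an error listing all roots, and
the routine returns `None` when one treatment dominates on all of [−1, 1]
(e.g. m_I > m_D r₁).  With the calibrated intensity the boundary sits at
λ̃ = −0.0893.

Burden reduction is `(K − X)/K` at the end of the treatment duration;
values pushed marginally past the ends of [0, 1] by solver noise are
clipped and logged.

## Numerics

Integration uses `scipy.integrate.solve_ivp` with LSODA at rtol 10⁻⁸ /
atol 10⁻¹⁰ (the system is small and smooth; tight tolerances are cheap and
make reported quantities reproducible to printed precision).  The solver
restarts at every block boundary so intensity switches are exact, and
output sampling (default Δt = 0.1) never constrains the internal step.
Negative abundances within `max(10⁻¹², 100·atol)` of zero are round-off
from deep-decay segments and are clamped to zero with a debug log; anything
more negative raises.  Open-horizon equilibration integrates in chunks and
stops when both the rhs max-norm and the frequency drift per unit time fall
below 10⁻¹⁰, capped at a configurable horizon (default 1000 time units,
the standard regrowth window).  A solver-independence test checks that
default and tightened tolerances agree to 10⁻⁶ on an endpoint.

## Experiments and problem sizes

Scenario fixtures: `primary_site` = K/10 purely epithelial founder,
`secondary_site` = K/10 purely mesenchymal founder (the pure-M founder
mirrors the primary-site convention; real disseminating populations likely
carry a hybrid admixture), `ablate_*` = equilibrium with one compartment
zeroed, `equilibrium` = the closed form.  Sweeps start every (λ, c) cell
from its own equilibrium — the tumor is assumed to have settled before
treatment — and record the end-of-treatment reduction; for adaptive
schemes the resolved block sequence per cell is kept.  Default sweep grids
are 41 λ-points in [−1, 1] × 25 log-spaced c-points in [10⁻², 10²]
(spanning both the transition-dominated and growth-dominated regimes);
the test suite uses coarser grids (5–9 λ-points, 3–5 c-points), which
suffice for the qualitative orderings they assert.  Adjuvant
(transition-modulating) therapy is modelled as a persistent parameter
shift (λ + δλ, c + δc) applied before and during treatment, so the shifted
run re-equilibrates its initial condition at the shifted parameters; no
extra dynamical variable is introduced.

## What the tests do and do not show

All quantitative checks run on model-generated data: closed forms against
long integrations, analytic Jacobians against finite differences, scheme
equivalences that hold by construction, and qualitative orderings
(phenotype-matched corners dominate, efficacy grows with transition speed,
transient phenotype shifts relax after treatment).  Passing them validates
the mathematics and the numerics, not the biology: the model abstracts away
microenvironmental drivers, spatial structure, explicit dissemination, and
acquired resistance, and its treatment types are population-level
caricatures of chemo- and immunotherapy.  Two further behaviours worth
noting: the approach of the mean phenotype to its asymptote need not be
one-sided (a mesenchymal-founder run transiently undershoots while the
fast-growing compartment fills the site), and the efficacy of alternating
schemes is not monotone in the number of blocks — finer interleaving can
partially recover what two-block alternation loses at strongly biased
tumors, although every alternating scheme stays below the phenotype-matched
single block there.
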