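# Methods

## Model and assumptions

The organism is a hermaphroditic perennial with discrete breeding seasons,
overlapping generations and fixed life-history parameters; density dependence
is absent, and the resource budget (normalized to 1) is spent exactly once
per season on three competing functions: pollen (*M*), seeds (*F*) and adult
survival (1 − *M* − *F*).  Phenotypes are written in the life-history
coordinates (*E*, *r*, *s*): reproductive allocation *E* = *M* + *F*, sex
allocation *r* = *M*/*E*, selfing rate *s*.  At *E* = 0 the package fixes
*r* = 0 by convention (fitness does not depend on *r* there).

Inbreeding depression acts at two stages.  A selfed juvenile recruits with
probability Pj·wⱼ instead of Pj (wⱼ = 1 − δⱼ); a selfed adult survives a
season with probability Pa·wₐ instead of Pa (wₐ = 1 − δₐ).  The fraction of
the adult class that is selfed follows the resident selfing rate through
S(s) = γ·s with γ ∈ (0, 1), so the adult term of a mutant with selfing rate
*s*′ carries the discount 1 − S(*s*′)·δₐ.

Invasion fitness of a rare mutant (*E*′, *r*′, *s*′) against a monomorphic
resident (*E*, *r*, *s*) is

W = Pa(E′)(1 − S(s′)δₐ) + Pj·s′·wⱼ·f(F′) + ½Pj(1 − s′)f(F′) + ½Pj(1 − s)f(F)·m(M′)/m(M).

The ½ weights are genetic shares: an outcrossed offspring carries one gene
copy from each parent, a selfed offspring both copies from its single parent
(the automatic transmission advantage).  The outcross-siring term divides the
resident pool of outcrossed ovules, (1 − s)·f(F), in proportion to relative
pollen output; only the ratio m(M′)/m(M) ever matters, so the pollen scale
m_max cancels from all resident-level quantities.  The decomposition into
female (seed-parent) and male (pollen-parent) fitness splits the adult term
and the selfed-seed term half-and-half between the two parental roles —
a selfed offspring's two gene copies arrive one through each route — which
keeps W_f + W_m = W exact by construction.

## Gain curves and parameters

| parameter | meaning | default | why |
|---|---|---|---|
| Pj | outcrossed juvenile recruitment probability | 0.2 | perennial recruitment is rare |
| δⱼ, δₐ | juvenile / adult inbreeding-depression fractions | 0.2, 0.4 | an adult-cost-dominated perennial, clearly inside the "effort increases with selfing" regime |
| γ | growth rate of the selfed-adult class | 0.5 | mid-range of (0, 1) |
| f_max | seeds at full seed investment | 10 | moderate fecundity; only products Pj·f_max matter |
| m_max | pollen at full pollen investment | 100 | arbitrary — cancels in the siring ratio |
| η | male gain-curve exponent, m = m_max·M^η | 0.8 | diminishing returns on pollen; η = 1 is the degenerate linear case |
| Pa_max, β | survival curve Pa = Pa_max(1 − E)^β | 0.9, 0.5 | see below |

The female gain is linear (f = f_max·F) and the male gain a concave power —
the standard forms under which the effort condition loses its *r*-dependence
and the sex-allocation condition its *E*-dependence.  The survival curve's
shape is a modeling choice: the theory only requires Pa(E) strictly
decreasing and strictly concave.  Pa_max·(1 − E)^β with β ∈ (0, 1) is the
package default because it guarantees an interior fitness maximum in *E* and
yields a closed-form ESS, E* = 1 − (Pa_max·β/K)^{1/(1−β)} with
K = ½Pj·f_max·h(s)/c(s), h(s) = 1 + s(2wⱼ − 1), c(s) = 1 − γsδₐ.  All four
curves are pluggable objects exposing value and first derivative (the
defaults also second derivatives); every solver has a curve-agnostic route.

## Solvers and numerical choices

**Closed forms.**  `solve_ess_E` uses the closed form above for the default
survival curve and Brent root-finding on the effort condition for any other
concave curve (bracket [0, 1 − 10⁻¹²], xtol 10⁻¹²); roots outside [0, 1] are
clipped with a boundary flag in `solve_ess`.  `solve_ess_r` is the algebraic
formula r* = η(1−s)/(η(1−s) + h(s)); at s = 1 it returns the boundary value 0
directly.

**Gradients.**  `selection_gradient` offers two routes that are tested
against each other: curve-derivative formulas assembled by the chain rule
from the (M′, F′) gradient (dW/dE′ = r·W_M + (1−r)·W_F,
dW/dr′ = E·(W_M − W_F)), and central finite differences on the full fitness
with step 10⁻⁵·max(1, |x|).  Boundary residents raise an error rather than
silently switching to one-sided differences; only the selfing gradient,
whose domain endpoints s = 0, 1 are of intrinsic interest, falls back to a
second-order one-sided stencil there.

**Second-order conditions.**  `check_second_order` builds the 2×2 Hessian in
(M′, F′) by central differences (step 10⁻⁴) and tests negative definiteness
through the leading minors.  Minors within 10⁻⁶ of zero flag the result
indeterminate instead of failing: with a linear female gain the Hessian is
the rank-one survival curvature plus the male-gain curvature, so η = 1
(linear male gain) produces a singular matrix by structure, not by accident.

**The numeric oracle.**  `solve_ess_numeric` is deliberately independent of
the closed forms: the mutant best response against a fixed resident is found
by nested golden-section maximization of the raw fitness on [0, 1]²
(resolution 10⁻¹²), and the ESS is the resident that maps to itself.  Plain
best-response iteration is unstable here — the siring value of pollen,
B = ½Pj(1−s)f(F)/m(M), reacts steeply to the resident's own pollen output,
and the undamped map overshoots into a two-cycle.  The package exploits the
fact that, for fixed *s*, the resident enters the best-response problem only
through the scalar B: the fixed point is the unique root of the strictly
decreasing map B ↦ B_implied(best_response(B)) − B, bracketed and solved by
Brent's method.  The solver is deterministic (no randomness anywhere), snaps
near-edge optima to the boundary and flags boundary ESSs, and verifies the
result by taking one explicit best-response step; the verification tolerance
(10⁻⁶, the solver's advertised accuracy) is far looser than the golden
resolution because the best-response map amplifies coordinate noise through
its steep Jacobian.  Precondition: strictly concave male gain (η < 1) — at
η = 1 the best response in *r*′ is flat and no isolated fixed point exists,
the same degeneracy the second-order check flags.

**Mating-system analysis.**  The selfing gradient at the resident is
∂W/∂s′ = Pj·f(F)(wⱼ − ½) − Pa(E)·S′(s)·δₐ, evaluated by default at the
allocation ESS for resident s = 0; at s = 0 that ESS does not depend on δⱼ,
δₐ or γ, which keeps τ = δₐ·Pa·γ/(Pj·f) constant while
`find_deltaj_boundary` bisects the gradient's zero in δⱼ (xtol 10⁻⁸), so the
located boundary equals ½ − τ.  τ's Pa and f are numbers in the threshold
formula but functions in the model; both conventions are supported (ESS
evaluation by default, fixed-value curves or an explicit strategy on
request).  Because W is linear in s′ under the default curves, the gradient
sign is constant and only three regimes exist: complete selfing (gradient
> 0, δⱼ < ½ − τ), complete outcrossing (< 0), neutral (|gradient| ≤ 10⁻⁹).
A nonlinear selfed-adult uptake S(s) can cross zero inside (0, 1); the
classifier then reports the root with the regime label `interior_singular`,
an extension beyond the linear model and labeled as such.  The classifier
always computes the regime twice — rule (δⱼ vs ½ − τ) and gradient sign —
and raises an internal-consistency error if they disagree, as a tripwire.

**Tolerances.**  Arithmetic identities are asserted at 10⁻⁹ or exactly;
solver outputs at 10⁻⁶; classification ties at 10⁻⁹ on the ratio or
gradient.  The tie at ratio = ½ is reported as its own regime
("independent") because it is a structurally distinct case, not a rounding
artifact.

## Scenarios, sweeps and scope

The bundled scenarios sit clearly inside each qualitative regime: three
effort-vs-selfing regimes (ratio above, below and exactly at ½), a
sex-allocation family over wⱼ ∈ {0.3, 0.6, 0.9}, and both mating-system
endpoints.  Sweeps and the (δⱼ, τ) phase diagram reproduce signs,
monotonicities and boundaries only — no quantitative curve from any
particular published figure is targeted, and none could be: the package's
claims are about regime structure.  In the phase diagram each τ column is
realized by fixed-value Pa and f curves with δₐ back-solved from τ, so the
boundary cells straddle δⱼ = ½ − τ by construction of the model, not of the
table.

Out of scope: age- or stage-structured demography, density dependence,
pollen limitation / reproductive assurance beyond what the fitness function
encodes, allele-frequency recursions, and joint three-trait adaptive
dynamics of (E, r, s) — the selfing analysis holds the allocation at its ESS
for the resident selfing rate, as in the underlying theory.

## Problem sizes

The default verification runs use 100 random parameter sets for the
oracle-vs-closed-form comparison, 1000 draws for the slope-sign sweep, and
parameter draws spanning Pj ∈ [0.1, 1], δⱼ ∈ [0, 0.95], δₐ ∈ [0, 1],
γ ∈ [0.05, 0.95], f_max ∈ [2, 50], m_max ∈ [1, 200], η ∈ [0.3, 0.95],
Pa_max ∈ [0.3, 1], β ∈ [0.2, 0.8], with rejection of parameter sets whose
effort ESS is within 0.02 of the simplex boundary (the comparisons concern
interior ESSs).  These sizes keep the full suite under half a minute on one
CPU while sampling every regime; the acceptance script uses 50 oracle sets
for the same reason.

## Known limitations

* The numeric oracle requires η < 1 and a strictly decreasing, strictly
  concave survival curve; it reports — rather than resolves — boundary ESSs.
* The selfing-rate analysis assumes the allocation equilibrates faster than
  the mating system evolves; feedback of s on (E*, r*) is included only
  through that quasi-equilibrium.
* `classify_mating_ess` with non-default curves probes them at a fixed
  interior strategy (constant curves make the choice irrelevant); for
  user-supplied state-dependent curves the evaluation strategy should be
  passed explicitly.
* Exact neutrality claims (δⱼ = δₐ = 0, or ratio = ½) hold to machine
  precision only for the default linear/power curves.
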