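# perennial-ess

Evolutionarily stable resource allocation and mating-system evolution in
hermaphroditic perennial plants.

A hermaphroditic perennial divides a fixed resource budget each season among
pollen production (proportion *M*), ovule and seed production (*F*) and its
own survival (the remainder 1 − *M* − *F*).  Writing the reproductive
allocation *E* = *M* + *F* and the sex allocation *r* = *M*/*E*, and letting a
fraction *s* of ovules be self-fertilized, selfed offspring pay inbreeding
depression twice: a fraction δⱼ of selfed juveniles die during recruitment
(relative survivorship wⱼ = 1 − δⱼ) and a fraction δₐ of selfed adults die
each season (wₐ = 1 − δₐ), with the selfed-adult class growing at rate γ.
This package is for theoreticians in life-history and mating-system evolution
who want the model's evolutionarily stable strategies (ESS), their
sensitivities and the selfing-rate phase boundaries as reproducible
computations rather than hand-derived algebra.

## The model

A rare mutant (*E*′, *r*′, *s*′) in a resident population (*E*, *r*, *s*) has
fitness

```
W = Pa(E′)·(1 − S(s′)·δa)                      adult survival
  + Pj·s′·wj·f(F′)                             selfed seeds (double gene share)
  + ½·Pj·(1 − s′)·f(F′)                        outcrossed ovules
  + ½·Pj·(1 − s)·f(F)·m(M′)/m(M)               outcross siring
```

with survival curve Pa(E) = Pa_max·(1 − E)^β (strictly concave), seed gain
f(F) = f_max·F, pollen gain m(M) = m_max·M^η and selfed-adult fraction
S(s) = γ·s.  The ½ weights encode the automatic transmission advantage of
selfing.  Setting ∂W/∂E′ = ∂W/∂r′ = 0 at mutant = resident gives, with
h(s) = 1 + s(2wⱼ − 1) and c(s) = 1 − γsδₐ,

```
−Pa′(E*)·c(s) = ½·Pj·f_max·h(s)               E*: independent of r
r* = η(1 − s) / (η(1 − s) + h(s))             r*: independent of E, f_max, m_max, δa
```

Whether *E*\* rises or falls with the selfing rate is decided by the ratio
wⱼ / (1 − γ + γwₐ) against ½; *r*\* always falls with *s* (slope
−2ηwⱼ/(η(1−s)+h(s))²).  Treating *s* itself as the evolving trait, the
selection gradient ∂W/∂s′ = Pj·f·(wⱼ − ½) − Pa·γ·δₐ is sign-constant, so the
population runs to complete selfing when δⱼ < ½ − τ and to complete
outcrossing when δⱼ > ½ − τ, where τ = δₐ·Pa·γ/(Pj·f) is the selfed-adult
mortality rate caused by inbreeding depression.

Alongside the closed forms the package carries an independent numerical
oracle (`solve_ess_numeric`) that locates the ESS as the fixed point of the
mutant best-response map by golden-section maximization of the full fitness
function, plus selection-gradient routines, second-order (maximality)
checks, pairwise-invasibility grids, parameter sweeps and a CLI.

## Worked example

```python
from perennial_ess import LifeHistoryParams, classify_mating_ess, solve_ess, solve_ess_numeric

params = LifeHistoryParams()   # Pj=0.2, delta_j=0.2, delta_a=0.4, gamma=0.5,
                               # f_max=10, m_max=100, eta=0.8, Pa_max=0.9, beta=0.5
ess = solve_ess(params, s=0.5)
print(ess.E_star, ess.r_star, ess.second_order_ok)
# 0.9029437869822485 0.23529411764705882 True

oracle = solve_ess_numeric(params, s=0.5)
print(oracle.E_star, oracle.r_star)
# 0.9029437936193647 0.2352941183297025

print(classify_mating_ess(params.with_updates(delta_a=0.0)).regime)
# complete_selfing
```

At a selfing rate of one half this plant puts 90.3 % of its budget into
reproduction, 23.5 % of that into pollen, and the stationary point is a true
fitness maximum; the best-response oracle reproduces both allocations to
eight decimals.  With no adult inbreeding cost and δⱼ = 0.2 < ½, higher
selfing always invades, so complete selfing is the ESS.

The same numbers from the shell:

```
perennial-ess solve --s 0.5
perennial-ess classify --delta_a 0 --delta_j 0.2
perennial-ess sweep --axis s --n 21 --out out/
perennial-ess pip --n 21 --out out/
perennial-ess scenarios
```

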