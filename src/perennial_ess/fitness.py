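"""Mutant fitness: female, male and total.

A rare mutant with phenotype (E', r', s') in a resident population fixed for
(E, r, s) has total fitness

    W = Pa(E') * (1 - S(s') * delta_a)                        adult survival
      + Pj * s' * w_j * f(F')                                 selfed seeds
      + (1/2) * Pj * (1 - s') * f(F')                         outcrossed ovules
      + (1/2) * Pj * (1 - s) * f(F) * m(M') / m(M)            outcross siring

The 1/2 weights encode the automatic transmission advantage of selfing: an
outcrossed offspring carries one gene copy from each parent (genetic share
1/2 per parental role) while a selfed offspring carries both copies from its
single parent (total share 1).  Selfed juveniles survive recruitment with
probability Pj * w_j instead of Pj; selfed adults (a fraction S(s') of the
mutant's adult class) die at the extra rate delta_a, hence the survival
discount 1 - S(s') * delta_a.  The outcross-siring term divides the resident
pool of outcrossed ovules, (1 - s) * f(F), in proportion to pollen output
m(M') / m(M).

Female fitness (seed-parent accounting) takes half the adult term, half the
selfed-seed term and the outcrossed-ovule term; male fitness (pollen-parent
accounting) takes the other halves and the outcross-siring term.  Their sum
is the total fitness exactly, and the adult survivorship is counted exactly
once in the total.
"""

from __future__ import annotations

from .errors import DegeneratePollenPoolError
from .gains import GainFunctions
from .params import LifeHistoryParams, Strategy

__all__ = ["female_fitness", "male_fitness", "total_fitness"]


def _components(
    mutant: Strategy,
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None,
) -> tuple[float, float, float, float]:
    """Return (adult, selfed_seeds, outcrossed_ovules, outcross_siring)."""
    g = gains if gains is not None else GainFunctions.defaults(params)
    adult = g.survival(mutant.E) * (1.0 - g.selfed_fraction(mutant.s) * params.delta_a)
    f_mut = g.female(mutant.F)
    selfed = params.Pj * mutant.s * params.w_j * f_mut
    ovules = 0.5 * params.Pj * (1.0 - mutant.s) * f_mut
    pool = (1.0 - resident.s) * g.female(resident.F)
    if pool > 0.0:
        m_res = g.male(resident.M)
        if m_res <= 0.0:
            raise DegeneratePollenPoolError(
                "resident produces no pollen (m(M) = 0) while outcrossed "
                f"ovules exist ((1 - s) * f(F) = {pool})"
            )
        # ratio first: at mutant = resident it is exactly 1, making the
        # resident total bit-for-bit invariant to the pollen scale
        siring = 0.5 * params.Pj * pool * (g.male(mutant.M) / m_res)
    else:
        siring = 0.0
    return adult, selfed, ovules, siring


def female_fitness(
    mutant: Strategy,
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
) -> float:
    """Mutant fitness through the seed-parent role.

    Half the surviving-adult term, half the selfed-seed term (the ovule route
    of a selfed offspring's two gene copies) and the full outcrossed-ovule
    term.  ``female_fitness + male_fitness == total_fitness`` exactly.
    """
    adult, selfed, ovules, _ = _components(mutant, resident, params, gains)
    return 0.5 * adult + 0.5 * selfed + ovules


def male_fitness(
    mutant: Strategy,
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
) -> float:
    """Mutant fitness through the pollen-parent role.

    Half the surviving-adult term, the selfed-siring term (the pollen route
    of a selfed offspring's two gene copies) and the outcross-siring term
    (1/2) * Pj * (1 - s) * f(F) * m(M')/m(M).  The pollen scale m_max cancels
    in the siring ratio, so male fitness is invariant to it at any fixed
    mutant/resident pair under the default power curve.
    """
    adult, selfed, _, siring = _components(mutant, resident, params, gains)
    return 0.5 * adult + 0.5 * selfed + siring


def total_fitness(
    mutant: Strategy,
    resident: Strategy,
    params: LifeHistoryParams,
    gains: GainFunctions | None = None,
) -> float:
    """Total mutant fitness W = female_fitness + male_fitness.

    At mutant = resident with s = 0 this reduces to Pa(E) + Pj * f(F).  This
    is the single function every solver in the package differentiates or
    maximizes.
    """
    adult, selfed, ovules, siring = _components(mutant, resident, params, gains)
    # associate as (W_f) + (W_m) so the decomposition identity is exact
    return (0.5 * adult + 0.5 * selfed + ovules) + (0.5 * adult + 0.5 * selfed + siring)
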