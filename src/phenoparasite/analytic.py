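"""Closed-form disease-free results.

With no parasites (``alpha = 0`` or ``v_hat = 0``) the within-season system
is linear and decouples, so the probability that a host emerging at time
``e`` is alive as an adult at the season end ``T`` has an elementary form:
it must mature (rate ``l``) while escaping juvenile death (``mu_s``) and then
escape adult death (``mu_a``)::

    P(e) = l * exp(-mu_a*(T-e)) * (1 - exp(-k*(T-e))) / k,   k = mu_s + l - mu_a

Averaging P over the realized uniform emergence window gives the maturation
kernel ``phi(t0, tl)``: the per-capita probability that a member of the
scheduled cohort is a live adult at ``T`` (members scheduled after ``T``
never emerge and contribute zero).  The disease-free seasonal map is then
``s_hat -> eps*sigma*phi*s_hat / (1 + rho*phi*s_hat)`` whose nontrivial fixed
point is ``(eps*sigma*phi - 1) / (rho*phi)``.

These closed forms serve as an independent cross-check for the numerical
solver and the equilibrium iteration.
"""

from __future__ import annotations

import math

from .params import ModelParameters, PhenologyTraits

__all__ = ["maturation_probability_phi", "disease_free_equilibrium"]

_K_DEGENERATE = 1e-9


def _int_P(e1: float, e2: float, params: ModelParameters) -> float:
    """Exact integral of P(e) over [e1, e2] (both within [0, T])."""
    l, mu_s, mu_a, T = params.l, params.mu_s, params.mu_a, params.T
    k = mu_s + l - mu_a
    w1 = T - e1  # note w decreases as e increases
    w2 = T - e2
    if abs(k) > _K_DEGENERATE:
        term_a = (math.exp(-mu_a * w2) - math.exp(-mu_a * w1)) / mu_a
        c = mu_s + l
        term_b = (math.exp(-c * w2) - math.exp(-c * w1)) / c
        return (l / k) * (term_a - term_b)
    # k -> 0 limit: P(e) = l * (T-e) * exp(-mu_a*(T-e))
    c = mu_a

    def G(w: float) -> float:
        return -math.exp(-c * w) * (w / c + 1.0 / (c * c))

    return l * (G(w1) - G(w2))


def maturation_probability_phi(
    traits: PhenologyTraits, params: ModelParameters
) -> float:
    """Disease-free probability that a scheduled host is an adult at T.

    Averages the emergence-time-conditional survival/maturation probability
    over the uniform window [t0, t0+tl], truncated at the season end; the
    never-emerging tail contributes zero.
    """
    traits.validate_against(params)
    e1 = traits.t0
    e2 = min(traits.t0 + traits.tl, params.T)
    if e2 <= e1:
        return 0.0
    return _int_P(e1, e2, params) / traits.tl


def disease_free_equilibrium(
    traits: PhenologyTraits, params: ModelParameters
) -> float:
    """Equilibrium host cohort size with no parasites.

    Fixed point of the Beverton-Holt seasonal map with per-capita adult
    output ``phi``: ``(eps*sigma*phi - 1) / (rho*phi)`` when the basic
    reproduction factor ``eps*sigma*phi`` exceeds 1, else 0 (the host cannot
    replace itself and goes extinct).
    """
    phi = maturation_probability_phi(traits, params)
    r0 = params.epsilon * params.sigma * phi
    if r0 <= 1.0:
        return 0.0
    return (r0 - 1.0) / (params.rho * phi)
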