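"""Model parameters, phenology traits, and the between-season maps.

The model is semi-discrete: within a season of length ``T`` juvenile hosts
emerge, mature, and are attacked by a free-living sterilizing parasite
(continuous-time delay differential equations); between seasons the surviving
adults reproduce through a Beverton-Holt map and a fraction of the free
parasites carries over.  Everything in this module is the discrete/algebraic
part of that skeleton: the parameter set, the host emergence schedule
(a uniform pulse starting at ``t0`` lasting ``tl``), and the two
between-season maps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

__all__ = [
    "ModelParameters",
    "PhenologyTraits",
    "SeasonBoundaryState",
    "emergence_rate",
    "emerged_fraction",
    "next_season_cohort",
    "next_season_parasites",
]

#: Default lower bound on the emergence period length (the shortest pulse the
#: trait space allows; also the value used when tl is held fixed).
TL_MIN_DEFAULT = 0.5


@dataclass(frozen=True)
class ModelParameters:
    """All rate and size constants of the seasonal host-parasite model.

    Parameters
    ----------
    tau : float
        Parasite latency period: the fixed delay between infection of a
        juvenile host and the release of ``beta`` new parasites.  Infections
        that have not completed the latency period by the end of the season
        release nothing.  Required (it is the main environmental axis the
        analyses vary); all other parameters default to the standard set.
    alpha : float
        Density-dependent transmission rate, per parasite per unit time.
    beta : float
        Parasites released upon the death of one infected host.
    delta : float
        Decay rate of free parasites in the environment.
    mu_s, mu_a : float
        Background death rates of juvenile and adult hosts.
    l : float
        Maturation rate of juveniles into (infection-resistant) adults.
    gamma : float
        Probability that a free parasite survives between seasons.
    epsilon : float
        Probability that an adult host survives to reproduce between seasons.
    sigma : float
        Host fecundity (offspring per surviving adult).
    rho : float
        Strength of density dependence in host reproduction.
    T : float
        Season length.  Time units are deliberately unspecified; all rates
        share whatever unit ``T`` is expressed in.
    """

    tau: float
    alpha: float = 1e-6
    beta: float = 400.0
    delta: float = 2.0
    mu_s: float = 0.2
    mu_a: float = 0.015
    l: float = 1.0
    gamma: float = 0.9
    epsilon: float = 0.85
    sigma: float = 600.0
    rho: float = 1e-4
    T: float = 4.0

    def __post_init__(self) -> None:
        for name in ("tau", "alpha", "beta", "delta", "mu_s", "mu_a", "l",
                     "sigma", "rho", "T"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(
                    f"parameter {name!r} must be strictly positive and finite, "
                    f"got {value!r}"
                )
        for name in ("gamma", "epsilon"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(
                    f"parameter {name!r} is a probability and must lie in "
                    f"[0, 1], got {value!r}"
                )

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


@dataclass(frozen=True)
class PhenologyTraits:
    """The evolving host phenology pair: emergence start and period length.

    ``t0`` is the time within the season at which host emergence begins and
    ``tl`` the length of the emergence period; the cohort emerges uniformly on
    ``[t0, t0 + tl]``.  ``t0 + tl`` may exceed the season length ``T``, in
    which case the late tail of the cohort simply never emerges.

    ``tl_min`` is the hard lower bound of the ``tl`` trait axis (default 0.5,
    the shortest emergence period the trait space allows).
    """

    t0: float = 0.0
    tl: float = TL_MIN_DEFAULT
    tl_min: float = field(default=TL_MIN_DEFAULT, compare=False)

    def __post_init__(self) -> None:
        if not (self.t0 >= 0.0) or not math.isfinite(self.t0):
            raise ValueError(f"t0 must be finite and >= 0, got {self.t0!r}")
        if not math.isfinite(self.tl) or self.tl < self.tl_min:
            raise ValueError(
                f"tl must be >= tl_min ({self.tl_min}), got {self.tl!r}"
            )

    def replace(self, **changes: float) -> "PhenologyTraits":
        return replace(self, **changes)

    def validate_against(self, params: ModelParameters) -> None:
        """Check the season-length-dependent bound 0 <= t0 <= T."""
        if self.t0 > params.T:
            raise ValueError(
                f"t0 ({self.t0}) exceeds the season length T ({params.T})"
            )


@dataclass(frozen=True)
class SeasonBoundaryState:
    """State handed across a season boundary.

    ``s_hat`` is the size of the host cohort scheduled to emerge this season
    and ``v_hat`` the free-parasite density present at the season start
    (``t = 0``); ``n`` is the season index.
    """

    s_hat: float
    v_hat: float
    n: int = 1

    def __post_init__(self) -> None:
        if self.s_hat < 0 or self.v_hat < 0:
            raise ValueError(
                f"boundary densities must be nonnegative, got "
                f"s_hat={self.s_hat!r}, v_hat={self.v_hat!r}"
            )
        if self.n < 1:
            raise ValueError(f"season index must be >= 1, got {self.n!r}")


def emergence_rate(t: float, traits: PhenologyTraits) -> float:
    """Per-capita host emergence rate at time ``t`` within the season.

    A uniform pulse: 0 before ``t0``, ``1/tl`` on ``[t0, t0 + tl]``, 0 after.
    Integrates to 1 over the full window, or to ``(T - t0)/tl`` if the window
    is truncated by the season end.
    """
    if traits.t0 <= t <= traits.t0 + traits.tl:
        return 1.0 / traits.tl
    return 0.0


def emerged_fraction(traits: PhenologyTraits, params: ModelParameters) -> float:
    """Fraction of the scheduled cohort that actually emerges before ``T``."""
    return min(1.0, max(0.0, (params.T - traits.t0) / traits.tl))


def next_season_cohort(a_T: float, params: ModelParameters) -> float:
    """Beverton-Holt reproduction map: next season's emerging cohort.

    ``s_hat(n+1) = epsilon * sigma * a_T / (1 + rho * a_T)`` where ``a_T`` is
    the adult density surviving to the end of season ``n``.  Saturates at
    ``epsilon * sigma / rho``.
    """
    if a_T < 0:
        raise ValueError(f"adult density must be nonnegative, got {a_T!r}")
    return params.epsilon * params.sigma * a_T / (1.0 + params.rho * a_T)


def next_season_parasites(v_T: float, params: ModelParameters) -> float:
    """Parasite carryover map: ``v_hat(n+1) = gamma * v_T``."""
    if v_T < 0:
        raise ValueError(f"parasite density must be nonnegative, got {v_T!r}")
    return params.gamma * v_T
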