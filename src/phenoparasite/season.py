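"""Within-season dynamics: delay differential equations on [0, T].

The resident system tracks susceptible juveniles ``s``, infection-resistant
adults ``a`` and free parasites ``v``::

    ds/dt = s_hat * g(t; t0, tl) - mu_s*s - alpha*s*v - l*s
    da/dt = l*s - mu_a*a
    dv/dt = alpha*beta*exp(-mu_s*tau) * s(t-tau)*v(t-tau) - delta*v

with ``s(0) = a(0) = 0`` and ``v(0) = v_hat``.  The delayed term is zero for
``t < tau`` (there are no pre-season infections) and parasite loss to
transmission is neglected, the usual assumption for free-living parasites.
Infections initiated after ``T - tau`` therefore never contribute progeny
within the season.

The invasion variant adds a rare mutant juvenile/adult pair driven by its own
emergence schedule; the parasite equation is forced by the summed delayed
infections of resident and mutant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernel import STEPS_PER_UNIT, build_grid, integrate_season_kernel
from .params import (
    ModelParameters,
    PhenologyTraits,
    SeasonBoundaryState,
    emerged_fraction,
)

__all__ = ["SeasonTrajectory", "SeasonSummary", "integrate_season",
           "integrate_season_with_mutant"]

#: Negative excursions larger than this (relative to the emerging cohort)
#: indicate the step size is too coarse for the given parameters.
_NEG_TOL = 1e-8


@dataclass(frozen=True)
class SeasonSummary:
    """End-of-season scalars for one season.

    ``emerged`` is the number of hosts that actually emerged (the scheduled
    cohort times the realized window fraction), ``infections`` the cumulative
    number of infection events C(T), and ``prevalence`` their ratio (0 when
    nothing emerged).  Mutant fields are None unless a mutant was present.
    """

    a_T: float
    v_T: float
    emerged: float
    infections: float
    prevalence: float
    a_T_mutant: float | None = None
    emerged_mutant: float | None = None
    infections_mutant: float | None = None


class SeasonTrajectory:
    """Dense within-season solution sampled on the integration grid.

    Attributes
    ----------
    t : ndarray
        Grid times in [0, T] (breakpoint-refined, so spacing is not exactly
        uniform).
    s, a, v, cum_infections : ndarray
        Resident juveniles, adults, free parasites, and cumulative infection
        events at each grid node.
    s_m, a_m, cum_infections_m : ndarray or None
        Mutant analogues when a mutant cohort was integrated.
    """

    def __init__(self, t: np.ndarray, states: np.ndarray, has_mutant: bool):
        self.t = t
        self._states = states
        self.has_mutant = has_mutant

    @property
    def s(self) -> np.ndarray:
        return self._states[:, 0]

    @property
    def a(self) -> np.ndarray:
        return self._states[:, 1]

    @property
    def v(self) -> np.ndarray:
        return self._states[:, 2]

    @property
    def cum_infections(self) -> np.ndarray:
        return self._states[:, 3]

    @property
    def s_m(self) -> np.ndarray | None:
        return self._states[:, 4] if self.has_mutant else None

    @property
    def a_m(self) -> np.ndarray | None:
        return self._states[:, 5] if self.has_mutant else None

    @property
    def cum_infections_m(self) -> np.ndarray | None:
        return self._states[:, 6] if self.has_mutant else None

    def __call__(self, times: np.ndarray) -> np.ndarray:
        """Linearly interpolate all state columns at the requested times."""
        times = np.asarray(times, dtype=float)
        ncol = 7 if self.has_mutant else 4
        out = np.empty((times.size, ncol))
        for j in range(ncol):
            out[:, j] = np.interp(times, self.t, self._states[:, j])
        return out

    def to_frame(self, times: np.ndarray | None = None) -> pd.DataFrame:
        """Trajectory as a DataFrame, optionally resampled on ``times``."""
        cols = ["s", "a", "v", "cum_infections"]
        if self.has_mutant:
            cols += ["s_m", "a_m", "cum_infections_m"]
        if times is None:
            t = self.t
            data = self._states[:, : len(cols)]
        else:
            t = np.asarray(times, dtype=float)
            data = self(t)
        frame = pd.DataFrame(data, columns=cols)
        frame.insert(0, "t", t)
        return frame


def _run(
    boundary: SeasonBoundaryState,
    traits: PhenologyTraits,
    params: ModelParameters,
    mutant_cohort: float,
    mutant_traits: PhenologyTraits | None,
    steps_per_unit: int,
    grid: np.ndarray | None,
    out: np.ndarray | None,
) -> tuple[SeasonTrajectory, SeasonSummary]:
    traits.validate_against(params)
    has_mutant = mutant_traits is not None
    if has_mutant:
        mutant_traits.validate_against(params)
        if mutant_cohort < 0:
            raise ValueError("mutant cohort must be nonnegative")
        t0m, tlm = mutant_traits.t0, mutant_traits.tl
    else:
        mutant_cohort, t0m, tlm = 0.0, 0.0, 0.0

    if grid is None:
        edges = [traits.t0, traits.t0 + traits.tl]
        if has_mutant:
            edges += [t0m, t0m + tlm]
        grid = build_grid(params.T, params.tau, tuple(edges), steps_per_unit)
    if out is None or out.shape[0] != grid.shape[0]:
        out = np.empty((grid.shape[0], 7))

    worst = integrate_season_kernel(
        grid, boundary.v_hat, boundary.s_hat, traits.t0, traits.tl,
        mutant_cohort, t0m, tlm,
        params.alpha, params.beta, params.delta, params.mu_s, params.mu_a,
        params.l, params.tau, out,
    )
    scale = max(boundary.s_hat, mutant_cohort, boundary.v_hat, 1.0)
    if worst < -_NEG_TOL * scale:
        raise RuntimeError(
            f"within-season integration produced a negative state "
            f"({worst:.3e} against scale {scale:.3e}); decrease the step "
            f"size (steps_per_unit={steps_per_unit})"
        )

    emerged = boundary.s_hat * emerged_fraction(traits, params)
    infections = float(out[-1, 3])
    summary = SeasonSummary(
        a_T=float(out[-1, 1]),
        v_T=float(out[-1, 2]),
        emerged=emerged,
        infections=infections,
        prevalence=infections / emerged if emerged > 0 else 0.0,
        a_T_mutant=float(out[-1, 5]) if has_mutant else None,
        emerged_mutant=(
            mutant_cohort * emerged_fraction(mutant_traits, params)
            if has_mutant else None
        ),
        infections_mutant=float(out[-1, 6]) if has_mutant else None,
    )
    return SeasonTrajectory(grid, out, has_mutant), summary


def integrate_season(
    boundary: SeasonBoundaryState,
    traits: PhenologyTraits,
    params: ModelParameters,
    steps_per_unit: int = STEPS_PER_UNIT,
    _grid: np.ndarray | None = None,
    _out: np.ndarray | None = None,
) -> tuple[SeasonTrajectory, SeasonSummary]:
    """Integrate one resident-only season.

    Parameters
    ----------
    boundary : SeasonBoundaryState
        Emerging cohort size and starting parasite density for this season.
    traits : PhenologyTraits
        Resident emergence schedule (t0, tl).
    params : ModelParameters
        Model constants.
    steps_per_unit : int
        RK4 steps per unit time (accuracy knob).

    Returns
    -------
    (SeasonTrajectory, SeasonSummary)
    """
    return _run(boundary, traits, params, 0.0, None, steps_per_unit,
                _grid, _out)


def integrate_season_with_mutant(
    boundary: SeasonBoundaryState,
    mutant_cohort: float,
    resident_traits: PhenologyTraits,
    mutant_traits: PhenologyTraits,
    params: ModelParameters,
    steps_per_unit: int = STEPS_PER_UNIT,
    _grid: np.ndarray | None = None,
    _out: np.ndarray | None = None,
) -> tuple[SeasonTrajectory, SeasonSummary]:
    """Integrate one season with a rare mutant cohort alongside the resident.

    The mutant juveniles and adults obey the same dynamics under their own
    emergence schedule; resident and mutant infections jointly drive the
    parasite equation.  The invasion analysis introduces exactly one mutant
    host (``mutant_cohort = 1``).
    """
    return _run(boundary, resident_traits, params, float(mutant_cohort),
                mutant_traits, steps_per_unit, _grid, _out)
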