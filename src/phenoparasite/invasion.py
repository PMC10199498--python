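"""Evolutionary invasion analysis of host phenology.

A rare mutant host (a single founder) is introduced into the seasonal
environment set by a resident at its long-run boundary state.  Its invasion
fitness is the size of the mutant cohort emerging next season,

    fitness = eps * sigma * a_m(T) / (1 + rho * a(T)),

where ``a_m(T)`` is the mutant adult density at the season end and ``a(T)``
the resident's: a measure-zero mutant experiences the density dependence set
by the resident population, which also makes resident-vs-self neutrality
exact.  The mutant invades when fitness >= 1.  Evolutionary endpoints
(optimal ``t0*`` or ``tl*``) are located by trait substitution: repeatedly
test nearby mutants and move the resident in the invading direction until no
nearby mutant can invade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._kernel import STEPS_PER_UNIT
from .params import ModelParameters, PhenologyTraits, SeasonBoundaryState
from .season import integrate_season_with_mutant
from .seasons import DEFAULT_INITIAL, EquilibriumResult, equilibrium

__all__ = [
    "InvasionResult", "EssResult", "PipGrid", "DensityLandscape",
    "invasion_fitness", "selection_gradient", "find_ess",
    "pairwise_invasibility", "density_landscape",
]

#: Seasons run to set the resident environment before introducing a mutant.
#: A fixed count (not a tolerance) is used so that the tiny-but-positive
#: parasite density near the extinction boundary — part of the selective
#: environment — is well defined.
RESIDENT_SEASONS = 300

#: A probe mutant must exceed fitness 1 by this margin to count as invading;
#: guards against registering round-off around exact neutrality as selection.
INVASION_TOL = 1e-10


@dataclass(frozen=True)
class InvasionResult:
    """Invasion fitness of one mutant against one resident."""

    fitness: float
    invades: bool
    resident_equilibrium: tuple[float, float]  # (s_hat*, v_hat*)
    resident_converged: bool = True


@dataclass
class EssResult:
    """Outcome of a single-trait evolutionary endpoint search."""

    trait_name: str
    value: float
    trajectory: list[float]
    converged: bool
    status: str
    resident_equilibrium_at_ess: EquilibriumResult | None = None


@dataclass
class PipGrid:
    """Pairwise invasibility plot: fitness over resident x mutant grids."""

    trait_name: str
    resident_values: np.ndarray
    mutant_values: np.ndarray
    fitness: np.ndarray  # shape (len(resident_values), len(mutant_values))

    def sign_matrix(self) -> np.ndarray:
        """+1 where the mutant invades (fitness >= 1), -1 elsewhere."""
        return np.where(self.fitness >= 1.0, 1, -1)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            self.fitness,
            index=pd.Index(self.resident_values, name="resident"),
            columns=pd.Index(self.mutant_values, name="mutant"),
        )
        return frame

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class DensityLandscape:
    """Equilibrium host cohort over a (t0, tl) trait grid."""

    t0_values: np.ndarray
    tl_values: np.ndarray
    s_star: np.ndarray  # shape (len(t0_values), len(tl_values)); NaN = failed
    with_parasites: bool
    failures: list[tuple[float, float, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.s_star,
            index=pd.Index(self.t0_values, name="t0"),
            columns=pd.Index(self.tl_values, name="tl"),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _trait_bounds(trait_name: str, traits: PhenologyTraits,
                  params: ModelParameters) -> tuple[float, float]:
    if trait_name == "t0":
        return 0.0, params.T
    if trait_name == "tl":
        return traits.tl_min, params.T
    raise ValueError(f"unknown trait {trait_name!r}; expected 't0' or 'tl'")


def _with_trait(traits: PhenologyTraits, trait_name: str,
                value: float) -> PhenologyTraits:
    return traits.replace(**{trait_name: value})


def _mutant_fitness_in_env(
    mutant: PhenologyTraits,
    resident: PhenologyTraits,
    params: ModelParameters,
    env: EquilibriumResult,
    steps_per_unit: int,
) -> float:
    boundary = SeasonBoundaryState(s_hat=env.s_hat, v_hat=env.v_hat)
    _, summary = integrate_season_with_mutant(
        boundary, 1.0, resident, mutant, params, steps_per_unit
    )
    return (params.epsilon * params.sigma * summary.a_T_mutant
            / (1.0 + params.rho * summary.a_T))


def invasion_fitness(
    mutant: PhenologyTraits,
    resident: PhenologyTraits,
    params: ModelParameters,
    initial: SeasonBoundaryState = DEFAULT_INITIAL,
    n_seasons: int = RESIDENT_SEASONS,
    resident_env: EquilibriumResult | None = None,
    steps_per_unit: int = STEPS_PER_UNIT,
) -> InvasionResult:
    """Invasion fitness of ``mutant`` against ``resident`` at its attractor.

    The resident environment is obtained by running ``n_seasons`` seasons
    from ``initial`` (or supplied directly via ``resident_env``); a single
    mutant host is then introduced for one season and its per-founder
    next-season cohort is the fitness.
    """
    if resident_env is None:
        resident_env = equilibrium(
            resident, params, initial, n_fixed=n_seasons,
            steps_per_unit=steps_per_unit,
        )
    fitness = _mutant_fitness_in_env(
        mutant, resident, params, resident_env, steps_per_unit
    )
    return InvasionResult(
        fitness=fitness,
        invades=fitness >= 1.0,
        resident_equilibrium=(resident_env.s_hat, resident_env.v_hat),
        resident_converged=resident_env.converged,
    )


def selection_gradient(
    trait_name: str,
    resident: PhenologyTraits,
    params: ModelParameters,
    h: float = 0.01,
    initial: SeasonBoundaryState = DEFAULT_INITIAL,
    n_seasons: int = RESIDENT_SEASONS,
    steps_per_unit: int = STEPS_PER_UNIT,
) -> float:
    """Finite-difference selection gradient of invasion fitness.

    Central difference ``(w(x+h) - w(x-h)) / (2h)`` on the mutant trait at
    the resident value ``x``; one-sided where a trait bound makes a probe
    infeasible.
    """
    if h <= 0:
        raise ValueError("probe step h must be positive")
    lo, hi = _trait_bounds(trait_name, resident, params)
    x = getattr(resident, trait_name)
    up = x + h if x + h <= hi else None
    down = x - h if x - h >= lo else None
    if up is None and down is None:
        raise ValueError(
            f"no feasible probe around {trait_name}={x} with h={h}"
        )
    env = equilibrium(resident, params, initial, n_fixed=n_seasons,
                      steps_per_unit=steps_per_unit)

    def w(value: float) -> float:
        return _mutant_fitness_in_env(
            _with_trait(resident, trait_name, value), resident, params, env,
            steps_per_unit,
        )

    if up is None:
        return (w(x) - w(down)) / h
    if down is None:
        return (w(up) - w(x)) / h
    return (w(up) - w(down)) / (2.0 * h)


def find_ess(
    trait_name: str,
    start: float,
    params: ModelParameters,
    traits: PhenologyTraits | None = None,
    step: float = 0.01,
    h: float | None = None,
    max_iter: int = 1000,
    initial: SeasonBoundaryState = DEFAULT_INITIAL,
    n_seasons: int = RESIDENT_SEASONS,
    steps_per_unit: int = STEPS_PER_UNIT,
) -> EssResult:
    """Locate the evolutionary endpoint of one phenology trait.

    Trait-substitution dynamics: at each iteration the resident's long-run
    environment is recomputed, mutants one probe step ``h`` (default equal to
    ``step``) to either side are tested, and the resident moves by ``step``
    in the invading direction.  The search stops when neither probe invades
    (an evolutionarily stable point at the search resolution), when an active
    bound blocks the only invading direction, or when the substitution
    sequence revisits a state (reported honestly via ``status``).

    ``traits`` supplies the non-evolving trait's fixed value (defaults:
    t0 = 0, tl = 0.5).
    """
    if traits is None:
        traits = PhenologyTraits()
    if h is None:
        h = step
    if step <= 0 or h <= 0:
        raise ValueError("step and h must be positive")
    lo, hi = _trait_bounds(trait_name, traits, params)
    if not (lo <= start <= hi):
        raise ValueError(
            f"start {start} outside [{lo}, {hi}] for trait {trait_name!r}"
        )

    def snap(value: float) -> float:
        # keep resident values on the step lattice anchored at the lower
        # bound, so repeated +/- step cannot drift off it in floating point
        return min(hi, max(lo, lo + round((value - lo) / step) * step))

    def probe_fitnesses(x: float) -> tuple[float | None, float | None,
                                           EquilibriumResult]:
        resident = _with_trait(traits, trait_name, x)
        env = equilibrium(resident, params, initial, n_fixed=n_seasons,
                          steps_per_unit=steps_per_unit)
        w_up = w_down = None
        if x + h <= hi + 1e-9:
            w_up = _mutant_fitness_in_env(
                _with_trait(traits, trait_name, min(x + h, hi)), resident,
                params, env, steps_per_unit)
        if x - h >= lo - 1e-9:
            w_down = _mutant_fitness_in_env(
                _with_trait(traits, trait_name, max(x - h, lo)), resident,
                params, env, steps_per_unit)
        return w_up, w_down, env

    def invades(w: float | None) -> bool:
        return w is not None and w >= 1.0 + INVASION_TOL

    x = snap(float(start))
    trajectory = [x]
    status = "max_iter"
    converged = False
    env = None
    for _ in range(max_iter):
        w_up, w_down, env = probe_fitnesses(x)
        up, down = invades(w_up), invades(w_down)
        if not up and not down:
            converged = True
            status = "ess" if (w_up is not None and w_down is not None) \
                else "bound"
            break
        if up and down:
            direction = 1.0 if w_up >= w_down else -1.0
        else:
            direction = 1.0 if up else -1.0
        x_new = snap(x + direction * step)
        if len(trajectory) >= 2 and abs(x_new - trajectory[-2]) < 1e-12:
            # 2-cycle: the endpoint lies between x and x_new at this
            # resolution; keep the point closer to evolutionary stability
            w_up2, w_down2, env2 = probe_fitnesses(x_new)
            m1 = max(w for w in (w_up, w_down) if w is not None)
            m2 = max(w for w in (w_up2, w_down2) if w is not None)
            if m2 < m1:
                x, env = x_new, env2
            trajectory.append(x_new)
            converged = True
            status = "cycle"
            break
        x = x_new
        trajectory.append(x)
    resident = _with_trait(traits, trait_name, x)
    if env is None:  # pragma: no cover - max_iter = 0 style edge
        env = equilibrium(resident, params, initial, n_fixed=n_seasons,
                          steps_per_unit=steps_per_unit)
    return EssResult(
        trait_name=trait_name,
        value=x,
        trajectory=trajectory,
        converged=converged,
        status=status,
        resident_equilibrium_at_ess=env,
    )


def pairwise_invasibility(
    trait_name: str,
    grid: np.ndarray,
    params: ModelParameters,
    traits: PhenologyTraits | None = None,
    initial: SeasonBoundaryState = DEFAULT_INITIAL,
    n_seasons: int = RESIDENT_SEASONS,
    steps_per_unit: int = STEPS_PER_UNIT,
) -> PipGrid:
    """Invasion fitness for every (resident, mutant) pair on a trait grid.

    One resident environment is computed per grid value and reused across
    that row's mutants.  Singular strategies appear where the fitness sign
    changes across the diagonal.
    """
    if traits is None:
        traits = PhenologyTraits()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D array")
    lo, hi = _trait_bounds(trait_name, traits, params)
    if grid[0] < lo or grid[-1] > hi:
        raise ValueError(f"grid outside trait bounds [{lo}, {hi}]")
    fitness = np.empty((grid.size, grid.size))
    for i, res_value in enumerate(grid):
        resident = _with_trait(traits, trait_name, res_value)
        env = equilibrium(resident, params, initial, n_fixed=n_seasons,
                          steps_per_unit=steps_per_unit)
        for j, mut_value in enumerate(grid):
            fitness[i, j] = _mutant_fitness_in_env(
                _with_trait(traits, trait_name, mut_value), resident,
                params, env, steps_per_unit)
    return PipGrid(trait_name=trait_name, resident_values=grid,
                   mutant_values=grid, fitness=fitness)


def density_landscape(
    t0_values: np.ndarray,
    tl_values: np.ndarray,
    params: ModelParameters,
    n_seasons: int = 100,
    with_parasites: bool = True,
    initial: SeasonBoundaryState = DEFAULT_INITIAL,
    steps_per_unit: int = STEPS_PER_UNIT,
) -> DensityLandscape:
    """Equilibrium host cohort size over a (t0, tl) grid.

    With ``with_parasites=False`` the run starts with zero parasites, giving
    the disease-free landscape (whose maximum is always the earliest,
    shortest emergence).  Per-cell failures are recorded and leave NaN in the
    grid rather than aborting the sweep.
    """
    t0_values = np.asarray(t0_values, dtype=float)
    tl_values = np.asarray(tl_values, dtype=float)
    s_star = np.full((t0_values.size, tl_values.size), np.nan)
    failures: list[tuple[float, float, str]] = []
    if not with_parasites:
        initial = SeasonBoundaryState(s_hat=initial.s_hat, v_hat=0.0)
    for i, t0 in enumerate(t0_values):
        for j, tl in enumerate(tl_values):
            try:
                traits = PhenologyTraits(t0=t0, tl=tl)
                env = equilibrium(traits, params, initial,
                                  n_fixed=n_seasons,
                                  steps_per_unit=steps_per_unit)
                s_star[i, j] = env.s_hat
            except (ValueError, RuntimeError) as err:
                failures.append((float(t0), float(tl), str(err)))
    return DensityLandscape(t0_values=t0_values, tl_values=tl_values,
                            s_star=s_star, with_parasites=with_parasites,
                            failures=failures)
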