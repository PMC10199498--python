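# Methods

## The model

`phenoparasite` implements a semi-discrete model of a free-living,
sterilizing parasite attacking a seasonally emerging, univoltine host.
Within a season of length `T` the state is `(s, a, v)`: susceptible
juveniles, infection-resistant adults, and free parasite propagules.  The
host cohort `ŝ_n` scheduled for season `n` emerges at the uniform per-capita
rate `g(t) = 1/tl` on the window `[t0, t0 + tl]` (zero outside it); if
`t0 + tl > T` the late tail of the cohort simply never emerges.  The
within-season dynamics are delay differential equations:

    ds/dt = ŝ_n g(t) − μ_s s − α s v − l s
    da/dt = l s − μ_a a
    dv/dt = α β e^(−μ_s τ) s(t−τ) v(t−τ) − δ v

A host infected at time `u` is sterilized (leaves `s`, never reaches `a`);
if it survives the latency period `τ` (probability `e^(−μ_s τ)`) it releases
`β` new parasites at `u + τ`.  Two standard simplifications are built in:
parasite loss to transmission is neglected (the usual free-living-parasite
assumption), and infections that have not completed the latency period by
the season end release nothing — the delayed term is identically zero for
`t < τ`, so there are no cross-season infections.  The season starts with
`s(0) = a(0) = 0` and `v(0) = v̂_n`.

Between seasons, surviving adults reproduce through a Beverton–Holt map and
free parasites carry over with probability `γ`:

    ŝ_{n+1} = ε σ a_n(T) / (1 + ρ a_n(T)),      v̂_{n+1} = γ v_n(T)

Time is deliberately unitless; `T = 4` in the default set.

### Default parameters

The shipped configuration (`phenoparasite/data/default.yaml`) is the
standard set used throughout: `α = 1e−6`, `β = 400`, `δ = 2`, `μ_s = 0.2`,
`μ_a = 0.015`, `l = 1`, `γ = 0.9`, `ε = 0.85`, `σ = 600`, `ρ = 1e−4`,
`T = 4`.  The latency period `τ` has no default in the API (it is the main
environmental axis; the analyses use 1.5 for a short-latency parasite that
completes several infection generations per season and 3 for a long-latency
parasite that completes one).  When a phenology trait is held fixed it sits
at `t0 = 0`, `tl = 0.5`; `tl` has a hard floor `tl_min = 0.5` (the shortest
emergence period the trait space allows, configurable).

## Numerical integration

The season is integrated by the method of steps on a breakpoint-refined
fixed grid.  The vector field is non-smooth at the emergence-pulse edges
(`t0`, `t0 + tl`, and the mutant pair when present), at the delay onset
`τ`, and at every forward shift of these by multiples of `τ`
(discontinuities propagate through the delay).  All such points are inserted
into a uniform mesh (default 2000 steps per unit time, so a step of 5e−4),
and one classical RK4 step is taken per grid interval; the emergence rate is
evaluated at the interval midpoint, which is exact because no interval
straddles a pulse edge.  The delayed product `s(t−τ) v(t−τ)` is read back
from the stored dense history by linear interpolation — the delay always
exceeds the step, so the lookup never runs ahead of the integration front.
Interpolating the history limits the scheme's formal order, but at the
default step the season-end states are converged to well below 1e−6
relative (checked by step-halving and against an independent explicit-Euler
oracle); with no infections the solution matches closed forms to machine
accuracy.  The kernel is numba-compiled; a full 300-season run costs a few
tenths of a second.

Densities are clipped to zero when RK4 produces negative excursions at
pulse edges; excursions beyond 1e−8 relative to the run's scale abort the
run with a diagnostic, as they indicate the step is too coarse.

Cumulative infection events `C(t) = ∫ α s v dt` are integrated alongside
the state.  Prevalence is reported as `C(T)` divided by the number of hosts
that actually emerged.  (An alternative normalization by the scheduled
cohort `ŝ_n` differs only when `t0 + tl > T`; prevalence curves should not
be over-interpreted, as the quantity is a reporting convention, not part of
the dynamics.)

## Equilibria

The seasonal iteration settles to stable end-of-season densities for the
parameter ranges targeted here; no host–parasite cycling was observed.
`equilibrium` supports two stopping rules: iterate until the boundary state
stops changing (relative tolerance, default 1e−8, with an absolute floor for
near-extinct parasites), or run a prescribed number of seasons (`n_fixed`).
The second mode exists because near the parasite-extinction boundary the
tiny-but-positive parasite density after `n` seasons is part of the
selective environment: selection for later emergence vanishes only because
the residual parasite population is negligible, and that residual depends on
`n`.  Parasite boundary densities below 1e−30 are flagged as extinct, but
the state is never forcibly zeroed — the deterministic dynamics cannot reach
exact zero, and zeroing would distort selection near the boundary.

Default initial densities are `ŝ_1 = v̂_1 = 1e4`.  Equilibria are attractor
properties; the test suite verifies independence from the starting point to
better than 1e−3 relative over a grid of initials.

### Disease-free closed form

With no parasites the system is linear and the probability that a host
emerging at time `e` is a live adult at `T` is

    P(e) = l e^(−μ_a (T−e)) (1 − e^(−k (T−e))) / k,   k = μ_s + l − μ_a

(with the analytic `k → 0` limit at the degenerate rate combination, not a
numerical epsilon).  Averaging over the realized emergence window gives the
maturation kernel `φ(t0, tl)`, and the disease-free equilibrium cohort is
`ŝ* = (ε σ φ − 1)/(ρ φ)` when `ε σ φ > 1`, else 0.  These closed forms are
the package's independent cross-check surface for the DDE solver and the
season iteration.

A consequence worth noting: `P(e)` is not monotone.  It peaks near
`e ≈ 0.3` under the default parameters, because emerging in the very first
instant maximizes time spent exposed to adult mortality while the risk of
failing to mature is still negligible.  `φ(t0)` therefore has a shallow
interior maximum near `t0 ≈ 0.04` rather than exactly at 0, and the
disease-free ESS search stops there (within one mutation step of the
bound).  The effect is tiny (relative fitness differences of order 1e−4)
but real, and the invasion analysis resolves it.

## Evolutionary invasion analysis

A rare mutant (a single founder, cohort 1) is introduced into the
environment set by a resident at its long-run boundary state
(`n_fixed = 300` seasons by default).  The five-equation invasion system
adds mutant juveniles and adults under the mutant's own emergence schedule;
resident and mutant delayed infections jointly drive the parasite equation.
Invasion fitness is the mutant cohort emerging next season,

    w = ε σ a_m(T) / (1 + ρ a(T)),

with the *resident's* adult density in the density-dependence denominator: a
measure-zero mutant experiences the resident-set competition, and this
choice makes resident-vs-self neutrality exact (the summed infection term
already makes it exact to O(1/ŝ*) ≈ 1e−6; tests require 1e−4).  The mutant
invades when `w ≥ 1`, with a 1e−10 margin in the search so round-off around
exact neutrality is never read as selection.

`find_ess` runs trait-substitution dynamics: recompute the resident
environment, probe mutants one step `h` to either side (default
`h = step = 0.01`), move the resident by `step` in the invading direction
(the direction of larger fitness if both invade), and stop when neither
probe invades or when an active bound blocks the only invading direction.
Resident trait values are snapped to the step lattice anchored at the lower
bound, so repeated stepping cannot drift off it in floating point.  If the
substitution sequence enters a 2-cycle — which happens when the endpoint
lies between two lattice points, typically at the parasite-persistence
boundary — the member of the cycle with the smaller worst-probe fitness is
reported and the outcome is labelled `cycle` rather than hidden.  One trait
evolves at a time; the other stays at its held-constant default.

The optima under parasites have a transparent mechanical reading: along the
`t0` axis the endpoint coincides with the parasite-persistence boundary (the
phenology at which the parasite's per-season low-density multiplication
factor crosses 1), while along the `tl` axis with a long-latency parasite
the endpoint is interior, balancing infection avoidance against the reduced
maturation probability of late-emerging cohort members.

`pairwise_invasibility` computes the full resident × mutant fitness matrix
over a grid (one resident environment per row, reused across mutants) as a
cross-check that sign changes bracket the endpoints found by substitution;
`density_landscape` maps equilibrium host density over the `(t0, tl)` plane
with and without parasites.

## What the defaults do and do not show

All headline numbers are attractor or endpoint properties of the
deterministic model at the default parameter set and season counts
(`n = 150` for equilibria, `n = 300` per resident in the invasion
analysis; these match the settings the reference values were printed
under).  The model has no demographic stochasticity, no parasite evolution,
a uniform emergence pulse, and one parasite strain; conclusions about real
systems inherit those assumptions.  Near the parasite-persistence boundary
results are knife-edge by construction: at `τ = 3` the boundary falls
between `t0 = 0.91` (marginal persistence; the parasite first collapses by
three orders of magnitude, then regrows over hundreds of seasons to a
low-prevalence attractor that still leaves host density within 0.2% of the
disease-free value) and `t0 = 0.92` (clean geometric extinction).  Reported
optima are resolved to the search step (0.01) and should be read at that
resolution.

## Known limitations

- The fixed-grid kernel requires `τ` to exceed a few integration steps
  (enforced); latency periods far below the default range would need a
  finer mesh.
- `selection_gradient` is a finite difference of an already-iterated
  quantity; probe steps much below 1e−3 amplify equilibrium round-off.
- The baseline parasitized equilibrium at the earliest/shortest phenology
  is a high-prevalence state (98.9% of emerged hosts infected,
  `ŝ* ≈ 3.98e6` at `τ = 3`): the parasite's low-density per-season
  multiplication factor at the disease-free attractor is ≈ 66, so the
  parasite amplifies until host depletion stops it.  Solver validation
  (independent Euler oracle, closed-form cross-checks, step-halving) shows
  this is a genuine property of the equations as implemented, not a
  numerical artifact.  Analyses that assume a mild-suppression baseline at
  this phenology will not match this model.
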