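# phenoparasite

Seasonal host–parasite dynamics and the evolution of host phenology under
parasite-mediated selection.

## The problem

Host phenology — when seasonal activity starts (`t0`) and how spread out it
is (`tl`) — shapes infection risk: a free-living, sterilizing parasite is
most abundant at the start of the season, so hosts that emerge early mature
and reproduce best but are also infected most.  This package asks when
parasite avoidance pays: it simulates a univoltine host attacked by a
parasite with a fixed latency period `τ` and finds the evolutionarily
optimal emergence schedule by invasion analysis.  It is written for
theoretical ecologists and disease modelers who want a reproducible,
well-tested implementation of this class of semi-discrete
(continuous-within-season, discrete-between-season) models.

## The model

Within a season of length `T`, juveniles `s`, adults `a` and free parasites
`v` obey delay differential equations

    ds/dt = ŝₙ g(t; t0, tl) − μₛ s − α s v − l s
    da/dt = l s − μₐ a
    dv/dt = α β e^(−μₛ τ) s(t−τ) v(t−τ) − δ v

where `g` is a uniform emergence pulse on `[t0, t0 + tl]`, infection (rate
`α v`) sterilizes, and each infected host that survives the latency period
`τ` releases `β` parasites.  Between seasons, adults reproduce through a
Beverton–Holt map `ŝₙ₊₁ = ε σ a(T) / (1 + ρ a(T))` and parasites carry over
as `v̂ₙ₊₁ = γ v(T)`.  A rare mutant's invasion fitness is its per-founder
next-season cohort in the environment set by the resident at its seasonal
attractor; trait-substitution search on `t0` or `tl` locates the
evolutionary endpoints (`t0*`, `tl*`).  See `docs/methods.md` for the full
model, numerics and design choices.

## Worked example

The library surface:

```python
from phenoparasite import ModelParameters, PhenologyTraits, find_ess

params = ModelParameters(tau=1.5)          # short-latency parasite
result = find_ess("t0", start=0.0, params=params)
print(result.value)                        # 2.13
```

Or from the shell.  Disease-free reference point (closed form):

```
$ phenoparasite phi --tau 3
{
  "phi": 0.7882098002148311,
  "s_hat_star_disease_free": 5087313.022500767,
  "t0": 0.0,
  "tl": 0.5
}
```

`phi` is the probability that a host from the earliest, shortest emergence
schedule is a live adult at the season end; the corresponding disease-free
equilibrium cohort is 5.09 million hosts.  Add a long-latency parasite and
iterate 150 seasons:

```
$ phenoparasite equilibrium --tau 3 --n-fixed 150
{
  "converged": true,
  "n_used": 150,
  "parasites_extinct": false,
  "prevalence": 0.9887156777830294,
  "s_hat": 3975920.9785983274,
  "v_hat": 184248261.24552274
}
```

At the early/short phenology the parasite amplifies until nearly every
emerged host is infected (prevalence 0.99); strong density-dependent
compensation keeps the host cohort at 3.98 million.  Now let the emergence
start evolve:

```
$ phenoparasite evolve --tau 3 --trait t0 --start 0
{
  "converged": true,
  "iterations": 94,
  "prevalence_star": 2.748671772476152e-29,
  "s_hat_star": 5087181.272483987,
  "status": "cycle",
  "trait_name": "t0",
  "v_hat_star": 7.182971492147829e-22,
  "value": 0.92
}
```

Selection walks the emergence start to `t0* = 0.92` — just past the
parasite-persistence boundary: the resident there no longer supports
parasite amplification (`v̂* ≈ 7e−22`, prevalence ≈ 0), and host density
returns to the disease-free level.  The `cycle` status reports that the
substitution dynamics oscillated between the two lattice points straddling
the boundary and the more stable one was kept.  With a short-latency
parasite (`--tau 1.5`) the same command yields `t0* = 2.13`, and evolving
the emergence period (`--trait tl`) yields `tl* = 1.45` (`τ = 1.5`) and
`tl* = 2.88` (`τ = 3`).

Other subcommands: `simulate` (per-season CSV series), `pip` (pairwise
invasibility matrices), `landscape` (equilibrium density over a `(t0, tl)`
grid), `sweep` (vary `α`, `σ`, `ρ`, `τ`).  All runs are deterministic;
identical configs give byte-identical outputs.

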