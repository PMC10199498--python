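"""Run configuration: flat YAML files, validation, and output writers.

A config file is a flat key-value mapping.  Model parameter keys are spelled
exactly like the `ModelParameters` fields (alpha, beta, delta, mu_s, mu_a,
l, tau, gamma, epsilon, sigma, rho, T); trait keys are t0, tl and optionally
tl_min; initial densities are s_hat_1 and v_hat_1; run directives cover
season counts, tolerances and the evolution setup.  Unknown keys are
rejected loudly so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from ._kernel import STEPS_PER_UNIT
from .params import ModelParameters, PhenologyTraits, SeasonBoundaryState

__all__ = ["RunConfig", "load_config", "default_config_path", "write_outputs"]

_PARAM_KEYS = set(ModelParameters.field_names())
_TRAIT_KEYS = {"t0", "tl", "tl_min"}
_INITIAL_KEYS = {"s_hat_1", "v_hat_1"}
_RUN_KEYS = {
    "n_seasons", "rel_tol", "n_max", "steps_per_unit",
    "evolve_trait", "evolve_start", "evolve_step", "evolve_h",
    "evolve_max_iter", "resident_seasons",
}
_KNOWN_KEYS = _PARAM_KEYS | _TRAIT_KEYS | _INITIAL_KEYS | _RUN_KEYS


@dataclass
class RunConfig:
    """Fully validated configuration for one reproducible run."""

    parameters: ModelParameters
    traits: PhenologyTraits
    initial: SeasonBoundaryState
    n_seasons: int = 150
    rel_tol: float = 1e-8
    n_max: int = 2000
    steps_per_unit: int = STEPS_PER_UNIT
    evolve_trait: str = "t0"
    evolve_start: float | None = None
    evolve_step: float = 0.01
    evolve_h: float | None = None
    evolve_max_iter: int = 1000
    resident_seasons: int = 300
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out: dict = {}
        for key in sorted(_PARAM_KEYS):
            out[key] = getattr(self.parameters, key)
        out["t0"] = self.traits.t0
        out["tl"] = self.traits.tl
        out["tl_min"] = self.traits.tl_min
        out["s_hat_1"] = self.initial.s_hat
        out["v_hat_1"] = self.initial.v_hat
        for key in sorted(_RUN_KEYS):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out

    def dump(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False)
        )


def default_config_path() -> Path:
    """Path of the shipped default configuration (standard parameter set)."""
    return Path(resources.files("phenoparasite") / "data" / "default.yaml")


def load_config(path=None) -> RunConfig:
    """Load and validate a flat YAML config; ``None`` loads the default.

    Raises ``ValueError`` naming the offending key for unknown keys, missing
    required keys (``tau`` has no default: the latency period is the main
    environmental axis and must be chosen), and constraint violations.
    """
    if path is None:
        path = default_config_path()
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {unknown}; known keys: "
            f"{sorted(_KNOWN_KEYS)}"
        )
    if "tau" not in raw:
        raise ValueError(
            "config is missing required key 'tau' (parasite latency period)"
        )

    param_kwargs = {k: float(raw[k]) for k in _PARAM_KEYS if k in raw}
    try:
        parameters = ModelParameters(**param_kwargs)
    except ValueError as err:
        raise ValueError(f"invalid model parameter in {path}: {err}") from err

    trait_kwargs = {k: float(raw[k]) for k in _TRAIT_KEYS if k in raw}
    try:
        traits = PhenologyTraits(**trait_kwargs)
        traits.validate_against(parameters)
    except ValueError as err:
        raise ValueError(f"invalid trait value in {path}: {err}") from err

    try:
        initial = SeasonBoundaryState(
            s_hat=float(raw.get("s_hat_1", 1e4)),
            v_hat=float(raw.get("v_hat_1", 1e4)),
        )
    except ValueError as err:
        raise ValueError(f"invalid initial density in {path}: {err}") from err

    run_kwargs = {}
    for key in _RUN_KEYS:
        if key in raw:
            value = raw[key]
            if key in {"n_seasons", "n_max", "steps_per_unit",
                       "evolve_max_iter", "resident_seasons"}:
                value = int(value)
            elif key != "evolve_trait":
                value = float(value)
            run_kwargs[key] = value
    config = RunConfig(parameters=parameters, traits=traits, initial=initial,
                       **run_kwargs)
    if config.evolve_trait not in ("t0", "tl"):
        raise ValueError(
            f"evolve_trait must be 't0' or 'tl', got {config.evolve_trait!r}"
        )
    for key in ("n_seasons", "n_max", "steps_per_unit", "evolve_max_iter",
                "resident_seasons"):
        if getattr(config, key) < 1:
            raise ValueError(f"config key {key!r} must be >= 1")
    if config.rel_tol <= 0 or config.evolve_step <= 0:
        raise ValueError("rel_tol and evolve_step must be positive")
    return config


def write_outputs(results: dict, paths: dict) -> None:
    """Write a batch of results to files, validating paths up front.

    ``results`` maps a name to an object with either a ``to_csv(path)``
    method (series, trajectories, grids) or a plain mapping (written as
    JSON); ``paths`` maps the same names to destinations.  All parent
    directories are checked before anything is written so a bad path cannot
    discard half a computation.
    """
    missing = sorted(set(results) - set(paths))
    if missing:
        raise ValueError(f"no output path given for result(s) {missing}")
    for name in results:
        parent = Path(paths[name]).parent
        if not parent.is_dir():
            raise ValueError(
                f"output directory {parent} for {name!r} does not exist"
            )
    for name, obj in results.items():
        path = Path(paths[name])
        if hasattr(obj, "to_csv"):
            obj.to_csv(path)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
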