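"""Biological parameter set for *Drosophila suzukii* SIT modelling.

All rates are per day; the time unit is the day throughout the package.
The default preset carries the values calibrated for *D. suzukii* in a
~500 m² strawberry tunnel (carrying capacity K ≈ 36,000 larvae).

Two derived dimensionless quantities drive the qualitative behaviour of
the compartmental model:

* the basic reproduction number ``R0 = ω(1−p)ν / (μF(μL+ν))`` — the
  average number of viable female offspring produced by one female over
  her lifetime; the pest persists only when R0 > 1;
* the male conversion factor ``γ = νp/μM`` — equilibrium wild males per
  equilibrium larva.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping

import yaml

__all__ = [
    "ModelParameters",
    "ReleasePolicy",
    "DerivedQuantities",
    "ParameterError",
    "default_suzukii_parameters",
    "basic_reproduction_number",
    "gamma_factor",
    "derived_quantities",
    "load_config",
    "save_config",
]


class ParameterError(ValueError):
    """Raised when a parameter value violates its biological domain."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


_RATE_FIELDS = (
    "omega", "nu", "mu_L", "mu_M", "mu_F", "mu_S", "chi", "tau_F", "tau_I",
)
_UNIT_INTERVAL_FIELDS = ("p", "eta")


@dataclass(frozen=True)
class ModelParameters:
    """Immutable biological parameter set (rates in day⁻¹).

    Attributes
    ----------
    omega : egg-laying rate of fertilized females, eggs·female⁻¹·day⁻¹.
    nu : larval hatching (emergence) rate, day⁻¹.
    p : proportion of males among offspring, in [0, 1].
    mu_L, mu_M, mu_F, mu_S : stage-specific mortality rates (larvae,
        wild males, females, sterilized males), day⁻¹.
    chi : female mating rate, day⁻¹ (fast relative to mortalities).
    eta : sterilized-male mating competitiveness, in [0, 1].
    K : larval carrying capacity (larvae per tunnel), > 0.
    tau_F : refractory rate of fertilized females, day⁻¹.
    tau_I : refractory rate of infertile females, day⁻¹.
    """

    omega: float
    nu: float
    p: float
    mu_L: float
    mu_M: float
    mu_F: float
    mu_S: float
    chi: float
    eta: float
    K: float
    tau_F: float
    tau_I: float

    def __post_init__(self) -> None:
        for name in _RATE_FIELDS:
            value = getattr(self, name)
            if not (value >= 0):
                raise ParameterError(name, f"rate must be >= 0, got {value!r}")
        for name in _UNIT_INTERVAL_FIELDS:
            value = getattr(self, name)
            if not (0 <= value <= 1):
                raise ParameterError(name, f"must lie in [0, 1], got {value!r}")
        if not (self.K > 0):
            raise ParameterError("K", f"carrying capacity must be > 0, got {self.K!r}")

    def replace(self, **overrides: float) -> "ModelParameters":
        """Return a copy with the given fields overridden (validated)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ParameterError(sorted(unknown)[0], "unknown parameter field")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class ReleasePolicy:
    """Sterilized-male release schedule.

    For the ODE model only ``sigma`` (a constant release rate,
    individuals·day⁻¹) is used. The ABM releases a batch of
    ``batch_size`` males every ``period`` days starting on
    ``start_day``; ``batch_size`` defaults to round(sigma), i.e. daily
    releases at the ODE rate.
    """

    sigma: float = 0.0
    batch_size: int | None = None
    period: int = 1
    start_day: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError("sigma", f"release rate must be >= 0, got {self.sigma!r}")
        if self.period < 1:
            raise ParameterError("period", f"release period must be >= 1, got {self.period!r}")
        if self.batch_size is not None and (
            self.batch_size < 0 or int(self.batch_size) != self.batch_size
        ):
            raise ParameterError("batch_size", f"must be a non-negative integer, got {self.batch_size!r}")

    @property
    def abm_batch(self) -> int:
        return int(round(self.sigma)) if self.batch_size is None else int(self.batch_size)

    def releases_on(self, day: int) -> bool:
        return day >= self.start_day and (day - self.start_day) % self.period == 0


@dataclass(frozen=True)
class DerivedQuantities:
    """Dimensionless derivatives of a parameter set: γ, R0 and the
    eradication threshold σ̄ (individuals·day⁻¹)."""

    gamma: float
    R0: float
    sigma_bar: float


def default_suzukii_parameters() -> ModelParameters:
    """Parameter preset calibrated for *Drosophila suzukii*."""
    return ModelParameters(
        omega=6.0,
        nu=0.08,
        p=0.50,
        mu_L=0.037,
        mu_M=0.013,
        mu_F=0.012,
        mu_S=0.054,
        chi=10.0,
        eta=0.60,
        K=36_000.0,
        tau_F=0.12,
        tau_I=0.14,
    )


def basic_reproduction_number(params: ModelParameters) -> float:
    """Average number of viable female offspring per female,
    R0 = ω(1−p)ν / (μF(μL+ν))."""
    denom = params.mu_F * (params.mu_L + params.nu)
    if denom == 0:
        raise ParameterError(
            "mu_F" if params.mu_F == 0 else "mu_L",
            "R0 undefined: mu_F and mu_L + nu must be positive",
        )
    return params.omega * (1 - params.p) * params.nu / denom


def gamma_factor(params: ModelParameters) -> float:
    """Male conversion factor γ = νp/μM."""
    if params.mu_M == 0:
        raise ParameterError("mu_M", "gamma undefined: mu_M must be positive")
    return params.nu * params.p / params.mu_M


def derived_quantities(params: ModelParameters) -> DerivedQuantities:
    # local import: equilibrium depends on this module
    from .equilibrium import eradication_threshold

    return DerivedQuantities(
        gamma=gamma_factor(params),
        R0=basic_reproduction_number(params),
        sigma_bar=eradication_threshold(params),
    )


# ---------------------------------------------------------------------------
# Config file handling (YAML, three sections: parameters/release/simulation)

_CONFIG_SECTIONS = ("parameters", "release", "simulation")


class ConfigError(ValueError):
    pass


def _check_keys(section: str, given: Mapping[str, Any], allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{section}': {sorted(unknown)}")


def load_config(path: str) -> dict[str, Any]:
    """Read a structured config file.

    Sections: ``parameters`` (ModelParameters fields), ``release``
    (ReleasePolicy fields), ``simulation`` (free-form scalars such as
    horizon, seed, scenario, initial counts). Unknown keys in the
    typed sections are an error, never a warning.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys("<root>", raw, set(_CONFIG_SECTIONS))

    out: dict[str, Any] = {}
    param_fields = {f.name for f in dataclasses.fields(ModelParameters)}
    release_fields = {f.name for f in dataclasses.fields(ReleasePolicy)}

    psec = raw.get("parameters", {}) or {}
    _check_keys("parameters", psec, param_fields)
    if psec:
        # a parameters section must be complete, so a config file is an
        # unambiguous record of the run
        missing = param_fields - set(psec)
        if missing:
            raise ConfigError(f"missing parameter field(s): {sorted(missing)}")
        out["parameters"] = ModelParameters(**{k: float(v) for k, v in psec.items()})
    else:
        out["parameters"] = default_suzukii_parameters()

    rsec = raw.get("release", {}) or {}
    _check_keys("release", rsec, release_fields)
    out["release"] = ReleasePolicy(**rsec)

    out["simulation"] = dict(raw.get("simulation", {}) or {})
    return out


def save_config(path: str, params: ModelParameters,
                release: ReleasePolicy | None = None,
                simulation: Mapping[str, Any] | None = None) -> None:
    """Write a config file that :func:`load_config` round-trips exactly."""
    doc: dict[str, Any] = {"parameters": params.to_dict()}
    if release is not None:
        doc["release"] = {
            "sigma": release.sigma,
            "batch_size": release.batch_size,
            "period": release.period,
            "start_day": release.start_day,
        }
    if simulation:
        doc["simulation"] = dict(simulation)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
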