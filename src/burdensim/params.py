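"""Parameter containers and validation for simulated scenarios.

A scenario bundles five ingredient groups:

* :class:`GrowthParams` — maximal growth rates of unburdened cells (``mu_N``)
  and producers (``mu_P``); the production burden is ``1 - mu_P/mu_N``.
* :class:`MutationRates` — dimensionless per-unit-growth mutation
  coefficients; the per-step mutation probability is ``k * mu_spec * dt``.
* :class:`CircuitSpec` — the expression architecture (naive vs.
  integrase-mediated differentiation, cassette copy number, terminal
  selection, division limit).
* :class:`EnvironmentSpec` — chemostat or serial-batch culture conditions.
* :class:`AntibioticSpec` — plasmid-selection antibiotic and the plasmid
  event mode (loss or mutation).

Validated scenarios are frozen; all invariants are checked at construction
and :func:`validate_scenario` is idempotent.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

__all__ = [
    "GrowthParams",
    "MutationRates",
    "CircuitSpec",
    "EnvironmentSpec",
    "AntibioticSpec",
    "Scenario",
    "ValidationError",
    "validate_scenario",
    "scenario_from_config",
    "scenario_to_config",
    "load_scenario",
    "save_scenario",
]

ARCHITECTURES = ("naive", "differentiation")
NAIVE_CONVENTIONS = ("2x", "2x*")
ENV_MODES = ("chemostat", "serial_batch")
PLASMID_EVENT_MODES = ("none", "loss", "mutation")
PI_RULES = ("all", "any")


class ValidationError(ValueError):
    """A scenario field violated an invariant; the message names the field."""


def _require(cond: bool, field_name: str, message: str) -> None:
    if not cond:
        raise ValidationError(f"{field_name}: {message}")


@dataclass(frozen=True)
class GrowthParams:
    """Maximal specific growth rates (h⁻¹).

    ``mu_P`` is the producer rate at the reference burden; the burden
    fraction ``1 - mu_P/mu_N`` must lie in [0, 1), i.e. producers grow,
    if only slowly.
    """

    mu_N: float
    mu_P: float

    def __post_init__(self) -> None:
        _require(self.mu_N > 0, "mu_N", "must be positive")
        _require(self.mu_P > 0, "mu_P", "must be positive (100% burden is disallowed)")
        _require(self.mu_P <= self.mu_N, "mu_P", "must not exceed mu_N")

    @property
    def burden_fraction(self) -> float:
        return 1.0 - self.mu_P / self.mu_N

    @classmethod
    def from_burden(cls, mu_N: float, burden_percent: float) -> "GrowthParams":
        """Build from a burden expressed in percent: mu_P = mu_N (1 - b/100)."""
        _require(0 <= burden_percent < 100, "burden_percent", "must be in [0, 100)")
        return cls(mu_N=mu_N, mu_P=mu_N * (1.0 - burden_percent / 100.0))


@dataclass(frozen=True)
class MutationRates:
    """Dimensionless per-unit-growth mutation coefficients.

    * ``k_MB`` — burden mutation (producer → non-producer).
    * ``k_MD`` — differentiation-cassette mutation (→ non-differentiator).
    * ``k_MI`` — integrase mutation, per functional integrase copy.
    * ``k_PL`` — plasmid event (loss or mutation, per the antibiotic spec).
    """

    k_MB: float = 0.0
    k_MD: float = 0.0
    k_MI: float = 0.0
    k_PL: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_MB", "k_MD", "k_MI", "k_PL"):
            v = getattr(self, name)
            _require(0.0 <= v <= 1.0, name, "must be in [0, 1]")


@dataclass(frozen=True)
class CircuitSpec:
    """Expression architecture.

    ``architecture`` is ``"naive"`` (the function is always on) or
    ``"differentiation"`` (integrase-mediated recombination switches it on).
    ``terminal`` adds selection that limits differentiated cells to
    ``n_div`` divisions before death.  ``naive_convention`` fixes whether
    ``mu_P`` describes a 2x naive cell with both cassettes active (``"2x"``)
    or with a single active cassette (``"2x*"``); two-cassette
    differentiation always uses the ``2x*`` reading.  ``pi_rule`` selects
    when replication of the pi-dependent plasmid ceases in two-cassette
    differentiation: with the split replication factor each cassette encodes
    one half, so ``"any"`` single recombination ablates it (default); the
    ``"all"`` variant requires every cassette to recombine.
    """

    architecture: str
    n_cassettes: int = 1
    naive_convention: str = "2x"
    terminal: bool = False
    k_diff: float = 0.0
    n_div: int = 4
    n_integrase: int = 2
    pi_rule: str = "any"

    def __post_init__(self) -> None:
        _require(self.architecture in ARCHITECTURES, "architecture",
                 f"must be one of {ARCHITECTURES}")
        _require(self.n_cassettes in (1, 2), "n_cassettes", "must be 1 or 2")
        _require(self.naive_convention in NAIVE_CONVENTIONS, "naive_convention",
                 f"must be one of {NAIVE_CONVENTIONS}")
        _require(self.k_diff >= 0, "k_diff", "must be non-negative")
        _require(int(self.n_div) == self.n_div and self.n_div >= 0, "n_div",
                 "must be a non-negative integer")
        _require(self.n_integrase >= 1, "n_integrase", "must be at least 1")
        _require(self.pi_rule in PI_RULES, "pi_rule", f"must be one of {PI_RULES}")
        if self.terminal:
            _require(self.architecture == "differentiation", "terminal",
                     "terminal selection requires the differentiation architecture")
        if self.architecture == "naive":
            _require(self.k_diff == 0, "k_diff",
                     "must be zero for the naive architecture")


@dataclass(frozen=True)
class EnvironmentSpec:
    """Culture environment: constant-dilution chemostat or serial batches."""

    mode: str
    K: float
    N0: float
    dt: float = 0.01
    D: float = 0.0
    t_end: float | None = None
    batch_duration: float | None = None
    n_batches: int | None = None
    dilution_factor: float | None = None

    def __post_init__(self) -> None:
        _require(self.mode in ENV_MODES, "mode", f"must be one of {ENV_MODES}")
        _require(self.K > 0, "K", "must be positive")
        _require(self.dt > 0, "dt", "must be positive")
        _require(0 < self.N0 <= self.K, "N0", "must lie in (0, K]")
        if self.mode == "chemostat":
            _require(self.D >= 0, "D", "must be non-negative")
            _require(self.t_end is not None and self.t_end > 0, "t_end",
                     "must be a positive duration for chemostat mode")
        else:
            _require(self.batch_duration is not None and self.batch_duration > 0,
                     "batch_duration", "must be positive for serial_batch mode")
            _require(self.n_batches is not None and self.n_batches >= 1,
                     "n_batches", "must be at least 1 for serial_batch mode")
            _require(self.dilution_factor is not None and self.dilution_factor > 1,
                     "dilution_factor", "must exceed 1 for serial_batch mode")


@dataclass(frozen=True)
class AntibioticSpec:
    """Plasmid-selection antibiotic pool and plasmid event mode.

    Plasmid-bearing cells degrade the antibiotic with Michaelis–Menten
    kinetics (``Vmax``, ``Km``); plasmid-free cells stop growing whenever
    the concentration is at or above ``MIC``.  ``Km`` defaults to
    1.0 μg/mL, a placeholder half-saturation constant: no headline
    behaviour of the model depends on its value.
    """

    enabled: bool = False
    A0: float = 0.0
    MIC: float = 1.1
    Vmax: float = 0.0
    Km: float = 1.0
    plasmid_event_mode: str = "none"

    def __post_init__(self) -> None:
        _require(self.A0 >= 0, "A0", "must be non-negative")
        _require(self.MIC > 0, "MIC", "must be positive")
        _require(self.Vmax >= 0, "Vmax", "must be non-negative")
        _require(self.Km > 0, "Km", "must be positive")
        _require(self.plasmid_event_mode in PLASMID_EVENT_MODES,
                 "plasmid_event_mode", f"must be one of {PLASMID_EVENT_MODES}")
        if self.enabled:
            _require(self.A0 > 0, "A0", "must be positive when antibiotic is enabled")


@dataclass(frozen=True)
class Scenario:
    """A frozen, validated simulation scenario."""

    growth: GrowthParams
    mutation: MutationRates
    circuit: CircuitSpec
    environment: EnvironmentSpec
    antibiotic: AntibioticSpec = field(default_factory=AntibioticSpec)
    label: str = ""

    @property
    def scenario_id(self) -> str:
        """Deterministic content hash, stable across processes."""
        payload = json.dumps(scenario_to_config(self), sort_keys=True)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def validate_scenario(*args: Any, **kwargs: Any) -> Scenario:
    """Validate and freeze a scenario.

    Accepts either a single :class:`Scenario` (idempotent: returns an equal
    object) or the component groups
    ``(growth, mutation, circuit, environment[, antibiotic, label])``.
    Raises :class:`ValidationError` naming the offending field otherwise.
    """
    if len(args) == 1 and not kwargs and isinstance(args[0], Scenario):
        s = args[0]
    else:
        s = Scenario(*args, **kwargs)
    # dataclass __post_init__ has checked per-group invariants; re-run the
    # cheap cross-group checks so hand-built (replaced) scenarios are caught.
    _require(isinstance(s.growth, GrowthParams), "growth", "must be GrowthParams")
    _require(isinstance(s.mutation, MutationRates), "mutation", "must be MutationRates")
    _require(isinstance(s.circuit, CircuitSpec), "circuit", "must be CircuitSpec")
    _require(isinstance(s.environment, EnvironmentSpec), "environment",
             "must be EnvironmentSpec")
    _require(isinstance(s.antibiotic, AntibioticSpec), "antibiotic",
             "must be AntibioticSpec")
    if s.antibiotic.plasmid_event_mode != "none":
        _require(s.mutation.k_PL >= 0, "k_PL", "must be set for plasmid events")
    return s


# ---------------------------------------------------------------------------
# config round trip

_GROUPS = {
    "growth": GrowthParams,
    "mutation": MutationRates,
    "circuit": CircuitSpec,
    "environment": EnvironmentSpec,
    "antibiotic": AntibioticSpec,
}


def scenario_to_config(scenario: Scenario) -> dict[str, Any]:
    """Plain nested dict with keys exactly matching the field names."""
    out: dict[str, Any] = {}
    for group in _GROUPS:
        out[group] = dataclasses.asdict(getattr(scenario, group))
    out["label"] = scenario.label
    return out


def scenario_from_config(config: Mapping[str, Any]) -> Scenario:
    """Build and validate a scenario from a nested mapping.

    The ``growth`` group additionally accepts ``{mu_N, burden_percent}``
    in place of ``{mu_N, mu_P}``.
    """
    kwargs: dict[str, Any] = {}
    for group, cls in _GROUPS.items():
        if group not in config:
            if group == "antibiotic":
                kwargs[group] = AntibioticSpec()
                continue
            raise ValidationError(f"{group}: missing configuration section")
        section = dict(config[group])
        if group == "growth" and "burden_percent" in section:
            kwargs[group] = GrowthParams.from_burden(
                section["mu_N"], section.pop("burden_percent"))
            continue
        try:
            kwargs[group] = cls(**section)
        except TypeError as exc:
            raise ValidationError(f"{group}: {exc}") from exc
    kwargs["label"] = config.get("label", "")
    return validate_scenario(Scenario(**kwargs))


def save_scenario(scenario: Scenario, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_config(scenario), fh, sort_keys=False)


def load_scenario(path: str) -> Scenario:
    with open(path) as fh:
        return scenario_from_config(yaml.safe_load(fh))
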