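"""Closed-form rate laws shared by both simulation engines.

Pure functions: logistic carrying-capacity growth, the two-cassette
growth/production conventions, production flux, the Heaviside MIC growth
gate for plasmid-free cells, Michaelis–Menten antibiotic degradation, and
the growth-scaled mutation probability.

Production is measured in arbitrary units at 1 unit·cell⁻¹·h⁻¹ for a fully
producing cell growing at its maximal rate; the realized flux scales with
the ratio of specific to maximal growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import GrowthParams

__all__ = [
    "CassetteRateTable",
    "specific_growth",
    "two_cassette_rates",
    "cassette_rate_table",
    "production_flux",
    "heaviside_growth_gate",
    "antibiotic_step",
    "mutation_probability",
]


@dataclass(frozen=True)
class CassetteRateTable:
    """Maximal growth rate and production share by active-cassette count.

    ``mu_max[c]`` and ``beta[c]`` are indexed by the number of active
    (producing) cassettes ``c``; ``mu_max[0] = mu_N`` and ``beta[0] = 0``
    always.  ``mu_max`` is non-increasing and ``beta`` non-decreasing in
    ``c`` (more active copies: slower growth, more production).
    """

    mu_max: tuple[float, ...]
    beta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.mu_max) != len(self.beta):
            raise ValueError("mu_max and beta must have equal length")
        for i in range(len(self.mu_max) - 1):
            if self.mu_max[i + 1] > self.mu_max[i] + 1e-12:
                raise ValueError("mu_max must be non-increasing in cassette count")
            if self.beta[i + 1] < self.beta[i] - 1e-12:
                raise ValueError("beta must be non-decreasing in cassette count")
        if self.beta[0] != 0:
            raise ValueError("beta[0] must be 0 (no active cassettes, no production)")

    @property
    def n_cassettes(self) -> int:
        return len(self.mu_max) - 1


def specific_growth(mu_max: float, N_total: float, K: float) -> float:
    """Specific growth rate under logistic carrying-capacity limitation.

    ``mu_max * max(0, 1 - N_total/K)``: growth slows linearly as the total
    population approaches the carrying capacity and stops at or above it.
    """
    if mu_max < 0 or N_total < 0:
        raise ValueError("mu_max and N_total must be non-negative")
    if K <= 0:
        raise ValueError("K must be positive")
    return mu_max * max(0.0, 1.0 - N_total / K)


def two_cassette_rates(mu_N: float, mu_P: float, convention: str = "2x") -> CassetteRateTable:
    """Growth/production rates for cells with 0, 1 or 2 active cassettes.

    Two conventions fix which cell the stated producer rate ``mu_P``
    describes:

    * ``"2x"`` — both cassettes active grow at ``mu_P`` (beta = 1); a cell
      with one active cassette grows at ``mu_N * sqrt(mu_P/mu_N)`` (the
      geometric mean of the two rates) and its production share is the
      proportional growth-rate decrease
      ``(mu_N - mu_1)/(mu_N - mu_P)``.
    * ``"2x*"`` — one active cassette grows at ``mu_P`` (beta = 1); both
      active compounds the proportional decrease, ``mu_P**2 / mu_N``, with
      production share ``(mu_N - mu_2)/(mu_N - mu_P)`` (> 1: two copies
      produce more than one).

    Requires strict burden ``0 < mu_P < mu_N`` — the shares' denominator is
    ``mu_N - mu_P``.
    """
    if not (0 < mu_P < mu_N):
        raise ValueError(
            "two_cassette_rates requires 0 < mu_P < mu_N (strict burden; "
            "production shares are undefined at zero burden)")
    if convention == "2x":
        mu_1 = mu_N * (mu_P / mu_N) ** 0.5
        beta_1 = (mu_N - mu_1) / (mu_N - mu_P)
        return CassetteRateTable(mu_max=(mu_N, mu_1, mu_P), beta=(0.0, beta_1, 1.0))
    if convention == "2x*":
        mu_2 = mu_P**2 / mu_N
        beta_2 = (mu_N - mu_2) / (mu_N - mu_P)
        return CassetteRateTable(mu_max=(mu_N, mu_P, mu_2), beta=(0.0, 1.0, beta_2))
    raise ValueError(f"unknown convention {convention!r} (expected '2x' or '2x*')")


def cassette_rate_table(growth: GrowthParams, n_cassettes: int,
                        convention: str = "2x") -> CassetteRateTable:
    """Rate table for a circuit with ``n_cassettes`` producer cassettes.

    Single-cassette circuits need no convention: one active cassette is the
    producer (``mu_P``, beta 1).  Two-cassette circuits dispatch on the
    convention; two-cassette differentiation uses ``"2x*"`` (one activated
    cassette is the reference producer).
    """
    if n_cassettes == 1:
        return CassetteRateTable(mu_max=(growth.mu_N, growth.mu_P), beta=(0.0, 1.0))
    if n_cassettes == 2:
        return two_cassette_rates(growth.mu_N, growth.mu_P, convention)
    raise ValueError("n_cassettes must be 1 or 2")


def production_flux(beta: float, mu_spec: float, mu_max: float, count: float) -> float:
    """Production rate (units/h) of ``count`` cells of one class.

    ``beta * (mu_spec/mu_max) * count``, at 1 unit·cell⁻¹·h⁻¹: production
    is proportional to the production share and to the realized fraction of
    the maximal growth rate.  Classes that cannot grow (``mu_max == 0``)
    produce nothing.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if count > 0 and mu_max <= 0:
        return 0.0
    if count == 0 or mu_max == 0:
        return 0.0
    return beta * (mu_spec / mu_max) * count


def heaviside_growth_gate(A: float, MIC: float) -> int:
    """0 if the antibiotic concentration is at or above the MIC, else 1."""
    return 0 if A >= MIC else 1


def antibiotic_step(A: float, degrader_count: float, Vmax: float, Km: float,
                    dt: float) -> float:
    """One Euler step of communal Michaelis–Menten antibiotic degradation.

    The concentration decreases by ``degrader_count * Vmax * A/(Km + A) * dt``
    and is floored at zero; it never increases.
    """
    if A < 0 or degrader_count < 0 or Vmax < 0 or dt < 0:
        raise ValueError("inputs must be non-negative")
    if Km <= 0:
        raise ValueError("Km must be positive")
    return max(0.0, A - degrader_count * Vmax * A / (Km + A) * dt)


def mutation_probability(k_coeff: float, mu_spec: float, dt: float) -> float:
    """Per-step mutation probability ``min(1, k * mu_spec * dt)``.

    Mutation coefficients are per unit growth, so the probability scales
    with the specific growth rate: cells that do not grow do not mutate.
    """
    if k_coeff < 0 or mu_spec < 0 or dt < 0:
        raise ValueError("inputs must be non-negative")
    return min(1.0, k_coeff * mu_spec * dt)
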