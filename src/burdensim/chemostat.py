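"""Deterministic chemostat model of burdensome-expression architectures.

Ordinary differential equations for three strategies, integrated by
fixed-step forward Euler under constant dilution ``D`` and logistic
carrying-capacity-limited growth:

* **naive** — producers ``P`` (growth ``mu_P``, production share 1) mutate
  into non-producers ``N`` (growth ``mu_N``) at the burden-mutation rate
  ``k_MB * mu_spec``.
* **differentiation** — progenitors ``G`` (unburdened, non-producing)
  differentiate irreversibly into producers at rate ``k_diff``; burden
  mutations in progenitors create ``G_bm`` (unburdened, differentiates into
  non-producers), differentiation mutations create non-differentiators
  ``X`` (the only class with a lasting selective advantage).
* **terminal differentiation** — as above, but differentiated cells carry a
  division index ``i`` and may divide only ``n_div`` times: a cell at rung
  ``i < n`` divides into two cells at rung ``i+1``; cells at the top rung
  die at their growth rate instead of dividing.

This engine models the single-cassette abstraction of each architecture;
multi-cassette genotypes, plasmid events and antibiotics live in the
stochastic serial-batch engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import Scenario, ValidationError, validate_scenario
from .trajectory import Trajectory

__all__ = [
    "ChemostatSystem",
    "build_naive_system",
    "build_differentiation_system",
    "euler_integrate",
    "simulate_architecture",
    "ladder_impulse_response",
]


@dataclass
class ChemostatSystem:
    """Derivative function plus metadata for one architecture."""

    labels: list[str]
    derivative: Callable[[np.ndarray], np.ndarray]
    production: Callable[[np.ndarray], float]
    initial_state: np.ndarray


def _logistic_factor(N_total: float, K: float) -> float:
    return max(0.0, 1.0 - N_total / K)


def build_naive_system(scenario: Scenario) -> ChemostatSystem:
    """Producer/non-producer system for naive expression.

    dP/dt = mu_P,spec P − D P − k_MB mu_P,spec P
    dN/dt = mu_N,spec N − D N + k_MB mu_P,spec P
    """
    s = validate_scenario(scenario)
    if s.circuit.architecture != "naive":
        raise ValidationError("architecture: build_naive_system requires 'naive'")
    if s.circuit.n_cassettes != 1:
        raise ValidationError(
            "n_cassettes: the deterministic engine models the single-cassette "
            "abstraction; use the stochastic engine for multi-cassette circuits")
    mu_N, mu_P = s.growth.mu_N, s.growth.mu_P
    k_MB = s.mutation.k_MB
    D, K = s.environment.D, s.environment.K

    def derivative(y: np.ndarray) -> np.ndarray:
        P, N = y
        f = _logistic_factor(P + N, K)
        mu_P_s, mu_N_s = mu_P * f, mu_N * f
        m_B = k_MB * mu_P_s * P
        return np.array([
            mu_P_s * P - D * P - m_B,
            mu_N_s * N - D * N + m_B,
        ])

    def production(y: np.ndarray) -> float:
        return _logistic_factor(y.sum(), K) * y[0]

    y0 = np.array([s.environment.N0, 0.0])
    return ChemostatSystem(["P", "N"], derivative, production, y0)


def build_differentiation_system(scenario: Scenario) -> ChemostatSystem:
    """Progenitor/producer system, with or without terminal selection.

    Classes: progenitors ``G``; burden-mutated progenitors ``G_bm``
    (wild-type fitness, differentiate into non-producers);
    non-differentiators ``X`` (absorbing sink for differentiation-mutation
    flux from both progenitor classes); and differentiated cells — plain
    ``P``/``N`` without terminal selection, division ladders ``P_i``/``N_i``
    (i = 0..n_div) with top-rung death under terminal selection.

    Differentiation is a first-order flux ``k_diff * count`` (not scaled by
    growth, unlike mutation); every class is diluted at ``D`` and shares
    the logistic factor.
    """
    s = validate_scenario(scenario)
    if s.circuit.architecture != "differentiation":
        raise ValidationError(
            "architecture: build_differentiation_system requires 'differentiation'")
    if s.circuit.n_cassettes != 1:
        raise ValidationError(
            "n_cassettes: the deterministic engine models the single-cassette "
            "abstraction; use the stochastic engine for multi-cassette circuits")
    mu_N, mu_P = s.growth.mu_N, s.growth.mu_P
    k_MB, k_MD = s.mutation.k_MB, s.mutation.k_MD
    k_diff = s.circuit.k_diff
    D, K = s.environment.D, s.environment.K
    terminal = s.circuit.terminal
    n = s.circuit.n_div

    if not terminal:
        labels = ["G", "G_bm", "X", "P", "N"]

        def derivative(y: np.ndarray) -> np.ndarray:
            G, G_bm, X, P, N = y
            f = _logistic_factor(y.sum(), K)
            mu_N_s, mu_P_s = mu_N * f, mu_P * f
            dG = mu_N_s * G - D * G - k_diff * G - (k_MD + k_MB) * mu_N_s * G
            dG_bm = (mu_N_s * G_bm - D * G_bm - k_diff * G_bm
                     - k_MD * mu_N_s * G_bm + k_MB * mu_N_s * G)
            dX = mu_N_s * X - D * X + k_MD * mu_N_s * (G + G_bm)
            dP = mu_P_s * P - D * P + k_diff * G - k_MB * mu_P_s * P
            dN = mu_N_s * N - D * N + k_diff * G_bm + k_MB * mu_P_s * P
            return np.array([dG, dG_bm, dX, dP, dN])

        def production(y: np.ndarray) -> float:
            return _logistic_factor(y.sum(), K) * y[3]

    else:
        labels = (["G", "G_bm", "X"]
                  + [f"P_{i}" for i in range(n + 1)]
                  + [f"N_{i}" for i in range(n + 1)])
        iP = 3
        iN = 3 + (n + 1)

        def derivative(y: np.ndarray) -> np.ndarray:
            G, G_bm, X = y[0], y[1], y[2]
            P = y[iP:iP + n + 1]
            N = y[iN:iN + n + 1]
            f = _logistic_factor(y.sum(), K)
            mu_N_s, mu_P_s = mu_N * f, mu_P * f
            d = np.empty_like(y)
            d[0] = mu_N_s * G - D * G - k_diff * G - (k_MD + k_MB) * mu_N_s * G
            d[1] = (mu_N_s * G_bm - D * G_bm - k_diff * G_bm
                    - k_MD * mu_N_s * G_bm + k_MB * mu_N_s * G)
            d[2] = mu_N_s * X - D * X + k_MD * mu_N_s * (G + G_bm)
            # ladder: every rung loses cells at its growth rate (division,
            # or death at the top rung); rungs i >= 1 gain 2 mu C_{i-1}
            m_B = k_MB * mu_P_s * P  # burden mutation P_i -> N_i
            dP = -mu_P_s * P - D * P - m_B
            dP[1:] += 2.0 * mu_P_s * P[:-1]
            dP[0] += k_diff * G
            dN = -mu_N_s * N - D * N + m_B
            dN[1:] += 2.0 * mu_N_s * N[:-1]
            dN[0] += k_diff * G_bm
            d[iP:iP + n + 1] = dP
            d[iN:iN + n + 1] = dN
            return d

        def production(y: np.ndarray) -> float:
            return _logistic_factor(y.sum(), K) * y[iP:iP + n + 1].sum()

    y0 = np.zeros(len(labels))
    y0[0] = s.environment.N0
    return ChemostatSystem(labels, derivative, production, y0)


def euler_integrate(derivative_fn: Callable[[np.ndarray], np.ndarray],
                    initial_state: np.ndarray,
                    dt: float,
                    t_end: float,
                    production_fn: Callable[[np.ndarray], float] | None = None,
                    labels: list[str] | None = None,
                    record_every: int = 1) -> Trajectory:
    """Fixed-step forward Euler integration.

    Any abundance driven below zero by a step is clamped to zero and the
    clamped mass recorded on the returned trajectory.  Production flux is
    evaluated at the start of each step (left-endpoint quadrature) and
    accumulated as ``flux * dt``.  A non-finite derivative aborts.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    y = np.asarray(initial_state, dtype=float).copy()
    if np.any(y < 0):
        raise ValueError("initial state must be non-negative")
    n_steps = int(round(t_end / dt))
    labels = labels if labels is not None else [f"y{i}" for i in range(y.size)]

    rec_steps = list(range(0, n_steps + 1, record_every))
    if rec_steps[-1] != n_steps:
        rec_steps.append(n_steps)
    rec_index = {step: k for k, step in enumerate(rec_steps)}

    times = np.array(rec_steps, dtype=float) * dt
    counts = np.empty((len(rec_steps), y.size))
    rate = np.zeros(len(rec_steps))
    cumulative = np.zeros(len(rec_steps))

    counts[0] = y
    cum = 0.0
    clamp_events = 0
    clamped_mass = 0.0
    flux = production_fn(y) if production_fn is not None else 0.0
    rate[0] = flux

    for step in range(n_steps):
        d = derivative_fn(y)
        if not np.all(np.isfinite(d)):
            raise FloatingPointError(
                f"non-finite derivative at t={step * dt:.4f} h; state={y!r}")
        flux = production_fn(y) if production_fn is not None else 0.0
        y = y + dt * d
        neg = y < 0
        if neg.any():
            clamp_events += int(neg.sum())
            clamped_mass += float(-y[neg].sum())
            y[neg] = 0.0
        cum += flux * dt
        k = rec_index.get(step + 1)
        if k is not None:
            counts[k] = y
            cumulative[k] = cum
            rate[k] = production_fn(y) if production_fn is not None else 0.0

    return Trajectory(time=times, counts=counts, labels=labels,
                      production_rate=rate, cumulative_production=cumulative,
                      clamp_events=clamp_events, clamped_mass=clamped_mass)


def simulate_architecture(scenario: Scenario, record_every: int = 1) -> Trajectory:
    """Run the deterministic chemostat model for a validated scenario.

    Dispatches on the architecture; all cells start in the progenitor class
    (differentiation) or the producer class (naive) at ``N0``.
    """
    s = validate_scenario(scenario)
    if s.environment.mode != "chemostat":
        raise ValidationError("mode: simulate_architecture requires chemostat mode")
    if s.circuit.architecture == "naive":
        system = build_naive_system(s)
    else:
        system = build_differentiation_system(s)
    traj = euler_integrate(system.derivative, system.initial_state,
                           s.environment.dt, s.environment.t_end,
                           production_fn=system.production,
                           labels=system.labels, record_every=record_every)
    traj.meta["scenario_id"] = s.scenario_id
    traj.meta["label"] = s.label
    return traj


def ladder_impulse_response(n_div: int, mu: float = 1.0, dt: float = 0.01,
                            t_end: float = 60.0) -> float:
    """Total deaths from one differentiation event under terminal selection.

    Integrates the division ladder seeded with a single cell at rung 0 and
    no further inflow, accumulating the top-rung death flux.  One cell at
    rung 0 doubles at each of ``n_div`` rungs, so the exact total is
    ``2**n_div`` deaths per differentiating cell.
    """
    n = int(n_div)
    C = np.zeros(n + 1)
    C[0] = 1.0
    deaths = 0.0
    for _ in range(int(round(t_end / dt))):
        dC = -mu * C
        dC[1:] += 2.0 * mu * C[:-1]
        deaths += mu * C[n] * dt
        C = C + dt * dC
        np.clip(C, 0.0, None, out=C)
    return deaths
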