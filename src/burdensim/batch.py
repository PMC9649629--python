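"""Genotype-explicit stochastic serial-batch simulator.

Each subpopulation is a :class:`CellClassKey`: the state of every producer
cassette (intact, burden-mutated, differentiation-mutated, recombined and
producing, recombined and burden-mutated), the number of functional
integrase expression cassettes, the plasmid state (present, mutated, lost)
and — under terminal selection — the post-differentiation division index.

Growth, differentiation, antibiotic degradation and production are
deterministic (forward Euler, shared update formulas with the chemostat
engine); mutations and plasmid events are stochastic, drawn per step from a
binomial distribution with probability ``k * mu_spec * dt`` over the
(rounded) class count.  Cultures are diluted 1:``dilution_factor`` between
batches and the antibiotic pool is reset to ``A0``.

Sub-step order within one Euler step is a fixed contract:
growth (including division-ladder transfers and top-rung death) →
differentiation → stochastic mutation draws → antibiotic degradation →
production accumulation.  Deterministic fluxes are evaluated from
start-of-step counts so a zero-mutation run reproduces the deterministic
engine exactly; production uses start-of-step counts (left-endpoint
quadrature), matching the chemostat integrator.
"""

from __future__ import annotations

import functools
from collections import deque
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .params import CircuitSpec, Scenario, ValidationError, validate_scenario
from .rates import (CassetteRateTable, cassette_rate_table,
                    heaviside_growth_gate, antibiotic_step)
from .trajectory import Trajectory

__all__ = [
    "INTACT", "INTACT_BM", "DIFF_MUT", "REC_ACTIVE", "REC_BM",
    "PRESENT", "MUTATED", "LOST", "DIV_NONE",
    "CellClassKey", "BatchState", "StochasticResult", "Transition",
    "enumerate_classes", "pi_replication_off", "class_rates",
    "transition_table", "SerialBatchSimulator", "step",
    "run_serial", "replicate_runs",
]

# cassette states
INTACT = "INTACT"            # wild type: recombinable, not producing
INTACT_BM = "INTACT_BM"      # burden-mutated but still recombinable
DIFF_MUT = "DIFF_MUT"        # recombination-incompetent, inert
REC_ACTIVE = "REC_ACTIVE"    # recombined, producing
REC_BM = "REC_BM"            # recombined, burden-mutated (non-producing)
_CASSETTE_ORDER = (INTACT, INTACT_BM, DIFF_MUT, REC_ACTIVE, REC_BM)
_RECOMBINED = (REC_ACTIVE, REC_BM)
_RECOMBINABLE = (INTACT, INTACT_BM)

# plasmid states
PRESENT = "PRESENT"
MUTATED = "MUTATED"
LOST = "LOST"

DIV_NONE = -1  # division index sentinel: not under the division limit


class CellClassKey(NamedTuple):
    """Genotype of one subpopulation (cassettes stored as a sorted tuple)."""

    cassette_states: tuple[str, ...]
    integrase_functional: int
    plasmid: str
    div_index: int

    def label(self) -> str:
        cas = "+".join(self.cassette_states)
        div = "" if self.div_index == DIV_NONE else f"|i{self.div_index}"
        return f"{cas}|int{self.integrase_functional}|{self.plasmid}{div}"


class Transition(NamedTuple):
    target: CellClassKey
    kind: str  # burden | diff_mut | integrase | plasmid | differentiation
    coefficient: float


def _sorted_cassettes(states: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(states, key=_CASSETTE_ORDER.index))


def pi_replication_off(key: CellClassKey, circuit: CircuitSpec) -> bool:
    """Whether recombination has ended replication of the pi-dependent plasmid.

    Single cassette: one recombination excises the replication factor.  Two
    cassettes: under the default ``pi_rule="any"`` the replication factor is
    split between the cassettes, so the first recombination ablates it;
    ``pi_rule="all"`` models a redundant full-length factor that survives
    until every cassette has recombined.
    """
    recombined = [c in _RECOMBINED for c in key.cassette_states]
    if circuit.pi_rule == "any":
        return any(recombined)
    return all(recombined) and len(recombined) > 0


def _with_div_index(cassettes: tuple[str, ...], integrase: int, plasmid: str,
                    prev_div: int, circuit: CircuitSpec) -> CellClassKey:
    key = CellClassKey(cassettes, integrase, plasmid, DIV_NONE)
    if circuit.terminal and pi_replication_off(key, circuit):
        div = prev_div if prev_div != DIV_NONE else 0
        key = key._replace(div_index=div)
    return key


def class_rates(key: CellClassKey, scenario: Scenario, A: float = 0.0
                ) -> tuple[float, float]:
    """(mu_max, beta) of one class at antibiotic concentration ``A``.

    Active cassettes confer burden and production only while the plasmid is
    present; plasmid mutation or loss relieves burden and zeroes production.
    Plasmid-free cells additionally stop growing at or above the MIC.
    """
    s = scenario
    table = _scenario_rate_table(s)
    if key.plasmid == PRESENT:
        c = sum(1 for cs in key.cassette_states if cs == REC_ACTIVE)
        mu_max, beta = table.mu_max[c], table.beta[c]
    else:
        mu_max, beta = s.growth.mu_N, 0.0
        if key.plasmid == LOST and s.antibiotic.enabled:
            mu_max *= heaviside_growth_gate(A, s.antibiotic.MIC)
    return mu_max, beta


def _scenario_rate_table(s: Scenario) -> CassetteRateTable:
    convention = (s.circuit.naive_convention if s.circuit.architecture == "naive"
                  else "2x*")
    return cassette_rate_table(s.growth, s.circuit.n_cassettes, convention)


def _structural_successors(key: CellClassKey, circuit: CircuitSpec,
                           plasmid_event_mode: str) -> list[CellClassKey]:
    """All one-event successors, independent of rate values (for reachability)."""
    out: list[CellClassKey] = []
    cas = list(key.cassette_states)
    if circuit.architecture == "differentiation":
        for i, cs in enumerate(cas):
            moves = []
            if cs == INTACT:
                moves = [INTACT_BM, DIFF_MUT, REC_ACTIVE]
            elif cs == INTACT_BM:
                moves = [DIFF_MUT, REC_BM]
            elif cs == REC_ACTIVE:
                moves = [REC_BM]
            for new in moves:
                if new in _RECOMBINED and key.integrase_functional == 0:
                    continue  # differentiation needs functional integrase
                nxt = cas.copy()
                nxt[i] = new
                out.append(_with_div_index(_sorted_cassettes(nxt),
                                           key.integrase_functional, key.plasmid,
                                           key.div_index, circuit))
        if key.integrase_functional > 0:
            out.append(_with_div_index(key.cassette_states,
                                       key.integrase_functional - 1, key.plasmid,
                                       key.div_index, circuit))
    else:  # naive: only burden mutation of active cassettes
        for i, cs in enumerate(cas):
            if cs == REC_ACTIVE:
                nxt = cas.copy()
                nxt[i] = REC_BM
                out.append(key._replace(cassette_states=_sorted_cassettes(nxt)))
    if key.plasmid == PRESENT and plasmid_event_mode != "none":
        target_plasmid = LOST if plasmid_event_mode == "loss" else MUTATED
        out.append(key._replace(plasmid=target_plasmid))
    if key.div_index != DIV_NONE and key.div_index < circuit.n_div:
        out.append(key._replace(div_index=key.div_index + 1))
    return out


def initial_class(circuit: CircuitSpec) -> CellClassKey:
    """Fully functional founder genotype."""
    if circuit.architecture == "naive":
        cassettes = _sorted_cassettes([REC_ACTIVE] * circuit.n_cassettes)
    else:
        cassettes = _sorted_cassettes([INTACT] * circuit.n_cassettes)
    return CellClassKey(cassettes, circuit.n_integrase, PRESENT, DIV_NONE)


def enumerate_classes(circuit: CircuitSpec, plasmid_event_mode: str = "none"
                      ) -> list[CellClassKey]:
    """Deterministically ordered list of reachable genotype classes.

    Breadth-first search over the one-event transition graph from the
    founder genotype, then sorted by a canonical key (cassette states,
    integrase count descending, plasmid state, division index) so the
    ordering is documented and stable.
    """
    start = initial_class(circuit)
    seen = {start}
    queue = deque([start])
    while queue:
        key = queue.popleft()
        for nxt in _structural_successors(key, circuit, plasmid_event_mode):
            if nxt not in seen:
                seen.add(nxt)
                queue.append(nxt)

    def sort_key(k: CellClassKey):
        return (tuple(_CASSETTE_ORDER.index(c) for c in k.cassette_states),
                -k.integrase_functional,
                (PRESENT, MUTATED, LOST).index(k.plasmid),
                k.div_index)

    return sorted(seen, key=sort_key)


def transition_table(key: CellClassKey, scenario: Scenario) -> list[Transition]:
    """Mutation, plasmid and differentiation transitions out of one class.

    Mutation/plasmid coefficients are dimensionless (to be multiplied by
    ``mu_spec * dt`` for a per-step probability); differentiation entries
    carry a first-order rate in h⁻¹ — ``k_diff`` scaled by the functional
    fraction of integrase cassettes — and are applied as deterministic
    fluxes, not draws.  Coefficients are multiplied by the number of
    cassettes in the source state.
    """
    s = scenario
    circuit, mut = s.circuit, s.mutation
    out: list[Transition] = []
    cas = list(key.cassette_states)

    def make(i: int, new_state: str) -> CellClassKey:
        nxt = cas.copy()
        nxt[i] = new_state
        return _with_div_index(_sorted_cassettes(nxt), key.integrase_functional,
                               key.plasmid, key.div_index, circuit)

    counted: dict[str, int] = {}
    for cs in cas:
        counted[cs] = counted.get(cs, 0) + 1
    first_index = {cs: cas.index(cs) for cs in counted}

    diff_rate_per_cassette = 0.0
    if circuit.architecture == "differentiation" and circuit.n_integrase > 0:
        diff_rate_per_cassette = (circuit.k_diff * key.integrase_functional
                                  / circuit.n_integrase)

    for cs, m in counted.items():
        i = first_index[cs]
        if circuit.architecture == "differentiation":
            if cs == INTACT:
                if mut.k_MB > 0:
                    out.append(Transition(make(i, INTACT_BM), "burden", m * mut.k_MB))
                if mut.k_MD > 0:
                    out.append(Transition(make(i, DIFF_MUT), "diff_mut", m * mut.k_MD))
                if diff_rate_per_cassette > 0:
                    out.append(Transition(make(i, REC_ACTIVE), "differentiation",
                                          m * diff_rate_per_cassette))
            elif cs == INTACT_BM:
                if mut.k_MD > 0:
                    out.append(Transition(make(i, DIFF_MUT), "diff_mut", m * mut.k_MD))
                if diff_rate_per_cassette > 0:
                    out.append(Transition(make(i, REC_BM), "differentiation",
                                          m * diff_rate_per_cassette))
            elif cs == REC_ACTIVE and mut.k_MB > 0:
                out.append(Transition(make(i, REC_BM), "burden", m * mut.k_MB))
        else:
            if cs == REC_ACTIVE and mut.k_MB > 0:
                out.append(Transition(make(i, REC_BM), "burden", m * mut.k_MB))

    if (circuit.architecture == "differentiation" and key.integrase_functional > 0
            and mut.k_MI > 0):
        target = _with_div_index(key.cassette_states, key.integrase_functional - 1,
                                 key.plasmid, key.div_index, circuit)
        out.append(Transition(target, "integrase",
                              key.integrase_functional * mut.k_MI))

    mode = s.antibiotic.plasmid_event_mode
    if key.plasmid == PRESENT and mode != "none" and mut.k_PL > 0:
        target_plasmid = LOST if mode == "loss" else MUTATED
        target = key._replace(plasmid=target_plasmid)
        out.append(Transition(target, "plasmid", mut.k_PL))
    return out


# ---------------------------------------------------------------------------


@dataclass
class BatchState:
    """Mutable simulation state: class counts plus culture-level quantities."""

    counts: np.ndarray  # aligned with SerialBatchSimulator.classes
    antibiotic: float
    cumulative_production: float
    time: float
    batch_index: int
    clamp_events: int = 0
    clamped_mass: float = 0.0


@dataclass
class StochasticResult:
    """One replicate: trajectory, per-batch endpoints, seed and scenario id."""

    trajectory: Trajectory
    batch_endpoints: pd.DataFrame
    seed: int
    scenario_id: str
    classes: list[CellClassKey] = field(default_factory=list)

    @property
    def total_production(self) -> float:
        return float(self.trajectory.cumulative_production[-1])


def class_group(key: CellClassKey, scenario: Scenario) -> str:
    """Coarse reporting group for a genotype class."""
    if key.plasmid == PRESENT and any(c == REC_ACTIVE for c in key.cassette_states):
        return "producer"
    if any(c in _RECOMBINED for c in key.cassette_states):
        return "differentiated_nonproducer"
    if (any(c in _RECOMBINABLE for c in key.cassette_states)
            and key.integrase_functional > 0):
        return "progenitor"
    return "non_differentiator"


class SerialBatchSimulator:
    """Compiled per-scenario engine: class list, rate vectors, transitions."""

    def __init__(self, scenario: Scenario):
        s = validate_scenario(scenario)
        self.scenario = s
        circuit, env, abx = s.circuit, s.environment, s.antibiotic
        self.classes = enumerate_classes(circuit, abx.plasmid_event_mode)
        self.labels = [k.label() for k in self.classes]
        index = {k: i for i, k in enumerate(self.classes)}
        n = len(self.classes)

        self.mu_max = np.zeros(n)
        self.beta = np.zeros(n)
        self.gated = np.zeros(n, dtype=bool)   # Heaviside MIC gate applies
        self.degrader = np.zeros(n, dtype=bool)
        self.is_ladder = np.zeros(n, dtype=bool)
        rung_src, rung_dst = [], []
        for i, key in enumerate(self.classes):
            self.mu_max[i], self.beta[i] = class_rates(key, s, A=0.0)
            self.gated[i] = key.plasmid == LOST and abx.enabled
            self.degrader[i] = key.plasmid in (PRESENT, MUTATED)
            if key.div_index != DIV_NONE:
                self.is_ladder[i] = True
                if key.div_index < circuit.n_div:
                    rung_src.append(i)
                    rung_dst.append(index[key._replace(div_index=key.div_index + 1)])
        self.rung_src = np.array(rung_src, dtype=np.intp)
        self.rung_dst = np.array(rung_dst, dtype=np.intp)

        diff_src, diff_dst, diff_rate = [], [], []
        mut_src, mut_dst, mut_coeff = [], [], []
        for i, key in enumerate(self.classes):
            for tr in transition_table(key, s):
                j = index[tr.target]
                if tr.kind == "differentiation":
                    diff_src.append(i)
                    diff_dst.append(j)
                    diff_rate.append(tr.coefficient)
                else:
                    mut_src.append(i)
                    mut_dst.append(j)
                    mut_coeff.append(tr.coefficient)
        self.diff_src = np.array(diff_src, dtype=np.intp)
        self.diff_dst = np.array(diff_dst, dtype=np.intp)
        self.diff_rate = np.array(diff_rate)
        self.mut_src = np.array(mut_src, dtype=np.intp)
        self.mut_dst = np.array(mut_dst, dtype=np.intp)
        self.mut_coeff = np.array(mut_coeff)

        self.start_index = index[initial_class(circuit)]
        self.dt = env.dt
        self.K = env.K
        self.groups = [class_group(k, s) for k in self.classes]

    # -- state construction -------------------------------------------------

    def initial_state(self) -> BatchState:
        counts = np.zeros(len(self.classes))
        counts[self.start_index] = self.scenario.environment.N0
        A0 = self.scenario.antibiotic.A0 if self.scenario.antibiotic.enabled else 0.0
        return BatchState(counts=counts, antibiotic=A0,
                          cumulative_production=0.0, time=0.0, batch_index=0)

    # -- one Euler step -----------------------------------------------------

    def step(self, state: BatchState, rng: np.random.Generator) -> BatchState:
        s = self.scenario
        dt = self.dt
        counts = state.counts
        A = state.antibiotic

        N_tot = counts.sum()
        factor = max(0.0, 1.0 - N_tot / self.K)
        gate = 0.0 if (s.antibiotic.enabled and A >= s.antibiotic.MIC) else 1.0
        eff = np.where(self.gated, gate * factor, factor)
        mu_spec = self.mu_max * eff

        # production from start-of-step counts (left-endpoint quadrature);
        # producing classes always carry the plasmid, so the ratio
        # mu_spec/mu_max reduces to the logistic factor
        flux = factor * float(self.beta @ counts)

        # deterministic growth (ladder rungs lose at mu: division or death)
        growth = np.where(self.is_ladder, -mu_spec * counts, mu_spec * counts)
        new = counts + dt * growth
        if self.rung_src.size:
            np.add.at(new, self.rung_dst,
                      2.0 * dt * mu_spec[self.rung_src] * counts[self.rung_src])

        # deterministic differentiation, from start-of-step counts
        if self.diff_src.size:
            dflux = dt * self.diff_rate * counts[self.diff_src]
            np.subtract.at(new, self.diff_src, dflux)
            np.add.at(new, self.diff_dst, dflux)

        # stochastic mutation / plasmid events: binomial over rounded counts
        if self.mut_src.size:
            p = np.clip(self.mut_coeff * mu_spec[self.mut_src] * dt, 0.0, 1.0)
            n_cells = np.maximum(np.rint(new[self.mut_src]), 0.0).astype(np.int64)
            events = rng.binomial(n_cells, p).astype(float)
            if events.any():
                avail = np.maximum(new, 0.0)
                outflow = np.zeros_like(new)
                np.add.at(outflow, self.mut_src, events)
                over = outflow > avail
                if over.any():
                    scale = np.ones_like(new)
                    scale[over] = avail[over] / outflow[over]
                    events = events * scale[self.mut_src]
                np.subtract.at(new, self.mut_src, events)
                np.add.at(new, self.mut_dst, events)

        # communal antibiotic degradation by plasmid-bearing cells
        if s.antibiotic.enabled:
            degraders = float(new[self.degrader].sum())
            A = antibiotic_step(A, degraders, s.antibiotic.Vmax,
                                s.antibiotic.Km, dt)

        clamp_events = state.clamp_events
        clamped_mass = state.clamped_mass
        neg = new < 0
        if neg.any():
            clamp_events += int(neg.sum())
            clamped_mass += float(-new[neg].sum())
            new[neg] = 0.0

        return BatchState(counts=new, antibiotic=A,
                          cumulative_production=state.cumulative_production
                          + flux * dt,
                          time=state.time + dt,
                          batch_index=state.batch_index,
                          clamp_events=clamp_events, clamped_mass=clamped_mass)

    def dilute(self, state: BatchState) -> BatchState:
        env, abx = self.scenario.environment, self.scenario.antibiotic
        return replace(state,
                       counts=state.counts / env.dilution_factor,
                       antibiotic=abx.A0 if abx.enabled else 0.0,
                       batch_index=state.batch_index + 1)

    # -- full run -----------------------------------------------------------

    def run_serial(self, seed: int, record_every: int = 10) -> StochasticResult:
        s = self.scenario
        env = s.environment
        if env.mode != "serial_batch":
            raise ValidationError("mode: run_serial requires serial_batch mode")
        rng = np.random.default_rng(seed)
        state = self.initial_state()
        steps_per_batch = int(round(env.batch_duration / env.dt))

        times, counts, rates, cums, abx_series, batch_series = [], [], [], [], [], []
        endpoints = []

        def record(st: BatchState) -> None:
            times.append(st.time)
            counts.append(st.counts.copy())
            factor = max(0.0, 1.0 - st.counts.sum() / self.K)
            rates.append(factor * float(self.beta @ st.counts))
            cums.append(st.cumulative_production)
            abx_series.append(st.antibiotic)
            batch_series.append(st.batch_index)

        record(state)
        group_names = sorted(set(self.groups))
        group_masks = {g: np.array([gg == g for gg in self.groups])
                       for g in group_names}
        for b in range(env.n_batches):
            for k in range(steps_per_batch):
                state = self.step(state, rng)
                if (k + 1) % record_every == 0 or k + 1 == steps_per_batch:
                    record(state)
            row = {"batch": b, "time": state.time,
                   "total": float(state.counts.sum()),
                   "antibiotic": state.antibiotic,
                   "cumulative_production": state.cumulative_production}
            for g in group_names:
                row[g] = float(state.counts[group_masks[g]].sum())
            endpoints.append(row)
            if b + 1 < env.n_batches:
                state = self.dilute(state)
                record(state)

        traj = Trajectory(time=np.array(times),
                          counts=np.array(counts),
                          labels=list(self.labels),
                          production_rate=np.array(rates),
                          cumulative_production=np.array(cums),
                          antibiotic=np.array(abx_series),
                          batch_index=np.array(batch_series),
                          clamp_events=state.clamp_events,
                          clamped_mass=state.clamped_mass,
                          meta={"scenario_id": s.scenario_id, "label": s.label,
                                "seed": seed})
        return StochasticResult(trajectory=traj,
                                batch_endpoints=pd.DataFrame(endpoints),
                                seed=seed, scenario_id=s.scenario_id,
                                classes=list(self.classes))


@functools.lru_cache(maxsize=64)
def _compiled(scenario: Scenario) -> SerialBatchSimulator:
    return SerialBatchSimulator(scenario)


def step(state: BatchState, scenario: Scenario,
         rng: np.random.Generator) -> BatchState:
    """One Euler step of the stochastic engine (compiles the scenario once)."""
    return _compiled(scenario).step(state, rng)


def run_serial(scenario: Scenario, seed: int,
               record_every: int = 10) -> StochasticResult:
    """Run one replicate of the serial-batch protocol."""
    return _compiled(scenario).run_serial(seed, record_every=record_every)


def replicate_runs(scenario: Scenario, n_replicates: int, base_seed: int,
                   record_every: int = 10) -> list[StochasticResult]:
    """Independent replicates with seeds ``base_seed + i`` (documented scheme)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    sim = _compiled(scenario)
    return [sim.run_serial(base_seed + i, record_every=record_every)
            for i in range(n_replicates)]
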