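"""Preset scenario grids emulating the study's modeling experiments.

These generators are the synthetic-input layer of the package: every
parameter they set is a stated study condition (growth rates, mutation
coefficients, culture protocol, antibiotic levels) and the grids are the
ones swept in the modeling experiments.

* :func:`preset_chemostat` — deterministic chemostat comparison of naive,
  differentiation and terminal differentiation: D = 0.1 h⁻¹, μ_N = 2 h⁻¹,
  k_MB = 10⁻⁶ (per unit growth), K = 10⁹ cells, N0 = 8×10⁸, 1000 h,
  burden ∈ {10, 50, 90}%, k_MD ∈ {10⁻⁶, 10⁻¹², 10⁻¹⁸}, n_div = 4.
* :func:`preset_serial_batch` — stochastic serial-batch sweeps: 20 batches
  of 8 h with 1:50 dilutions, K = 10⁹; architectures 1x/2x/2x* naive and
  1x/2x differentiation ± terminal; k_diff ∈ {0.2 … 1.2} h⁻¹; plasmid-loss
  arm (k_PL = 10⁻⁴, 100 μg/mL antibiotic, MIC = 1.1 μg/mL,
  Vmax ∈ {0, 2.52×10⁻⁶, 1.26×10⁻⁵} μg·cell⁻¹·h⁻¹) and plasmid-mutation arm
  (k_PL ∈ {10⁻⁸, 10⁻⁶, 10⁻⁴}, no antibiotic, Vmax = 0).
* :func:`preset_ndiv_sweep` — terminal differentiation varying the division
  limit n_div at low and high burden.

The chemostat preset's differentiation rate defaults to k_diff = 0.6 h⁻¹
(the middle of the serial-batch grid) and the full grid is exposed for the
production-versus-k_diff tradeoff analysis.
"""

from __future__ import annotations

from typing import Sequence

from .params import (AntibioticSpec, CircuitSpec, EnvironmentSpec, GrowthParams,
                     MutationRates, Scenario, validate_scenario)

__all__ = [
    "KDIFF_GRID",
    "BURDEN_GRID",
    "KMD_GRID",
    "ARCHITECTURES_SERIAL",
    "preset_chemostat",
    "preset_serial_batch",
    "preset_ndiv_sweep",
    "get_preset",
]

KDIFF_GRID = (0.2, 0.4, 0.6, 0.8, 1.0, 1.2)
BURDEN_GRID = (10.0, 50.0, 90.0)
KMD_GRID = (1e-6, 1e-12, 1e-18)
ARCHITECTURES_SERIAL = ("1x_naive", "2x_naive", "2xstar_naive",
                        "1x_diff", "1x_term", "2x_diff", "2x_term")

MU_N = 2.0
K_MB = 1e-6
N_DIV = 4


def _circuit(arch: str, k_diff: float = 0.0, n_div: int = N_DIV) -> CircuitSpec:
    if arch == "1x_naive":
        return CircuitSpec("naive", n_cassettes=1)
    if arch == "2x_naive":
        return CircuitSpec("naive", n_cassettes=2, naive_convention="2x")
    if arch == "2xstar_naive":
        return CircuitSpec("naive", n_cassettes=2, naive_convention="2x*")
    n_cas = 2 if arch.startswith("2x") else 1
    terminal = arch.endswith("term")
    return CircuitSpec("differentiation", n_cassettes=n_cas, terminal=terminal,
                       k_diff=k_diff, n_div=n_div)


def preset_chemostat(burdens: Sequence[float] = BURDEN_GRID,
                     k_MDs: Sequence[float] = KMD_GRID,
                     k_diff: float = 0.6,
                     include_kdiff_grid: bool = True) -> list[Scenario]:
    """Deterministic chemostat scenarios (single-cassette abstraction)."""
    env = EnvironmentSpec(mode="chemostat", K=1e9, N0=8e8, dt=0.01,
                          D=0.1, t_end=1000.0)
    out: list[Scenario] = []
    for b in burdens:
        growth = GrowthParams.from_burden(MU_N, b)
        out.append(validate_scenario(
            growth, MutationRates(k_MB=K_MB),
            CircuitSpec("naive"), env, AntibioticSpec(),
            label=f"naive_b{b:g}"))
        for terminal in (False, True):
            arch = "term" if terminal else "diff"
            for k_MD in k_MDs:
                out.append(validate_scenario(
                    growth, MutationRates(k_MB=K_MB, k_MD=k_MD),
                    CircuitSpec("differentiation", terminal=terminal,
                                k_diff=k_diff, n_div=N_DIV),
                    env, AntibioticSpec(),
                    label=f"{arch}_b{b:g}_kMD{k_MD:g}"))
    if include_kdiff_grid:
        growth = GrowthParams.from_burden(MU_N, 50.0)
        for kd in KDIFF_GRID:
            out.append(validate_scenario(
                growth, MutationRates(k_MB=K_MB, k_MD=1e-6),
                CircuitSpec("differentiation", terminal=True,
                            k_diff=kd, n_div=N_DIV),
                env, AntibioticSpec(),
                label=f"term_b50_kdiff{kd:g}"))
    return out


def _serial_env() -> EnvironmentSpec:
    return EnvironmentSpec(mode="serial_batch", K=1e9, N0=1e9 / 50, dt=0.01,
                           batch_duration=8.0, n_batches=20,
                           dilution_factor=50.0)


_LOSS_VMAX = (0.0, 2.52e-6, 1.26e-5)
_MUTATION_KPL = (1e-8, 1e-6, 1e-4)


def _arms(which: Sequence[str]) -> list[tuple[str, float, AntibioticSpec]]:
    arms: list[tuple[str, float, AntibioticSpec]] = []
    if "baseline" in which:
        arms.append(("baseline", 0.0, AntibioticSpec()))
    if "loss" in which:
        for vmax in _LOSS_VMAX:
            arms.append((f"loss_V{vmax:g}", 1e-4,
                         AntibioticSpec(enabled=True, A0=100.0, MIC=1.1,
                                        Vmax=vmax, plasmid_event_mode="loss")))
    if "mutation" in which:
        for k_PL in _MUTATION_KPL:
            arms.append((f"mut_kPL{k_PL:g}", k_PL,
                         AntibioticSpec(enabled=False, Vmax=0.0,
                                        plasmid_event_mode="mutation")))
    return arms


def preset_serial_batch(architectures: Sequence[str] = ARCHITECTURES_SERIAL,
                        burdens: Sequence[float] = BURDEN_GRID,
                        k_diffs: Sequence[float] = KDIFF_GRID,
                        arms: Sequence[str] = ("baseline", "loss", "mutation"),
                        n_batches: int = 20) -> list[Scenario]:
    """Stochastic serial-batch scenario grid.

    The full default grid is large (hundreds of scenarios); the keyword
    filters select sub-grids for targeted analyses.
    """
    env = _serial_env()
    if n_batches != env.n_batches:
        env = EnvironmentSpec(mode="serial_batch", K=env.K, N0=env.N0, dt=env.dt,
                              batch_duration=env.batch_duration,
                              n_batches=n_batches,
                              dilution_factor=env.dilution_factor)
    out: list[Scenario] = []
    for arch in architectures:
        kd_values: Sequence[float] = (0.0,) if arch.endswith("naive") else k_diffs
        for b in burdens:
            growth = GrowthParams.from_burden(MU_N, b)
            for kd in kd_values:
                for arm_label, k_PL, abx in _arms(arms):
                    mut = MutationRates(k_MB=K_MB, k_MD=K_MB, k_MI=K_MB,
                                        k_PL=k_PL)
                    kd_tag = "" if arch.endswith("naive") else f"_kdiff{kd:g}"
                    out.append(validate_scenario(
                        growth, mut, _circuit(arch, kd), env, abx,
                        label=f"{arch}_b{b:g}{kd_tag}_{arm_label}"))
    return out


def preset_ndiv_sweep(n_divs: Sequence[int] = (0, 1, 2, 4, 8, 16),
                      burdens: Sequence[float] = (10.0, 90.0),
                      k_diff: float = 0.6) -> list[Scenario]:
    """Terminal differentiation varying the post-differentiation division
    limit, all else as the serial-batch baseline arm."""
    env = _serial_env()
    out: list[Scenario] = []
    for arch in ("1x_term", "2x_term"):
        for b in burdens:
            growth = GrowthParams.from_burden(MU_N, b)
            for n_div in n_divs:
                mut = MutationRates(k_MB=K_MB, k_MD=K_MB, k_MI=K_MB)
                out.append(validate_scenario(
                    growth, mut, _circuit(arch, k_diff, n_div=n_div), env,
                    AntibioticSpec(),
                    label=f"{arch}_b{b:g}_ndiv{n_div}"))
    return out


_PRESETS = {
    "chemostat": preset_chemostat,
    "serial": preset_serial_batch,
    "ndiv": preset_ndiv_sweep,
}


def get_preset(name: str, **kwargs) -> list[Scenario]:
    """Look up a preset generator by CLI name: chemostat, serial or ndiv."""
    try:
        fn = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    return fn(**kwargs)
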