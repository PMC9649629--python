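import pytest

import burdensim as bs


def chemostat_scenario(architecture="naive", burden=50.0, k_MB=1e-6, k_MD=0.0,
                       terminal=False, k_diff=0.6, n_div=4, t_end=1000.0,
                       D=0.1, N0=8e8, dt=0.01, mu_N=2.0):
    """Chemostat scenario with the standard study conditions."""
    if architecture == "naive":
        circuit = bs.CircuitSpec("naive")
    else:
        circuit = bs.CircuitSpec("differentiation", terminal=terminal,
                                 k_diff=k_diff, n_div=n_div)
    return bs.validate_scenario(
        bs.GrowthParams.from_burden(mu_N, burden),
        bs.MutationRates(k_MB=k_MB, k_MD=k_MD),
        circuit,
        bs.EnvironmentSpec(mode="chemostat", K=1e9, N0=N0, dt=dt, D=D,
                           t_end=t_end),
        label=f"{architecture}{'_term' if terminal else ''}_b{burden:g}",
    )


def serial_scenario(architecture="1x_term", burden=50.0, k_diff=0.6,
                    n_batches=20, n_div=4, k_MB=1e-6, k_MD=1e-6, k_MI=1e-6,
                    k_PL=0.0, plasmid_event_mode="none", abx_enabled=False,
                    A0=0.0, Vmax=0.0, dt=0.01, pi_rule="any"):
    """Serial-batch scenario with the standard 20x8h, 1:50 protocol."""
    n_cas = 2 if architecture.startswith("2x") else 1
    if architecture.endswith("naive"):
        conv = "2x*" if "star" in architecture else "2x"
        circuit = bs.CircuitSpec("naive", n_cassettes=n_cas,
                                 naive_convention=conv)
    else:
        circuit = bs.CircuitSpec("differentiation", n_cassettes=n_cas,
                                 terminal=architecture.endswith("term"),
                                 k_diff=k_diff, n_div=n_div, pi_rule=pi_rule)
    return bs.validate_scenario(
        bs.GrowthParams.from_burden(2.0, burden),
        bs.MutationRates(k_MB=k_MB, k_MD=k_MD, k_MI=k_MI, k_PL=k_PL),
        circuit,
        bs.EnvironmentSpec(mode="serial_batch", K=1e9, N0=2e7, dt=dt,
                           batch_duration=8.0, n_batches=n_batches,
                           dilution_factor=50.0),
        bs.AntibioticSpec(enabled=abx_enabled, A0=A0, MIC=1.1, Vmax=Vmax,
                          plasmid_event_mode=plasmid_event_mode),
        label=architecture,
    )


@pytest.fixture(scope="session")
def fig_style_naive_run():
    """50% burden naive chemostat run (producers overtaken by non-producers)."""
    return bs.simulate_architecture(chemostat_scenario("naive", 50.0),
                                    record_every=10)
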