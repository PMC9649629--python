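"""Plasmid-mutation robustness: naive expression vs terminal differentiation.

The burdensome function is driven from a high-copy plasmid; a stochastic
plasmid mutation relieves the burden without affecting antibiotic
resistance.  Under naive expression such mutants sweep; under terminal
differentiation every differentiated cell dies after n_div divisions, so
burden relief confers no lasting advantage.
"""

import numpy as np

import burdensim as bs

env = bs.EnvironmentSpec(mode="serial_batch", K=1e9, N0=2e7, dt=0.01,
                         batch_duration=8.0, n_batches=20,
                         dilution_factor=50.0)
growth = bs.GrowthParams.from_burden(2.0, 50.0)
abx = bs.AntibioticSpec(enabled=False, plasmid_event_mode="mutation")

for arch, circuit in [
        ("2x naive", bs.CircuitSpec("naive", n_cassettes=2)),
        ("2x terminal", bs.CircuitSpec("differentiation", n_cassettes=2,
                                       terminal=True, k_diff=0.6, n_div=4))]:
    for k_PL in (1e-8, 1e-4):
        mut = bs.MutationRates(k_MB=1e-6, k_MD=1e-6, k_MI=1e-6, k_PL=k_PL)
        scenario = bs.validate_scenario(growth, mut, circuit, env, abx,
                                        label=arch)
        results = bs.replicate_runs(scenario, 4, base_seed=11)
        mean = np.mean([r.total_production for r in results])
        print(f"{arch:12} k_PL={k_PL:g}: mean total production {mean:.3e}")
    print()

print("Raising the plasmid-mutation coefficient 1e-8 -> 1e-4 collapses")
print("naive production but leaves terminal differentiation nearly unchanged.")
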