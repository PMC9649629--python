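"""Deterministic chemostat comparison of expression strategies.

Runs naive expression and terminal differentiation at 50% burden for
1000 h (D = 0.1 h^-1, K = 1e9 cells) and prints total production and the
duration of function (time to reach 95% of final cumulative production).
Naive producers are overtaken by burden mutants; terminal differentiation's
duration is set by non-differentiator takeover instead, which does not
depend on the burden level.
"""

import burdensim as bs

env = bs.EnvironmentSpec(mode="chemostat", K=1e9, N0=8e8, dt=0.01, D=0.1,
                         t_end=1000.0)
growth = bs.GrowthParams.from_burden(2.0, 50.0)

naive = bs.validate_scenario(growth, bs.MutationRates(k_MB=1e-6),
                             bs.CircuitSpec("naive"), env, label="naive")
terminal = bs.validate_scenario(
    growth, bs.MutationRates(k_MB=1e-6, k_MD=1e-6),
    bs.CircuitSpec("differentiation", terminal=True, k_diff=0.6, n_div=4),
    env, label="terminal")

for scenario in (naive, terminal):
    traj = bs.simulate_architecture(scenario, record_every=10)
    total = bs.total_production(traj)
    duration = bs.duration_of_function(traj)
    print(f"{scenario.label:>9}: total production {total:.3e} units, "
          f"duration of function {duration:6.1f} h")

print()
print("Naive production lasts longer here (50% burden, 1000 h horizon) but")
print("collapses sharply as burden rises; terminal duration tracks the")
print("non-differentiator takeover time ~ ln(1/k_MD)/k_diff instead.")
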