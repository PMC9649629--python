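"""Growth/production rates of one- and two-cassette producers.

With a non-producer growing at mu_N and a reference producer at mu_P, the
two-cassette conventions fix which cell mu_P describes; the other case is
derived so each cassette contributes the same proportional growth-rate cost
and production rises linearly with the growth-rate decrease.
"""

import burdensim as bs

mu_N, mu_P = 1.0, 0.5

for convention in ("2x", "2x*"):
    table = bs.two_cassette_rates(mu_N, mu_P, convention)
    print(f"convention {convention}: (growth rate h^-1, production share) "
          f"by active-cassette count")
    for c in range(3):
        print(f"  {c} active: mu_max = {table.mu_max[c]:.5f}, "
              f"beta = {table.beta[c]:.5f}")

print()
print("Under 2x*, activating the second cassette compounds the burden")
print("(0.5 -> 0.25 h^-1) and raises the production share above 1 (1.5):")
print("two active copies produce 1.5x what the reference producer does.")
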