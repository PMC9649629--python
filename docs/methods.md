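# Methods

## Scope and model structure

`burdensim` models the population genetics of a burdensome engineered
function under three expression strategies — naive, differentiation, and
terminal differentiation — with two engines that share one set of rate
laws (`burdensim.rates`):

1. a **deterministic chemostat** engine (`burdensim.chemostat`) for the
   single-cassette abstraction of each strategy, and
2. a **stochastic serial-batch** engine (`burdensim.batch`) with explicit
   per-cassette genotypes, integrase copies, plasmid state and antibiotic
   dynamics.

Both integrate with fixed-step forward Euler at `dt = 0.01 h`.

## Growth, burden and production

Growth is logistic: every class's specific rate is
`μ_spec = μ_max · max(0, 1 − N_tot/K)`. Non-producers (progenitors,
burden mutants, non-differentiators) grow at `μ_N`; producers at `μ_P`;
the burden is `b = 1 − μ_P/μ_N` and may be given as a percent
(`GrowthParams.from_burden`). `μ_P = 0` (100% burden) is disallowed: the
two-cassette production shares divide by `μ_N − μ_P`, and no study
condition uses either extreme.

Each producing cell makes 1 arbitrary unit·h⁻¹ scaled by
`β · μ_spec/μ_max`; since producing classes always carry the plasmid, the
ratio reduces to the logistic factor. Cumulative production uses
left-endpoint quadrature (flux evaluated at the start of each Euler step),
identically in both engines.

With two cassettes each active copy imposes the same proportional
growth-rate cost: the `2x` convention
takes a both-active cell at `μ_P` and derives one-active as
`μ_1 = μ_N √(μ_P/μ_N)` with share `β_1 = (μ_N − μ_1)/(μ_N − μ_P)`; the
`2x*` convention takes one-active at `μ_P` and derives both-active as
`μ_2 = μ_P²/μ_N` with `β_2 = (μ_N − μ_2)/(μ_N − μ_P)` (> 1). Two-cassette
differentiation always uses the `2x*` reading (its reference producer is a
cell with one activated cassette). Production share rises linearly with
the growth-rate decrease in both conventions; `β` is monotone
non-decreasing and `μ_max` non-increasing in the active-copy count, which
is enforced by the rate-table container and property-tested.

## Mutation and differentiation rates

Mutation coefficients are per unit growth: the per-step probability (or
deterministic flux fraction) is `k · μ_spec · dt`, clamped to [0, 1], so
cells that do not grow do not mutate. Coefficients: `k_MB` (burden
mutation, silences an active or intact cassette's product), `k_MD`
(differentiation mutation, makes a cassette recombination-incompetent),
`k_MI` (integrase mutation, per functional copy: a cell with `f` copies
loses one at aggregate `f · k_MI`), `k_PL` (plasmid event). The study
conditions set `k_MB = k_MD = k_MI = 10⁻⁶`.

Differentiation is first order in time, not growth-scaled: its rate
constant is stated in h⁻¹. Per recombinable cassette the rate is
`k_diff · f/n_integrase`, linear in the functional integrase fraction and
normalized so the stated `k_diff` applies to fully functional cells
(`n_integrase = 2` in all presets). Burden-mutated progenitors
differentiate at the unchanged `k_diff` (the mutation disables the
payload, not the differentiation machinery) and yield non-producing
differentiated cells.

## The division ladder (terminal selection)

Under terminal selection a differentiated cell carries a division index
`i`, starting at 0 on the recombination event that ends replication of the
selection plasmid. A cell at rung `i < n_div` divides at `μ_spec` into two
cells at `i + 1`; cells at `i = n_div` die at `μ_spec` instead of
dividing. The death rate is therefore throttled by the same logistic
factor as growth. One differentiation event yields exactly `2^n_div`
deaths' worth of descendants (`ladder_impulse_response` integrates the
impulse response; the suite checks 16 at `n_div = 4`).

For the two-cassette circuit the replication factor of the selection
plasmid is split between the cassettes, so the **first** recombination
ablates it and starts the ladder (`pi_rule="any"`, the default). The
variant in which a redundant full-length factor survives until every
cassette has recombined is available as `pi_rule="all"`. The choice
matters: under `"all"`, singly recombined cells are a long-lived producing
population in which burden-relieving plasmid mutations sweep, and the
plasmid-robustness contrast between naive and terminal architectures
disappears.

## Plasmid state and antibiotics

The product is driven from a high-copy plasmid treated as a binary state:
one stochastic event either **mutates** all copies (burden relieved,
production zero, antibiotic resistance intact) or **loses** them (burden
relieved, production zero, resistance lost). Plasmid-bearing cells —
present or mutated — degrade the selection antibiotic with
Michaelis–Menten kinetics (`Vmax`, `Km`), providing communal protection;
plasmid-free cells grow at `μ_N` below the MIC and not at all at or above
it (Heaviside gate). `Km` defaults to 1.0 μg/mL; it is a placeholder
half-saturation constant and no headline behaviour or test depends on its
value. The antibiotic pool models plasmid selection only; the
chloramphenicol selection that enforces terminal differentiation is
modeled implicitly by the division ladder.

## Environments

* **Chemostat**: constant dilution `D` applied to every class,
  `t_end = 1000 h`; study conditions `D = 0.1 h⁻¹`, `μ_N = 2 h⁻¹`,
  `K = 10⁹`, `N0 = 8×10⁸`.
* **Serial batch**: 20 batches of 8 h; between batches every class count is
  divided by 50 (deterministic scaling — the stochasticity of the model is
  confined to mutations; a sampled bottleneck would be an extension) and
  the antibiotic resets to `A0`. `N0 = K/50`. Cumulative production is a
  property of the culture lineage and is never diluted.

## Stochastic update order

Each serial-batch Euler step applies, in a fixed documented order:
(1) class-specific `μ_spec` from start-of-step totals; (2) deterministic
growth including ladder transfers and top-rung death; (3) deterministic
differentiation transfers; (4) binomial mutation draws — for each
transition, `Binomial(round(count), k·μ_spec·dt)` events moved from source
to target (counts are continuous, so the draw size is the rounded count;
if independent draws from one class exceed its content they are scaled
down proportionally); (5) antibiotic degradation; (6) production
accumulation; (7) time advance. The deterministic fluxes in (2)–(3) are
evaluated from start-of-step counts, so a run with all stochastic
coefficients zero reproduces the chemostat engine's update formula
exactly — the suite checks state-by-state agreement at `rtol = 10⁻⁹`
(floating-point summation order is the only difference). At `dt = 0.01 h`
the ordering of sub-steps is a second-order effect; the contract exists
for reproducibility. Negative abundances produced by an Euler undershoot
are clamped to zero and counted on the trajectory.

All randomness flows through one `numpy` generator per replicate;
replicate seeds are `base_seed + index`. Equal seeds give bit-identical
results.

## Metrics

* **Total production**: final value of the cumulative production series.
* **Duration of function**: earliest time at which cumulative production
  reaches 95% of its final value, linearly interpolated. The cumulative
  series is monotone, so "95% of max" is well defined. The alternative
  reading — time at which the instantaneous rate falls to 95% of its peak —
  is not used; it is noisier under stochastic batch dynamics and undefined
  for non-unimodal rate series.
* **Replicate summaries**: sample mean and SD (n−1) over replicates
  (default 8).

## Preset scenario grids

The presets (`burdensim.scenarios`) encode the study conditions: burden ∈
{10, 50, 90}%, `k_MD` ∈ {10⁻⁶, 10⁻¹², 10⁻¹⁸} (chemostat),
`k_diff` ∈ {0.2 … 1.2 h⁻¹}, `n_div = 4`; serial-batch plasmid-loss arm
(`k_PL = 10⁻⁴`, 100 μg/mL antibiotic, MIC 1.1 μg/mL,
`Vmax` ∈ {0, 2.52×10⁻⁶, 1.26×10⁻⁵} μg·cell⁻¹·h⁻¹) and plasmid-mutation arm
(`k_PL` ∈ {10⁻⁸, 10⁻⁶, 10⁻⁴}, no antibiotic). The serial-batch stated
growth rate is read as the unburdened `μ_N = 2 h⁻¹` with the burden
percent applied to it.

The chemostat preset needs a differentiation rate, which the study
conditions do not pin down; it defaults to `k_diff = 0.6 h⁻¹`, the middle
of the serial-batch grid, chosen once for comparability across engines.
This choice has one visible consequence (below).

## Design choices made where the design was open

* Carrying capacity as a multiplicative logistic factor on every class's
  maximal rate (simplest form consistent with all stated parameters), also
  applied to top-rung death.
* Differentiation not scaled by growth (stated in h⁻¹, unlike mutation
  coefficients).
* Non-differentiators arising from burden-mutated progenitors are merged
  with the plain non-differentiator class in the chemostat engine; the two
  are fitness-identical and the merge changes no observable.
* Binomial draw size `round(count)`; dilution deterministic; product never
  diluted; `pi_rule="any"` for split-factor circuits (see above).
* Chemostat-engine scope: the deterministic engine implements the
  single-cassette abstraction only; multi-cassette genotypes are the
  stochastic engine's domain (run it with zero coefficients for
  deterministic behaviour).

## What the synthetic scenarios do and do not emulate

The presets reproduce modeling conditions, not wet-lab data: real cultures
add plasmid copy-number fluctuation, bottleneck sampling at dilution,
recombination errors (e.g. inversions) with their own spectrum,
non-logistic growth phases and measurement noise. Passing tests show the
model's internal claims — fixed points, monotonicities, robustness
contrasts, conservation laws — hold for these idealized conditions; they
do not validate the model against experimental production curves.

## Numerical notes and limitations

* Forward Euler at `dt = 0.01 h` is the model's definition, not an
  approximation target; the suite nevertheless checks step-halving changes
  1000-h abundances by < 1% and that the mutation-free chemostat hits the
  analytic fixed point `K(1 − D/μ)` to well under 0.1%.
* Terminal-differentiation duration is set by non-differentiator takeover,
  `≈ ln(seed fraction)/k_diff` at fixed `k_MD`, and is burden-invariant in
  the limit where that time dominates the division-ladder transit time
  (`~ n_div/μ_P,spec`, burden-dependent). At the preset `k_diff = 0.6 h⁻¹`
  durations are ~30 h and the ladder contributes visibly: the measured
  spread across 10/50/90% burden is ~21%. At `k_diff = 0.1 h⁻¹`
  (durations ~150 h) the spread is under 5%, and with `k_MD = 0` it is
  under 0.1%. The burden-invariance claim should therefore be read as a
  statement about the takeover-dominated regime.
* In the 1000-h chemostat the production-maximizing differentiation rate
  lies near `ln(·)/t_end ≈ 0.03–0.05 h⁻¹`, below the serial-batch grid;
  over the 0.2–1.2 h⁻¹ grid under the 160-h serial protocol the optimum is
  interior (0.4 h⁻¹ under default conditions).
* Problem sizes: chemostat runs integrate 10⁵ steps over 13 classes;
  serial-batch runs integrate 1.6×10⁴ steps over 39 (1x) to ~250 (2x with
  plasmid states) classes; replicate counts default to 8.
* Not modeled: per-cell agent simulation, plasmid copy-number
  distributions, sequence-level mutation, spatial structure, substrate
  dynamics, and recombination-error outcome classes.
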