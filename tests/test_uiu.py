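"""UIU transmission model: unit behaviour, oracles, statistical invariants."""

import math

import numpy as np
import pytest

from cyclenet import (ColonyConfig, OscillatorConfig, UIUParams,
                      contact_transmission_time, generate_contact_sequence,
                      run_ensemble, simulate_run)
from tests.conftest import random_small_network, temporal_reachable_set, toy_network

INSTANT = UIUParams(beta=math.inf, mu=0.0)


class TestContactTransmissionTime:
    def test_zero_beta_never_transmits(self):
        rng = np.random.default_rng(0)
        assert all(contact_transmission_time(0.0, 0.0, 100.0, rng) is None
                   for _ in range(100))

    def test_infinite_beta_transmits_at_overlap_start(self):
        rng = np.random.default_rng(0)
        assert contact_transmission_time(math.inf, 5.0, 6.0, rng) == 5.0

    def test_success_probability_matches_exponential_law(self):
        # beta = 1 /s over a 1 s overlap: P(success) = 1 - exp(-1).
        rng = np.random.default_rng(42)
        n = 10 ** 5
        hits = sum(contact_transmission_time(1.0, 0.0, 1.0, rng) is not None
                   for _ in range(n))
        p = 1 - math.exp(-1)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se

    def test_empty_overlap_returns_none(self):
        rng = np.random.default_rng(0)
        assert contact_transmission_time(1.0, 10.0, 10.0, rng) is None


class TestSimulateRun:
    def test_final_set_equals_temporal_reachability(self):
        # mu = 0 with deterministic transmission: the informed set must be
        # exactly the time-respecting forward-reachable set from the seed.
        for seed in range(25):
            rng = np.random.default_rng(seed)
            net = random_small_network(rng)
            seed_ant = int(rng.integers(10))
            run = simulate_run(net, INSTANT, seed_ant, 0.0, net.duration_s,
                               np.random.default_rng(seed))
            informed = {int(a) for a, d in zip(run.ants, run.deltas) if d > 0}
            assert informed == temporal_reachable_set(net, seed_ant, 0.0,
                                                      net.duration_s)

    def test_beta_zero_only_seed_ever_informed(self):
        net = toy_network([(0, 1, 10.0, 500.0), (1, 2, 20.0, 600.0)], 1000.0)
        run = simulate_run(net, UIUParams(beta=0.0, mu=0.01), 0, 0.0, 1000.0,
                           np.random.default_rng(1))
        assert run.n_transmissions == 0
        assert (run.counts <= 1).all()
        assert run.extinct_at_s is not None  # single exponential loss

    def test_unknown_seed_ant_rejected(self):
        net = toy_network([(0, 1, 0.0, 10.0)], 100.0)
        with pytest.raises(KeyError):
            simulate_run(net, INSTANT, 99, 0.0, 100.0, np.random.default_rng(0))

    def test_contact_in_progress_joins_with_remaining_overlap(self):
        # Contact spans t0; instant transmission fires exactly at t0, not at
        # the original contact start.
        net = toy_network([(0, 1, 0.0, 100.0)], 200.0)
        run = simulate_run(net, INSTANT, 0, 50.0, 200.0,
                           np.random.default_rng(0))
        assert run.times[1] == pytest.approx(50.0)

    def test_max_once_per_contact(self):
        # With mu = 0, a single long contact can produce at most one
        # transmission however large beta is.
        net = toy_network([(0, 1, 0.0, 1000.0)], 1000.0)
        run = simulate_run(net, UIUParams(beta=10.0, mu=0.0), 0, 0.0, 1000.0,
                           np.random.default_rng(3))
        assert run.n_transmissions <= 1

    def test_transition_log_is_consistent(self):
        net = random_small_network(np.random.default_rng(5))
        run = simulate_run(net, UIUParams(beta=0.5, mu=0.01), 0, 0.0,
                           net.duration_s, np.random.default_rng(5))
        counts = run.counts
        assert (counts >= 0).all()
        assert run.deltas[0] == 1 and run.ants[0] == 0
        assert (np.abs(run.deltas) == 1).all()
        assert (np.diff(run.times) >= 0).all()
        if run.extinct_at_s is not None:
            assert counts[-1] == 0

    def test_quiescent_gap_kills_information(self):
        # Seed at an activity peak followed by a long silent gap: with
        # 1/mu shorter than the gap the information dies out before the next
        # peak in the majority of runs.
        rows = [(i, j, float(t), float(t) + 5.0)
                for t in range(0, 300, 10)
                for i, j in [(t // 10 % 5, (t // 10 + 1) % 5)] if i != j]
        net = toy_network(rows, duration_s=4000.0, ants=list(range(5)))
        params = UIUParams(beta=0.5, mu=0.01)  # 1/mu = 100 s << 3700 s gap
        extinct = 0
        for k in range(40):
            run = simulate_run(net, params, 0, 0.0, 4000.0,
                               np.random.default_rng(k))
            extinct += run.extinct_at_s is not None
        assert extinct > 30


class TestRunEnsemble:
    def test_single_run_ensemble(self, stationary_net):
        ens = run_ensemble(stationary_net, UIUParams(1.0, 0.01), 100.0, 1,
                           3600.0, 0)
        assert ens.n_runs == 1

    def test_same_master_seed_identical_ensembles(self, stationary_net):
        a = run_ensemble(stationary_net, UIUParams(0.5, 0.01), 100.0, 10,
                         3600.0, 77)
        b = run_ensemble(stationary_net, UIUParams(0.5, 0.01), 100.0, 10,
                         3600.0, 77)
        for ra, rb in zip(a.runs, b.runs):
            assert ra.seed_ant == rb.seed_ant
            np.testing.assert_array_equal(ra.times, rb.times)
            np.testing.assert_array_equal(ra.ants, rb.ants)

    def test_enumeration_oracle_three_ant_chain(self):
        # Three ants, three sequential contacts, mu = 0: every outcome is a
        # subset of transmission successes with probability
        # p = 1 - exp(-beta * duration) each.  Exhaustive outcome-tree
        # enumeration gives the exact mean informed count over time.
        beta = 0.2
        net = toy_network([(0, 1, 10.0, 20.0), (1, 2, 30.0, 40.0),
                           (0, 2, 50.0, 60.0)], duration_s=100.0,
                          ants=[0, 1, 2])
        p = 1 - math.exp(-beta * 10.0)
        checkpoints = [25.0, 45.0, 65.0]

        def enumerate_mean(seed_ant):
            # informed sets evolve contact by contact; branch on each
            # U-I contact succeeding (prob p) or not.
            contacts = [((0, 1), 25.0), ((1, 2), 45.0), ((0, 2), 65.0)]
            states = {(frozenset([seed_ant])): 1.0}
            mean_at = {}
            order = [((0, 1), 20.0), ((1, 2), 40.0), ((0, 2), 60.0)]
            # evaluate checkpoints interleaved with contacts
            timeline = [(20.0, (0, 1)), (40.0, (1, 2)), (60.0, (0, 2))]
            cp = sorted(checkpoints)
            cp_means = []
            ci = 0
            for t_check in cp:
                while ci < len(timeline) and timeline[ci][0] <= t_check:
                    pair = timeline[ci][1]
                    new_states = {}
                    for s, prob in states.items():
                        a, b = pair
                        if (a in s) != (b in s):
                            new_states[s | {a, b}] = new_states.get(s | {a, b}, 0.0) \
                                + prob * p
                            new_states[s] = new_states.get(s, 0.0) + prob * (1 - p)
                        else:
                            new_states[s] = new_states.get(s, 0.0) + prob
                    states = {frozenset(k): v for k, v in new_states.items()}
                    ci += 1
                cp_means.append(sum(len(s) * prob for s, prob in states.items()))
            return np.array(cp_means)

        expected = np.mean([enumerate_mean(a) for a in (0, 1, 2)], axis=0)
        n_runs = 3000
        ens = run_ensemble(net, UIUParams(beta=beta, mu=0.0), 0.0, n_runs,
                           100.0, 123)
        counts = ens.counts_at(checkpoints)
        observed = counts.mean(axis=0)
        se = counts.std(axis=0, ddof=1) / math.sqrt(n_runs)
        assert (np.abs(observed - expected) < 3 * se + 1e-12).all()

    def test_max_once_rule_bounds_transmissions(self, stationary_net):
        # Transmissions never exceed the number of distinct U-I overlaps,
        # which is itself bounded by the number of contacts in the window.
        ens = run_ensemble(stationary_net, UIUParams(5.0, 0.001), 0.0, 20,
                           3600.0, 9)
        ev = stationary_net.events
        n_window = ((ev["t_start_s"] < 3600.0) & (ev["t_end_s"] > 0)).sum()
        for r in ens.runs:
            assert r.n_transmissions <= n_window


class TestStatisticalInvariants:
    def test_prevalence_monotone_in_beta_and_mu(self, stationary_net):
        # Mean prevalence over a fixed window: non-decreasing in beta at
        # fixed mu, non-increasing in mu at fixed beta.
        times = np.arange(1800.0, 9000.0, 300.0)

        def mean_prev(beta, mu, seed=101):
            ens = run_ensemble(stationary_net, UIUParams(beta, mu), 600.0,
                               500, 9000.0, seed)
            return ens.counts_at(times).mean()

        by_beta = [mean_prev(b, 0.01) for b in (0.05, 0.5, 5.0)]
        assert by_beta == sorted(by_beta)
        by_mu = [mean_prev(1.0, m) for m in (0.002, 0.02, 0.2)]
        assert by_mu == sorted(by_mu, reverse=True)

    def test_mean_field_limit_on_dense_stationary_process(self):
        # Dense aperiodic contact process: steady-state prevalence should
        # match the SIS mean-field fixed point when beta * c >> mu.
        n, rate, dur = 30, 3.0, 4000.0
        colony = ColonyConfig(n_ants=n, duration_s=dur)
        osc = OscillatorConfig(stac_amplitude=0.0, diurnal_day_level=1.0,
                               diurnal_night_level=1.0)
        net = generate_contact_sequence(colony, osc, rate, rng=17,
                                        duration_median_s=0.5,
                                        duration_sigma_ln=0.3)
        beta, mu = 2.0, 0.02
        # Per-ant contact rate c and per-contact success probability from the
        # realised event list (durations are random), then solve the balance
        # equation c*p*rho*(1-rho)*N/(N-1) = mu*rho for rho.
        durs = (net.events["t_end_s"] - net.events["t_start_s"]).to_numpy()
        c = 2 * len(durs) / (n * dur)
        p = float(np.mean(1 - np.exp(-beta * durs)))
        rho_star = 1 - mu * (n - 1) / (c * p * n)
        assert rho_star > 0.5  # parameter choice sanity
        times = np.arange(2000.0, 4000.0, 100.0)
        ens = run_ensemble(net, UIUParams(beta, mu), 0.0, 30, dur, 55)
        counts = ens.counts_at(times)
        extant = counts >= 1
        prev = counts[extant].mean() / n
        assert prev == pytest.approx(rho_star, rel=0.10)
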