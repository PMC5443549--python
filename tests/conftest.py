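"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from cyclenet import (ColonyConfig, OscillatorConfig, TemporalNetwork,
                      generate_contact_sequence)


def toy_network(rows: list[tuple], duration_s: float,
                ants: list[int] | None = None) -> TemporalNetwork:
    """Build a network from (ant_i, ant_j, start, end) tuples."""
    ev = pd.DataFrame(rows, columns=["ant_i", "ant_j", "t_start_s", "t_end_s"])
    return TemporalNetwork.from_events(ev, duration_s=duration_s, ants=ants)


def random_small_network(rng: np.random.Generator, n_ants: int = 10,
                         n_contacts: int = 40,
                         duration_s: float = 1000.0) -> TemporalNetwork:
    starts = rng.uniform(0, duration_s * 0.95, size=n_contacts)
    durs = rng.uniform(1.0, 20.0, size=n_contacts)
    pairs = np.array([rng.choice(n_ants, size=2, replace=False)
                      for _ in range(n_contacts)])
    ev = pd.DataFrame({"ant_i": pairs[:, 0], "ant_j": pairs[:, 1],
                       "t_start_s": starts,
                       "t_end_s": np.minimum(starts + durs, duration_s)})
    return TemporalNetwork.from_events(ev, duration_s=duration_s,
                                       ants=np.arange(n_ants))


def temporal_reachable_set(network: TemporalNetwork, seed_ant: int,
                           t0_s: float, t_end_s: float) -> set[int]:
    """Brute-force time-respecting reachability (instant transmission, no loss).

    Iterates infection times to a fixed point: an ant j becomes reachable at
    time max(contact start, partner's infection time) for any contact whose
    overlap with [t0, t_end) covers that moment.  Independent of the
    event-driven simulator.
    """
    ev = network.events
    inf_time = {int(a): math.inf for a in network.ants}
    inf_time[int(seed_ant)] = t0_s
    changed = True
    while changed:
        changed = False
        for ant_i, ant_j, s, e in ev[["ant_i", "ant_j", "t_start_s",
                                      "t_end_s"]].itertuples(index=False):
            s, e = max(float(s), t0_s), min(float(e), t_end_s)
            if e <= s:
                continue
            for a, b in ((int(ant_i), int(ant_j)), (int(ant_j), int(ant_i))):
                if inf_time[a] < e:
                    t = max(s, inf_time[a])
                    if t < inf_time[b]:
                        inf_time[b] = t
                        changed = True
    return {a for a, t in inf_time.items() if t < math.inf}


@pytest.fixture(scope="session")
def periodic_strong_net() -> TemporalNetwork:
    """A strongly periodic 24-h, 40-ant synthetic recording (shared)."""
    from cyclenet import make_fixture
    net, _ = make_fixture("periodic_strong", rng=2024)
    return net


@pytest.fixture(scope="session")
def stationary_net() -> TemporalNetwork:
    """A flat (aperiodic, no diurnal cycle) 20-ant, 4-h recording."""
    colony = ColonyConfig(n_ants=20, duration_s=4 * 3600.0, rng_seed=7)
    osc = OscillatorConfig(stac_amplitude=0.0, diurnal_day_level=1.0,
                           diurnal_night_level=1.0)
    return generate_contact_sequence(colony, osc, mean_rate_per_s=0.4, rng=7)
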