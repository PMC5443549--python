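"""Event-driven UIU (Uninformed-Informed-Uninformed) transmission simulation.

The UIU model is an SIS-type two-state process relabelled for information:
during physical contact between an informed (I) and an uninformed (U) ant,
the uninformed partner becomes informed according to a Poisson process with
rate beta per second of U-I overlap, with at most one successful transmission
per contact and direction; an informed ant independently reverts to
uninformed at rate mu at any time, in or out of contact.  Simulations run on
the raw time-ordered contact sequence, so transmission can only follow
time-respecting paths.

The implementation is event-driven: contact onsets are consumed in time
order, and candidate transmission times plus information-loss times live in a
priority queue.  Whenever the U-I configuration of an ongoing contact changes
(either participant flips state, e.g. through another contact or a loss),
pending transmission attempts on that contact are invalidated and, if a U-I
configuration holds again, a fresh exponential attempt is drawn — the Poisson
clock restarts.  Simultaneous events resolve deterministically: losses before
transmissions, then by ant identity.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .containers import TemporalNetwork


@dataclass(frozen=True)
class UIUParams:
    """Transmission rate beta and loss rate mu, both per second.

    Per-second units make mu directly comparable with the colony cycle rate
    gamma = 1/lambda.  ``beta = math.inf`` gives deterministic transmission
    at the start of every U-I overlap.
    """

    beta: float
    mu: float
    max_one_per_contact: bool = True  # fixed; the model transmits once per contact

    def __post_init__(self) -> None:
        if self.beta < 0 or self.mu < 0:
            raise ValueError("beta and mu must be nonnegative")
        if not self.max_one_per_contact:
            raise ValueError("the UIU model always caps transmission at once per contact")


def contact_transmission_time(beta: float, overlap_start_s: float,
                              overlap_end_s: float,
                              rng: np.random.Generator) -> float | None:
    """Time of the (at most one) transmission during a U-I overlap, or None.

    Draws an exponential(beta) waiting time from the start of the overlap;
    the transmission happens only if the wait ends before the overlap does.
    """
    if overlap_end_s <= overlap_start_s:
        return None
    if beta == 0:
        return None
    if math.isinf(beta):
        return overlap_start_s
    wait = rng.exponential(1.0 / beta)
    t = overlap_start_s + wait
    return t if t < overlap_end_s else None


@dataclass
class RunResult:
    """Event log of one UIU run.

    ``times``/``ants``/``deltas`` log every state transition in order; the
    first entry is the seeding (+1 for ``seed_ant`` at ``t0_s``).  The
    informed count is the running sum of ``deltas``.  ``extinct_at_s`` is the
    time the count first reached zero, or None if the run was still extant at
    ``t_end_s`` (censored).
    """

    seed_ant: int
    t0_s: float
    t_end_s: float
    times: np.ndarray
    ants: np.ndarray
    deltas: np.ndarray
    extinct_at_s: float | None

    @property
    def counts(self) -> np.ndarray:
        return np.cumsum(self.deltas)

    @property
    def n_transmissions(self) -> int:
        """U->I transitions beyond the initial seeding."""
        return int((self.deltas > 0).sum()) - 1

    @property
    def broke_out(self) -> bool:
        return self.n_transmissions >= 1

    def informed_count_at(self, query_times) -> np.ndarray:
        """Informed count at each query time (0 before t0, last value after)."""
        q = np.atleast_1d(np.asarray(query_times, dtype=float))
        idx = np.searchsorted(self.times, q, side="right")
        counts = np.concatenate(([0], self.counts))
        return counts[idx]

    def extant_at(self, t: float) -> bool:
        return bool(self.informed_count_at([t])[0] >= 1)


def simulate_run(network: TemporalNetwork, params: UIUParams, seed_ant: int,
                 t0_s: float, t_end_s: float,
                 rng: np.random.Generator) -> RunResult:
    """Run one UIU realisation on the contact sequence from t0 to t_end.

    Contacts already in progress at t0 participate with their remaining
    overlap only.  The run ends at extinction (no informed ants) or at
    ``t_end_s``, whichever comes first.
    """
    comp = network.compiled()
    if int(seed_ant) not in comp.index_of:
        raise KeyError(f"seed ant {seed_ant} not in the network roster")
    if not t0_s < t_end_s:
        raise ValueError("t0_s must precede t_end_s")
    # Plain lists in the inner loop: ndarray scalar indexing is several
    # times slower per access and dominates at realistic contact counts.
    starts, ends, ai, aj = comp.starts_l, comp.ends_l, comp.ai_l, comp.aj_l
    beta, mu = params.beta, params.mu

    n = comp.n_ants
    informed = [False] * n
    active: list[list[int]] = [[] for _ in range(n)]
    token: dict[int, int] = {}
    succeeded: set[tuple[int, int]] = set()
    heap: list[tuple] = []   # (time, prio, ant, counter, payload...)
    counter = 0

    log_t: list[float] = []
    log_a: list[int] = []
    log_d: list[int] = []

    def schedule(ci: int, src: int, dst: int, from_time: float) -> None:
        nonlocal counter
        if (ci, src) in succeeded:
            return
        tt = contact_transmission_time(beta, from_time,
                                       min(ends[ci], t_end_s), rng)
        if tt is not None:
            counter += 1
            heapq.heappush(heap, (tt, 1, dst, counter, ci, src,
                                  token.get(ci, 0)))

    count = 0

    def on_state_change(ant: int, t: float) -> None:
        lst = active[ant]
        keep = []
        for ci in lst:
            if ends[ci] <= t:
                continue
            keep.append(ci)
            token[ci] = token.get(ci, 0) + 1
            other = aj[ci] if ai[ci] == ant else ai[ci]
            if informed[ant] != informed[other]:
                src, dst = (ant, other) if informed[ant] else (other, ant)
                schedule(ci, src, dst, t)
        active[ant] = keep

    def infect(ant: int, t: float) -> None:
        nonlocal count, counter
        informed[ant] = True
        count += 1
        log_t.append(t)
        log_a.append(ant)
        log_d.append(1)
        if mu > 0:
            counter += 1
            heapq.heappush(heap, (t + rng.exponential(1.0 / mu), 0, ant,
                                  counter, -1, -1, -1))
        on_state_change(ant, t)

    # Contacts already in progress at t0 join with their remaining overlap.
    initially_active = np.flatnonzero((comp.starts <= t0_s) & (comp.ends > t0_s)
                                      & (comp.starts < t_end_s))
    for ci in initially_active:
        ci = int(ci)
        active[ai[ci]].append(ci)
        active[aj[ci]].append(ci)
    # Clamp attempt origins of initial contacts to t0 via the seeding call.
    infect(comp.index_of[int(seed_ant)], t0_s)

    k = int(np.searchsorted(comp.starts, t0_s, side="right"))
    n_contacts = len(starts)
    extinct_at: float | None = None

    while count > 0:
        t_contact = starts[k] if k < n_contacts else math.inf
        t_event = heap[0][0] if heap else math.inf
        if t_event <= t_contact:
            if t_event >= t_end_s:
                break
            t, prio, ant, _, ci, src, tok = heapq.heappop(heap)
            if prio == 0:                      # information loss
                informed[ant] = False
                count -= 1
                log_t.append(t)
                log_a.append(ant)
                log_d.append(-1)
                if count == 0:
                    extinct_at = t
                    break
                on_state_change(ant, t)
            else:                               # transmission attempt
                if tok != token.get(ci, 0):
                    continue                    # configuration changed; stale
                succeeded.add((ci, src))
                infect(ant, t)
        else:
            if t_contact >= t_end_s:
                break
            ci = k
            k += 1
            if ends[ci] <= t0_s:
                continue
            a = ai[ci]
            b = aj[ci]
            active[a].append(ci)
            active[b].append(ci)
            if informed[a] != informed[b]:
                if informed[a]:
                    schedule(ci, a, b, t_contact)
                else:
                    schedule(ci, b, a, t_contact)

    return RunResult(seed_ant=int(seed_ant), t0_s=t0_s, t_end_s=t_end_s,
                     times=np.asarray(log_t),
                     ants=comp.ants[np.asarray(log_a, dtype=int)],
                     deltas=np.asarray(log_d, dtype=int),
                     extinct_at_s=extinct_at)


@dataclass
class EnsembleResult:
    """Independent UIU runs sharing one start time, with per-run RNG streams."""

    runs: list[RunResult]
    t0_s: float
    t_end_s: float
    params: UIUParams

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def counts_at(self, query_times) -> np.ndarray:
        """(n_runs, n_times) informed counts."""
        return np.stack([r.informed_count_at(query_times) for r in self.runs])

    def mean_informed(self, query_times, extant_only: bool = False) -> np.ndarray:
        """Mean informed count over runs; optionally over extant runs only.

        With ``extant_only`` the mean is taken across runs whose count is at
        least 1 at each time, NaN where no run is extant.
        """
        counts = self.counts_at(query_times)
        if not extant_only:
            return counts.mean(axis=0)
        extant = counts >= 1
        n_ext = extant.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(n_ext > 0,
                            (counts * extant).sum(axis=0) / np.maximum(n_ext, 1),
                            np.nan)
        return mean


def run_ensemble(network: TemporalNetwork, params: UIUParams, t0_s: float,
                 n_runs: int, t_end_s: float,
                 rng: np.random.Generator | np.random.SeedSequence | int
                 ) -> EnsembleResult:
    """Run ``n_runs`` independent UIU realisations from one start time.

    Each run draws its own uniformly random seed ant and uses an independent
    RNG stream split from the master seed (``SeedSequence`` spawning), so run
    k is reproducible in isolation and the whole ensemble is reproducible
    from the master seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if isinstance(rng, np.random.SeedSequence):
        ss = rng
    elif isinstance(rng, np.random.Generator):
        ss = np.random.SeedSequence(int(rng.integers(2 ** 31)))
    else:
        ss = np.random.SeedSequence(int(rng))
    ants = network.compiled().ants
    runs = []
    for child in ss.spawn(n_runs):
        run_rng = np.random.default_rng(child)
        seed_ant = int(ants[run_rng.integers(len(ants))])
        runs.append(simulate_run(network, params, seed_ant, t0_s, t_end_s,
                                 run_rng))
    return EnsembleResult(runs=runs, t0_s=t0_s, t_end_s=t_end_s, params=params)
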