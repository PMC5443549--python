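"""Aperiodic null networks and observed-vs-expected transmission comparison.

The null model destroys short-term periodicity while conserving everything
else: for each edge (a unique ant pair that interacted at least once) the
whole contact timeline is displaced by a single uniform shift drawn from
[-max_shift, +max_shift], with max_shift = lambda/2 by default.  Because the
shifts are independent across edges, the colony-wide oscillation is smeared
out; because they are bounded by half a cycle period (minutes, not hours),
long-term structure such as the diurnal cycle is preserved.  Per-edge contact
counts and the duration of every contact are conserved exactly; shifts wrap
circularly around the recording window.

Transmission over observed and null networks is compared over a {beta, mu}
grid: the signed difference observed - expected (expected = mean over null
replicates) is negative wherever periodicity impedes transmission, and the
loss rate at which the reduction is greatest can be compared with the
colony's cycle rate gamma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TemporalNetwork
from .metrics import MetricsConfig, aggregate_metrics, evaluate_network
from .uiu import UIUParams

METRIC_NAMES = ("p_breakout", "p_sustain", "p_informed", "p_lost")


@dataclass(frozen=True)
class NullSpec:
    """Null-ensemble parameters: shift half-window and replicate count."""

    max_shift_s: float
    n_replicates: int = 20
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_shift_s <= 0:
            raise ValueError("max_shift_s must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def time_shift_null(network: TemporalNetwork, max_shift_s: float,
                    rng: np.random.Generator | int | None = None
                    ) -> TemporalNetwork:
    """One synthetic aperiodic replicate by per-edge time shifting.

    Every contact of an edge receives that edge's single uniform shift; start
    times wrap modulo the recording length (a wrapped contact keeps its full
    duration, so its end may overhang the nominal recording end by less than
    one contact duration).  Counts and durations are conserved exactly.
    """
    if max_shift_s <= 0:
        raise ValueError("max_shift_s must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    ev = network.events
    if len(ev) == 0:
        return TemporalNetwork.from_events(ev.copy(), network.duration_s,
                                           ants=network.ants)
    pair_codes = ev.groupby(["ant_i", "ant_j"], sort=True).ngroup().to_numpy()
    n_edges = int(pair_codes.max()) + 1
    shifts = rng.uniform(-max_shift_s, max_shift_s, size=n_edges)
    starts = ev["t_start_s"].to_numpy()
    durations = ev["t_end_s"].to_numpy() - starts
    new_starts = np.mod(starts + shifts[pair_codes], network.duration_s)
    out = pd.DataFrame({"ant_i": ev["ant_i"].to_numpy(),
                        "ant_j": ev["ant_j"].to_numpy(),
                        "t_start_s": new_starts,
                        "t_end_s": new_starts + durations})
    return TemporalNetwork.from_events(out, network.duration_s,
                                       ants=network.ants)


def null_ensemble(network: TemporalNetwork, spec: NullSpec) -> list[TemporalNetwork]:
    """Seeded, reproducible list of null replicates."""
    rng = np.random.default_rng(spec.rng_seed)
    return [time_shift_null(network, spec.max_shift_s, rng)
            for _ in range(spec.n_replicates)]


@dataclass
class DifferenceSurface:
    """Observed vs expected values of one metric over a {beta, mu} grid."""

    metric: str
    beta_grid: np.ndarray
    mu_grid: np.ndarray
    observed: np.ndarray     # shape (n_beta, n_mu)
    expected: np.ndarray
    p_empirical: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.observed - self.expected

    def to_long(self) -> pd.DataFrame:
        b, m = np.meshgrid(self.beta_grid, self.mu_grid, indexing="ij")
        return pd.DataFrame({
            "metric": self.metric,
            "beta": b.ravel(), "mu": m.ravel(),
            "observed": self.observed.ravel(),
            "expected": self.expected.ravel(),
            "difference": self.difference.ravel(),
            "p_empirical": self.p_empirical.ravel(),
        })


def default_beta_grid(n: int = 8) -> np.ndarray:
    return np.geomspace(0.01, 10.0, n)


def default_mu_grid(n: int = 8) -> np.ndarray:
    return np.geomspace(1e-4, 1e-1, n)


def _empirical_p(observed: float, null_values: np.ndarray) -> float:
    """Two-sided empirical rank p-value of the observed value among nulls."""
    null_values = null_values[np.isfinite(null_values)]
    if len(null_values) == 0 or not np.isfinite(observed):
        return float("nan")
    centre = null_values.mean()
    extreme = np.abs(null_values - centre) >= abs(observed - centre) - 1e-12
    return float((1 + extreme.sum()) / (len(null_values) + 1))


def sweep_surfaces(network: TemporalNetwork, nulls: list[TemporalNetwork],
                   beta_grid: np.ndarray, mu_grid: np.ndarray,
                   metrics_config: MetricsConfig,
                   rng: np.random.Generator | int
                   ) -> dict[str, DifferenceSurface]:
    """Observed/expected surfaces for all four metrics over a rate grid.

    Per cell, metrics are averaged over all sampled start times of each
    network; the expected value is the mean over null replicates and the
    empirical significance is a two-sided rank test of the observed value
    against the null distribution.  Degenerate start times propagate as
    missing values, never as zeros.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    mu_grid = np.asarray(mu_grid, dtype=float)
    if len(beta_grid) == 0 or len(mu_grid) == 0:
        raise ValueError("rate grids must be nonempty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nb, nm = len(beta_grid), len(mu_grid)
    obs = {m: np.full((nb, nm), np.nan) for m in METRIC_NAMES}
    exp_ = {m: np.full((nb, nm), np.nan) for m in METRIC_NAMES}
    pemp = {m: np.full((nb, nm), np.nan) for m in METRIC_NAMES}
    for ib, beta in enumerate(beta_grid):
        for im, mu in enumerate(mu_grid):
            params = UIUParams(beta=float(beta), mu=float(mu))
            obs_agg = aggregate_metrics(
                evaluate_network(network, params, metrics_config, rng))
            null_aggs = [aggregate_metrics(
                evaluate_network(nn, params, metrics_config, rng))
                for nn in nulls]
            for m in METRIC_NAMES:
                obs[m][ib, im] = obs_agg[m]
                null_vals = np.array([na[m] for na in null_aggs], dtype=float)
                exp_[m][ib, im] = (float(np.nanmean(null_vals))
                                   if np.isfinite(null_vals).any() else np.nan)
                pemp[m][ib, im] = _empirical_p(obs_agg[m], null_vals)
    return {m: DifferenceSurface(metric=m, beta_grid=beta_grid,
                                 mu_grid=mu_grid, observed=obs[m],
                                 expected=exp_[m], p_empirical=pemp[m])
            for m in METRIC_NAMES}


def surfaces_to_long(surfaces: dict[str, DifferenceSurface]) -> pd.DataFrame:
    return pd.concat([s.to_long() for s in surfaces.values()],
                     ignore_index=True)


def max_inhibition_loss_rate(mu_grid: np.ndarray,
                             difference_curve: np.ndarray) -> float | None:
    """Loss rate mu* at which the transmission reduction is greatest.

    Takes the mu grid and the observed - expected difference along it (beta
    held fixed) and returns the mu of the most negative difference, breaking
    ties toward the smallest mu.  Returns None when the curve is entirely
    missing.
    """
    mu_grid = np.asarray(mu_grid, dtype=float)
    diff = np.asarray(difference_curve, dtype=float)
    if len(mu_grid) < 3 or len(diff) != len(mu_grid):
        raise ValueError("need at least 3 mu points and matching curve length")
    if not np.isfinite(diff).any():
        return None
    return float(mu_grid[int(np.nanargmin(diff))])
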