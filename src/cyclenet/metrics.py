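"""Time-explicit steady state and the four transmission metrics.

On a non-stationary temporal network the SIS steady state is itself
time-dependent, so transmission is quantified against a *time-explicit*
steady state: a 'reference' ensemble launched tau seconds before the focal
start time t0, whose extant-mean informed count has converged by t0 and
traces the steady-state level thereafter.  A focal run 'reaches the steady
state' when its informed count first touches that reference curve (its
hitting time).  Four metrics summarise an ensemble of focal runs:

- P_breakout: proportion of runs that spread beyond the initial seed ant.
- P_sustain: proportion of runs with a hitting time (they reach the steady
  state, whether or not they later decline).
- P_informed: prevalence — the grand mean informed count over a persistence
  window after hitting, among runs extant throughout that window,
  normalised by colony size.
- P_lost: among runs still extant at the mean hitting time T-bar, the
  proportion that later decline to zero before the observation end
  (runs still extant at the end are censored, never counted as lost).

Metrics are sampled at a sequence of regularly spaced start times t0 across
the recording, because on a non-stationary network any single start time is
unrepresentative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import TemporalNetwork
from .uiu import EnsembleResult, RunResult, UIUParams, run_ensemble

logger = logging.getLogger(__name__)


@dataclass
class ReferenceCurve:
    """Extant-mean informed count of a reference ensemble, from t0 onwards.

    ``mean_informed`` is NaN wherever no reference run is extant; where
    defined it is at least 1 by construction (extant runs have >= 1
    informed ant).
    """

    t0_s: float
    tau_s: float
    times: np.ndarray
    mean_informed: np.ndarray

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")

    @property
    def defined_at_t0(self) -> bool:
        return bool(np.isfinite(self.mean_informed[0]))


@dataclass
class MetricsResult:
    """The four transmission metrics for one start time.

    NaN marks an undefined metric (e.g. the prevalence when no focal run
    reached the steady state); ``degenerate`` flags a t0 whose reference
    ensemble went extinct before t0, leaving the steady state undefined.
    """

    t0_s: float
    p_breakout: float
    p_sustain: float
    p_informed: float
    p_lost: float
    mean_hitting_time_s: float
    tau_s: float
    n_runs: int
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "t0_s": self.t0_s, "p_breakout": self.p_breakout,
            "p_sustain": self.p_sustain, "p_informed": self.p_informed,
            "p_lost": self.p_lost,
            "mean_hitting_time_s": self.mean_hitting_time_s,
            "tau_s": self.tau_s, "n_runs": self.n_runs,
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class MetricsConfig:
    """Defaults for the steady-state machinery.

    ``window_s`` is the per-t0 observation window (clipped to the time
    remaining in the recording); ``tau_candidates`` defaults to
    {2, 4, 8, 16} x lambda so the reference lead is commensurate with the
    colony's cycle period.
    """

    n_runs: int = 100
    n_reference_runs: int | None = None    # defaults to n_runs
    spacing_s: float = 3600.0
    margin_s: float = 4 * 3600.0
    window_s: float = 86400.0
    persist_window_s: float = 3600.0
    grid_s: float = 60.0
    lambda_s: float = 960.0
    tau_candidates: tuple[float, ...] | None = None
    tau_rel_tol: float = 0.05

    def candidates(self) -> tuple[float, ...]:
        if self.tau_candidates is not None:
            return tuple(self.tau_candidates)
        return tuple(m * self.lambda_s for m in (2, 4, 8, 16))

    @property
    def ref_runs(self) -> int:
        return self.n_reference_runs or self.n_runs


def sample_start_times(network: TemporalNetwork, spacing_s: float,
                       margin_s: float) -> np.ndarray:
    """Regularly spaced start times within the recording, respecting margins."""
    if spacing_s <= 0:
        raise ValueError("spacing_s must be positive")
    lo, hi = margin_s, network.duration_s - margin_s
    if hi < lo:
        raise ValueError("margins leave no room for any start time")
    t0 = np.arange(lo, hi + 1e-9, spacing_s)
    if len(t0) == 0:
        raise ValueError("margins leave no room for any start time")
    return t0


def build_reference(network: TemporalNetwork, params: UIUParams, t0_s: float,
                    tau_s: float, window_s: float, n_runs: int,
                    seed: int | np.random.SeedSequence,
                    grid_s: float = 60.0) -> ReferenceCurve:
    """Launch a reference ensemble at t0 - tau and record its extant mean."""
    ens = run_ensemble(network, params, t0_s - tau_s, n_runs,
                       t0_s + window_s, seed)
    times = t0_s + np.arange(0.0, window_s + grid_s / 2, grid_s)
    mean = ens.mean_informed(times, extant_only=True)
    return ReferenceCurve(t0_s=t0_s, tau_s=tau_s, times=times,
                          mean_informed=mean)


@dataclass
class TauResult:
    tau_s: float | None
    reference: ReferenceCurve | None
    fallback: bool = False
    degenerate: bool = False


def determine_tau(network: TemporalNetwork, params: UIUParams, t0_s: float,
                  candidates: tuple[float, ...],
                  rng: np.random.Generator,
                  *, window_s: float, n_runs: int = 100, grid_s: float = 60.0,
                  rel_tol: float = 0.05) -> TauResult:
    """Choose the reference lead tau for one start time.

    Accepts the smallest candidate tau for which reference ensembles
    launched at t0 - tau and t0 - 2*tau produce extant-mean curves that
    differ by less than ``rel_tol`` (relative) over the observation window —
    i.e. the reference has stopped depending on its own launch time, so it
    has converged to the steady state.  If no candidate converges, the
    largest is used with a logged warning.  If no reference run survives to
    t0 for any candidate, the start time is degenerate: the steady state is
    undefined there.
    """
    if list(candidates) != sorted(candidates):
        raise ValueError("tau candidates must be ascending")
    curves: dict[float, ReferenceCurve] = {}

    def curve_for(tau: float) -> ReferenceCurve:
        key = round(tau, 6)
        if key not in curves:
            seed = int(rng.integers(2 ** 31))
            curves[key] = build_reference(network, params, t0_s, tau,
                                          window_s, n_runs, seed, grid_s)
        return curves[key]

    any_extant = False
    for tau in candidates:
        ref = curve_for(tau)
        ref2 = curve_for(2 * tau)
        a, b = ref.mean_informed, ref2.mean_informed
        both = np.isfinite(a) & np.isfinite(b)
        if not ref.defined_at_t0 or not both.any():
            continue
        any_extant = True
        denom = max(float(np.nanmean(b[both])), 1e-12)
        rel = float(np.mean(np.abs(a[both] - b[both]))) / denom
        if rel < rel_tol:
            return TauResult(tau_s=tau, reference=ref)
    if not any_extant:
        return TauResult(tau_s=None, reference=None, degenerate=True)
    tau = candidates[-1]
    logger.warning("no tau candidate converged at t0=%.0f; using largest (%.0f s)",
                   t0_s, tau)
    return TauResult(tau_s=tau, reference=curve_for(tau), fallback=True)


def hitting_time(run: RunResult, ref: ReferenceCurve) -> float | None:
    """First time the run's informed count reaches the reference mean."""
    counts = run.informed_count_at(ref.times)
    ok = np.isfinite(ref.mean_informed) & (counts >= ref.mean_informed)
    idx = np.flatnonzero(ok)
    return float(ref.times[idx[0]]) if len(idx) else None


def transmission_metrics(ensemble: EnsembleResult, ref: ReferenceCurve,
                         persist_window_s: float, colony_size: int,
                         grid_s: float = 60.0) -> MetricsResult:
    """Compute the four transmission metrics for one focal ensemble."""
    if ensemble.n_runs == 0:
        raise ValueError("ensemble must contain at least one run")
    if colony_size < 1:
        raise ValueError("colony_size must be >= 1")
    runs = ensemble.runs
    n = len(runs)
    p_breakout = sum(r.broke_out for r in runs) / n

    hits = [hitting_time(r, ref) for r in runs]
    hit_vals = [h for h in hits if h is not None]
    p_sustain = len(hit_vals) / n
    t_bar = float(np.mean(hit_vals)) if hit_vals else float("nan")

    # Prevalence among runs that reach the steady state and stay extant for
    # the whole persistence window (window must fit inside the observation).
    per_run_means = []
    for r, h in zip(runs, hits):
        if h is None or h + persist_window_s > r.t_end_s + 1e-9:
            continue
        w_times = h + np.arange(0.0, persist_window_s + grid_s / 2, grid_s)
        counts = r.informed_count_at(w_times)
        if (counts >= 1).all():
            per_run_means.append(counts.mean())
    p_informed = (float(np.mean(per_run_means)) / colony_size
                  if per_run_means else float("nan"))

    if math.isnan(t_bar):
        p_lost = float("nan")
    else:
        extant_at_tbar = [r for r in runs if r.extant_at(t_bar)]
        if extant_at_tbar:
            lost = sum(1 for r in extant_at_tbar
                       if r.extinct_at_s is not None and r.extinct_at_s >= t_bar)
            p_lost = lost / len(extant_at_tbar)
        else:
            p_lost = float("nan")

    return MetricsResult(t0_s=ensemble.t0_s, p_breakout=p_breakout,
                         p_sustain=p_sustain, p_informed=p_informed,
                         p_lost=p_lost, mean_hitting_time_s=t_bar,
                         tau_s=ref.tau_s, n_runs=n)


def evaluate_start_time(network: TemporalNetwork, params: UIUParams,
                        t0_s: float, cfg: MetricsConfig,
                        rng: np.random.Generator,
                        tau_s: float | None = None) -> MetricsResult:
    """Full per-t0 evaluation: tau, reference curve, focal ensemble, metrics.

    When the reference ensemble goes wholly extinct (degenerate steady
    state), the reference-relative metrics are NaN — but P_breakout is still
    computed from the focal ensemble, because spreading beyond the seed is
    defined without reference to the steady state.  Dropping it too would
    bias any comparison across networks toward their favourable start times.
    """
    window = min(cfg.window_s, network.duration_s - t0_s)
    if window <= 0:
        raise ValueError("t0 leaves no observation window")
    ref: ReferenceCurve | None
    if tau_s is None:
        tau_res = determine_tau(network, params, t0_s, cfg.candidates(), rng,
                                window_s=window, n_runs=cfg.ref_runs,
                                grid_s=cfg.grid_s, rel_tol=cfg.tau_rel_tol)
        tau_s, ref = tau_res.tau_s, tau_res.reference
        degenerate = tau_res.degenerate
    else:
        ref = build_reference(network, params, t0_s, tau_s, window,
                              cfg.ref_runs, int(rng.integers(2 ** 31)),
                              cfg.grid_s)
        degenerate = not np.isfinite(ref.mean_informed).any()
    ensemble = run_ensemble(network, params, t0_s, cfg.n_runs, t0_s + window,
                            int(rng.integers(2 ** 31)))
    if degenerate:
        p_breakout = sum(r.broke_out for r in ensemble.runs) / ensemble.n_runs
        return MetricsResult(t0_s=t0_s, p_breakout=p_breakout,
                             p_sustain=float("nan"), p_informed=float("nan"),
                             p_lost=float("nan"),
                             mean_hitting_time_s=float("nan"),
                             tau_s=tau_s if tau_s is not None else float("nan"),
                             n_runs=ensemble.n_runs, degenerate=True)
    return transmission_metrics(ensemble, ref, cfg.persist_window_s,
                                network.n_ants, cfg.grid_s)


def evaluate_network(network: TemporalNetwork, params: UIUParams,
                     cfg: MetricsConfig, rng: np.random.Generator | int,
                     t0_list: np.ndarray | None = None) -> pd.DataFrame:
    """Metrics at every sampled start time of one network.

    The reference lead tau is determined once per (network, parameters) at
    the median start time and reused across the others, since tau reflects
    the relaxation time of the dynamics rather than the particular t0.
    Returns a DataFrame with one row per t0 (degenerate t0s carry NaNs).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if t0_list is None:
        t0_list = sample_start_times(network, cfg.spacing_s, cfg.margin_s)
    mid_t0 = float(t0_list[len(t0_list) // 2])
    window_mid = min(cfg.window_s, network.duration_s - mid_t0)
    tau_res = determine_tau(network, params, mid_t0, cfg.candidates(), rng,
                            window_s=window_mid, n_runs=cfg.ref_runs,
                            grid_s=cfg.grid_s, rel_tol=cfg.tau_rel_tol)
    shared_tau = tau_res.tau_s  # None => degenerate everywhere it stays so
    rows = []
    for t0 in t0_list:
        res = evaluate_start_time(network, params, float(t0), cfg, rng,
                                  tau_s=shared_tau)
        rows.append(res.as_dict())
    return pd.DataFrame(rows)


def aggregate_metrics(per_t0: pd.DataFrame) -> dict:
    """Recording-level means over start times.

    P_breakout averages over every t0 (it is reference-free).  A degenerate
    t0 — the reference ensemble wholly extinct, so no steady state exists
    there — contributes P_sustain = 0: information demonstrably cannot
    become self-sustaining at that start time, and dropping such t0s would
    bias comparisons toward each network's favourable start times.  The
    conditional quantities P_informed (prevalence given sustained) and
    P_lost (loss given extant at T-bar) are averaged only where defined.
    """
    out = {}
    deg = per_t0["degenerate"].to_numpy(dtype=bool)
    for key in ("p_breakout", "p_sustain", "p_informed", "p_lost"):
        vals = per_t0[key].to_numpy(dtype=float)
        if key == "p_sustain":
            vals = np.where(deg, 0.0, vals)
        out[key] = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return out
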