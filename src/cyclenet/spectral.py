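"""Colony-level activity series and their wavelet power spectra.

Two colony activity measures are supported: the 'movement activity' (mean of
the instantaneous speeds of all ants detected in a frame) and the 'contact
rate' (number of contacts starting or stopping in a frame).  Both are binned
(1-minute bins by default) and analysed with a continuous Morlet wavelet
transform, a time-frequency decomposition suited to non-stationary,
quasi-periodic series.  The global (time-averaged) wavelet spectrum gives a
periodogram over a logarithmic grid of periods; its argmax defines the
dominant cycle period lambda, the cycle rate is gamma = 1/lambda, and the
power at lambda measures the cycle amplitude.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pywt

from .containers import TemporalNetwork, TrajectoryTable
from .synth import DAY_S, _day_mask

logger = logging.getLogger(__name__)

# Morlet with nondimensional centre frequency omega0 = 6: the standard choice
# for quasi-periodic ecological series.  In PyWavelets' 'cmorB-C'
# parametrisation this is bandwidth B = 2 (Gaussian envelope exp(-t^2/2)) and
# centre frequency C = 6 / (2 pi).
_MORLET_W0 = 6.0
_MORLET_FC = _MORLET_W0 / (2.0 * math.pi)
_MORLET_NAME = f"cmor2.0-{_MORLET_FC:.10f}"
# Fourier period of the omega0=6 Morlet at unit scale, and its cone-of-
# influence e-folding time in units of the Fourier period.
_FOURIER_FACTOR = 4.0 * math.pi / (_MORLET_W0 + math.sqrt(2.0 + _MORLET_W0 ** 2))
_COI_FACTOR = math.sqrt(2.0) / _FOURIER_FACTOR


@dataclass
class ActivitySeries:
    """A binned, nonnegative colony-level activity time series."""

    bin_s: float
    t0_s: float
    values: np.ndarray
    kind: str = "contact_rate"        # or "movement"
    missing: np.ndarray | None = None  # bins with no detected ants (carried as 0)
    start_clock_s: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if (self.values < 0).any():
            raise ValueError("activity values must be nonnegative")
        if self.missing is not None:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != self.values.shape:
                raise ValueError("missing mask must match values")

    @property
    def duration_s(self) -> float:
        return len(self.values) * self.bin_s

    @property
    def times(self) -> np.ndarray:
        """Bin-centre times."""
        return self.t0_s + (np.arange(len(self.values)) + 0.5) * self.bin_s


@dataclass
class Periodogram:
    """Global wavelet spectrum on an ascending period grid.

    ``power`` is normalised to a proportion-of-variance interpretation (it
    sums to 1 over the analysed band); ``power_raw`` is the unnormalised
    time-averaged squared transform magnitude, which scales with the square
    of the oscillation amplitude.
    """

    periods_s: np.ndarray
    power: np.ndarray
    power_raw: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.periods_s = np.asarray(self.periods_s, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if (np.diff(self.periods_s) <= 0).any():
            raise ValueError("periods_s must be strictly ascending")
        if (self.power < 0).any():
            raise ValueError("power must be nonnegative")

    @property
    def lambda_s(self) -> float:
        """Dominant period (argmax of power; ties break to the shortest)."""
        return float(self.periods_s[int(np.argmax(self.power))])

    @property
    def lambda_power(self) -> float:
        return float(np.max(self.power))

    def power_at(self, period_s: float) -> float:
        """Power at the grid period nearest to ``period_s``."""
        k = int(np.argmin(np.abs(self.periods_s - period_s)))
        return float(self.power[k])


def movement_activity(trajs: TrajectoryTable, bin_s: float = 60.0) -> ActivitySeries:
    """Mean instantaneous speed of detected ants, binned.

    The instantaneous speed of an ant at a frame is the distance travelled
    since the previous frame times the frame rate (mm/s); an ant missing from
    either frame contributes nothing.  Frames with no measurable ants are
    carried as 0 and flagged in the ``missing`` mask.
    """
    fr = trajs.frames.sort_values(["ant_id", "time_s"], kind="stable")
    t = fr["time_s"].to_numpy()
    if len(np.unique(t)) < 2:
        raise ValueError("movement activity needs at least two frames")
    dt = 1.0 / trajs.frame_rate_hz
    same_ant = fr["ant_id"].to_numpy()[1:] == fr["ant_id"].to_numpy()[:-1]
    consecutive = np.abs(np.diff(t) - dt) < dt * 1e-6
    ok = same_ant & consecutive
    dx = np.diff(fr["x_mm"].to_numpy())[ok]
    dy = np.diff(fr["y_mm"].to_numpy())[ok]
    speed = np.hypot(dx, dy) * trajs.frame_rate_hz
    t_speed = t[1:][ok]

    times = trajs.times
    duration = trajs.duration_s
    n_bins = int(math.ceil(duration / bin_s - 1e-9))
    # Mean speed per frame, then average frames into bins.
    frame_idx = np.searchsorted(times, t_speed)
    frame_sum = np.bincount(frame_idx, weights=speed, minlength=len(times))
    frame_n = np.bincount(frame_idx, minlength=len(times))
    bin_of_frame = np.minimum((times / bin_s).astype(int), n_bins - 1)
    values = np.zeros(n_bins)
    missing = np.ones(n_bins, dtype=bool)
    with np.errstate(invalid="ignore"):
        frame_mean = np.where(frame_n > 0, frame_sum / np.maximum(frame_n, 1), np.nan)
    for b in range(n_bins):
        sel = frame_mean[bin_of_frame == b]
        sel = sel[~np.isnan(sel)]
        if len(sel):
            values[b] = sel.mean()
            missing[b] = False
    return ActivitySeries(bin_s=bin_s, t0_s=0.0, values=values, kind="movement",
                          missing=missing)


def contact_rate(network: TemporalNetwork, bin_s: float = 60.0) -> ActivitySeries:
    """Contact-rate series: each contact counts twice, at its start and stop."""
    n_bins = int(math.ceil(network.duration_s / bin_s - 1e-9))
    n_bins = max(n_bins, 1)
    values = np.zeros(n_bins)
    if network.n_events:
        stamps = np.concatenate([network.events["t_start_s"].to_numpy(),
                                 network.events["t_end_s"].to_numpy()])
        idx = np.clip((stamps / bin_s).astype(int), 0, n_bins - 1)
        values = np.bincount(idx, minlength=n_bins).astype(float)
    return ActivitySeries(bin_s=bin_s, t0_s=0.0, values=values, kind="contact_rate")


def _fill_missing(values: np.ndarray, missing: np.ndarray | None,
                  max_gap: int = 5) -> np.ndarray:
    """Linearly interpolate short missing runs; long gaps fall back to the mean."""
    if missing is None or not missing.any():
        return values
    x = values.astype(float).copy()
    idx = np.arange(len(x))
    good = ~missing
    if good.sum() < 2:
        return x
    x[missing] = np.interp(idx[missing], idx[good], x[good])
    # Identify runs longer than max_gap and replace them with the series mean.
    padded = np.concatenate(([False], missing, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s > max_gap:
            x[s:e] = values[good].mean()
            logger.warning("gap of %d bins at bin %d exceeds interpolation limit",
                           e - s, s)
    return x


def wavelet_periodogram(series: ActivitySeries,
                        period_range_s: tuple[float, float] = (240.0, 7200.0),
                        n_periods: int = 64) -> Periodogram:
    """Global Morlet wavelet spectrum of an activity series.

    The series is mean-subtracted and transformed over ``n_periods``
    log-spaced periods spanning ``period_range_s``; the raw power at each
    period is the time-averaged squared transform magnitude with bins inside
    the cone of influence excluded.  The normalised power sums to 1 over the
    analysed band, giving the proportion of in-band variance attributable to
    each period (flat in expectation for white noise, so peaks are
    interpretable against a level background).
    """
    p_min, p_max = period_range_s
    n = len(series.values)
    dt = series.bin_s
    if p_min < 2 * dt or p_max > n * dt / 2:
        raise ValueError("period range outside the resolvable band "
                         f"[{2 * dt}, {n * dt / 2}] s")
    if p_min >= p_max:
        raise ValueError("period range must be increasing")
    if n < 4 * p_max / dt:
        raise ValueError("series too short for the requested maximum period")

    x = _fill_missing(series.values, series.missing)
    x = x - x.mean()
    if x.std() == 0:
        raise ValueError("constant series has no cycles to analyse")

    periods = np.geomspace(p_min, p_max, n_periods)
    scales = _MORLET_FC * periods / dt
    coefs, _ = pywt.cwt(x, scales, _MORLET_NAME, sampling_period=dt,
                        method="fft")
    sq = np.abs(coefs) ** 2

    t = np.arange(n) * dt
    power_raw = np.empty(n_periods)
    for k, p in enumerate(periods):
        coi = _COI_FACTOR * p
        valid = (t >= coi) & (t <= (n - 1) * dt - coi)
        power_raw[k] = sq[k, valid].mean() if valid.any() else 0.0
    total = power_raw.sum()
    power = power_raw / total if total > 0 else power_raw
    return Periodogram(periods_s=periods, power=power, power_raw=power_raw)


def cycle_rate(lambda_s: float) -> float:
    """Cycle rate gamma = 1/lambda, in cycles per second."""
    if not lambda_s > 0:
        raise ValueError("lambda_s must be positive")
    return 1.0 / lambda_s


@dataclass(frozen=True)
class DayNightSummary:
    day_mean: float
    day_se: float
    n_day: int
    night_mean: float
    night_se: float
    n_night: int


def day_night_summary(series: ActivitySeries,
                      lights_on_s: float = 7 * 3600.0,
                      lights_off_s: float = 19 * 3600.0,
                      exclude_windows: list[tuple[float, float]] | None = None
                      ) -> DayNightSummary:
    """Mean and standard error of the series split by day/night clock time.

    ``exclude_windows`` is an optional list of clock-time intervals (seconds
    after midnight, wrap-aware) removed before averaging — e.g. the 4-hour
    windows around each light transition that are usually discarded because
    the switch itself disturbs the colony.
    """
    if series.duration_s < DAY_S:
        raise ValueError("day/night summary needs at least 24 h of data")
    clock = np.mod(series.start_clock_s + series.times, DAY_S)
    keep = np.ones(len(clock), dtype=bool)
    for a, b in exclude_windows or []:
        if a <= b:
            keep &= ~((clock >= a) & (clock < b))
        else:
            keep &= ~((clock >= a) | (clock < b))
    day = _day_mask(clock, lights_on_s, lights_off_s)

    def _stats(mask):
        v = series.values[mask & keep]
        if len(v) == 0:
            return float("nan"), float("nan"), 0
        se = v.std(ddof=1) / math.sqrt(len(v)) if len(v) > 1 else float("nan")
        return float(v.mean()), float(se), int(len(v))

    dm, dse, nd = _stats(day)
    nm, nse, nn = _stats(~day)
    return DayNightSummary(day_mean=dm, day_se=dse, n_day=nd,
                           night_mean=nm, night_se=nse, n_night=nn)
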