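"""Shared data containers: trajectory tables and time-ordered contact networks.

A :class:`TrajectoryTable` holds per-frame pose records (time, ant, position,
body orientation) for every ant detected in a recording.  A
:class:`TemporalNetwork` holds the raw time-ordered contact sequence — a roster
of ants plus timestamped, duration-bearing pairwise contact events — which is
the substrate for all transmission analyses.  Both round-trip through plain
CSV dialects so recordings can be exchanged with external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TRAJECTORY_COLUMNS = ["time_s", "ant_id", "x_mm", "y_mm", "orientation_deg"]
EDGE_COLUMNS = ["ant_i", "ant_j", "t_start_s", "t_end_s"]


@dataclass
class TrajectoryTable:
    """Per-frame pose records for all ants in one recording.

    ``frames`` has columns ``time_s, ant_id, x_mm, y_mm, orientation_deg``
    with orientation in degrees in [0, 360).  Times lie on a regular frame
    grid; an ant absent from a frame simply has no row there (a missing
    detection).
    """

    frames: pd.DataFrame
    frame_rate_hz: float

    def __post_init__(self) -> None:
        missing = [c for c in TRAJECTORY_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"trajectory table missing columns: {missing}")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def ants(self) -> np.ndarray:
        return np.unique(self.frames["ant_id"].to_numpy())

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.frames["time_s"].to_numpy())

    @property
    def duration_s(self) -> float:
        t = self.frames["time_s"].to_numpy()
        return float(t.max() - t.min()) + 1.0 / self.frame_rate_hz

    def to_csv(self, path: str | Path) -> None:
        self.frames.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)

    @classmethod
    def from_csv(cls, path: str | Path, frame_rate_hz: float | None = None) -> "TrajectoryTable":
        frames = pd.read_csv(path)
        if frame_rate_hz is None:
            t = np.unique(frames["time_s"].to_numpy())
            if len(t) < 2:
                raise ValueError("cannot infer frame rate from fewer than two frames")
            frame_rate_hz = 1.0 / float(np.median(np.diff(t)))
        return cls(frames=frames, frame_rate_hz=frame_rate_hz)


class _CompiledNetwork:
    """Time-sorted event arrays indexed for fast simulation.

    ``starts``/``ends``/``ai``/``aj`` are kept both as numpy arrays (for
    vectorised windowing) and as plain Python lists (``*_l``) for the
    event-driven inner loop, where ndarray scalar extraction would dominate
    the run time.
    """

    __slots__ = ("ants", "index_of", "starts", "ends", "ai", "aj", "n_ants",
                 "starts_l", "ends_l", "ai_l", "aj_l")

    def __init__(self, network: "TemporalNetwork") -> None:
        self.ants = np.asarray(network.ants)
        self.index_of = {int(a): k for k, a in enumerate(self.ants)}
        self.n_ants = len(self.ants)
        ev = network.events
        order = np.argsort(ev["t_start_s"].to_numpy(), kind="stable")
        self.starts = ev["t_start_s"].to_numpy(dtype=float)[order]
        self.ends = ev["t_end_s"].to_numpy(dtype=float)[order]
        self.ai = np.array([self.index_of[int(a)] for a in ev["ant_i"].to_numpy()[order]],
                           dtype=np.int64)
        self.aj = np.array([self.index_of[int(a)] for a in ev["ant_j"].to_numpy()[order]],
                           dtype=np.int64)
        self.starts_l = self.starts.tolist()
        self.ends_l = self.ends.tolist()
        self.ai_l = self.ai.tolist()
        self.aj_l = self.aj.tolist()


@dataclass
class TemporalNetwork:
    """A time-ordered contact sequence over a fixed recording window.

    ``events`` has columns ``ant_i, ant_j, t_start_s, t_end_s`` with
    ``ant_i < ant_j`` and strictly positive durations.  ``ants`` is the full
    roster (it may contain ants that never interacted).  The network is
    analysed as-is, without aggregation into a static graph.
    """

    ants: np.ndarray
    events: pd.DataFrame
    duration_s: float
    _compiled_cache: _CompiledNetwork | None = field(
        default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.ants = np.asarray(sorted(int(a) for a in np.asarray(self.ants)))
        missing = [c for c in EDGE_COLUMNS if c not in self.events.columns]
        if missing:
            raise ValueError(f"edge list missing columns: {missing}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        ev = self.events
        if len(ev) and (ev["t_end_s"].to_numpy() <= ev["t_start_s"].to_numpy()).any():
            raise ValueError("contact events must have positive duration")

    @property
    def n_ants(self) -> int:
        return len(self.ants)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def compiled(self) -> _CompiledNetwork:
        if self._compiled_cache is None:
            self._compiled_cache = _CompiledNetwork(self)
        return self._compiled_cache

    @classmethod
    def from_events(cls, events: pd.DataFrame, duration_s: float,
                    ants: np.ndarray | list | None = None) -> "TemporalNetwork":
        """Build a network, normalising pair order and time order."""
        ev = events.copy()
        if len(ev):
            lo = np.minimum(ev["ant_i"].to_numpy(), ev["ant_j"].to_numpy())
            hi = np.maximum(ev["ant_i"].to_numpy(), ev["ant_j"].to_numpy())
            ev["ant_i"], ev["ant_j"] = lo, hi
            ev = ev.sort_values(["t_start_s", "ant_i", "ant_j"], kind="stable")
            ev = ev.reset_index(drop=True)
        if ants is None:
            ants = np.unique(ev[["ant_i", "ant_j"]].to_numpy()) if len(ev) else np.array([], dtype=int)
        return cls(ants=np.asarray(ants), events=ev[EDGE_COLUMNS], duration_s=duration_s)

    def to_csv(self, path: str | Path) -> None:
        self.events.to_csv(path, index=False, columns=EDGE_COLUMNS)

    @classmethod
    def from_csv(cls, path: str | Path, duration_s: float | None = None,
                 ants: np.ndarray | list | None = None) -> "TemporalNetwork":
        ev = pd.read_csv(path)
        if duration_s is None:
            duration_s = float(ev["t_end_s"].max()) if len(ev) else 1.0
        return cls.from_events(ev, duration_s=duration_s, ants=ants)
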