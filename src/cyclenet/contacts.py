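"""Geometric inference of pairwise ant-to-ant contacts from trajectories.

Each ant is approximated by a trapezoid anchored at its tracked (thorax)
position with the long axis along its body orientation, plus an 'interaction
point' ahead of the position at the front edge.  A contact between two ants
opens at the first frame where the interaction point of at least one of them
lies inside the other's trapezoid AND the circular difference between their
body orientations is at least a threshold angle theta; it closes at the first
subsequent frame where both interaction points are outside one another's
trapezoids.  The angular gate applies at onset only — a contact already open
persists if the pair rotates.

Three threshold conventions are used downstream: theta >= 0 (all contacts),
theta >= 60 (head-to-body and head-to-head) and theta >= 120 (head-on only,
the conservative definition used for transmission simulations).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import TemporalNetwork, TrajectoryTable


@dataclass(frozen=True)
class TrapezoidSpec:
    """Body-approximation geometry, in mm.

    The trapezoid spans the body axis from ``interaction_point_offset_mm -
    length_mm`` (rear) to ``interaction_point_offset_mm`` (front) relative to
    the tracked position; its width tapers linearly from ``back_width_mm`` to
    ``front_width_mm``.  The interaction point sits on the front edge.
    Defaults are a typical *Leptothorax* worker body scale.
    """

    front_width_mm: float = 1.0
    back_width_mm: float = 1.6
    length_mm: float = 3.2
    interaction_point_offset_mm: float = 1.6

    def __post_init__(self) -> None:
        if min(self.front_width_mm, self.back_width_mm, self.length_mm,
               self.interaction_point_offset_mm) <= 0:
            raise ValueError("all trapezoid dimensions must be positive")


@dataclass(frozen=True)
class ContactEvent:
    """One pairwise contact: unordered ant pair, time bounds, onset angle."""

    ant_i: int
    ant_j: int
    t_start_s: float
    t_end_s: float
    theta_deg: float

    def __post_init__(self) -> None:
        if self.ant_i == self.ant_j:
            raise ValueError("a contact needs two distinct ants")
        if self.t_end_s <= self.t_start_s:
            raise ValueError("contact must have positive duration")


def angular_difference(orient_a_deg, orient_b_deg):
    """Minimum circular difference between two orientations, in [0, 180]."""
    d = np.abs(np.mod(np.asarray(orient_a_deg, dtype=float)
                      - np.asarray(orient_b_deg, dtype=float), 360.0))
    out = np.minimum(d, 360.0 - d)
    return float(out) if out.ndim == 0 else out


def _points_in_trapezoid(px, py, ax, ay, orient_deg, spec: TrapezoidSpec):
    """Vectorised point-in-trapezoid test in the body frame of ant A.

    Boundaries are inclusive (a point on an edge counts as inside), giving a
    deterministic tie-break.  NaN coordinates yield False.
    """
    phi = np.radians(orient_deg)
    c, s = np.cos(phi), np.sin(phi)
    dx, dy = px - ax, py - ay
    u = dx * c + dy * s        # along body axis, forward positive
    v = -dx * s + dy * c       # lateral
    u_front = spec.interaction_point_offset_mm
    u_back = u_front - spec.length_mm
    frac = (u - u_back) / spec.length_mm
    half_w = 0.5 * (spec.back_width_mm
                    + (spec.front_width_mm - spec.back_width_mm) * frac)
    with np.errstate(invalid="ignore"):
        inside = (u >= u_back) & (u <= u_front) & (np.abs(v) <= half_w)
    return np.where(np.isnan(u) | np.isnan(v), False, inside)


def _interaction_point(x, y, orient_deg, spec: TrapezoidSpec):
    phi = np.radians(orient_deg)
    return (x + spec.interaction_point_offset_mm * np.cos(phi),
            y + spec.interaction_point_offset_mm * np.sin(phi))


def _pose_arrays(trajs: TrajectoryTable):
    """Dense (n_frames, n_ants) pose arrays with NaN for missing detections."""
    times = trajs.times
    ants = trajs.ants
    t_index = {t: k for k, t in enumerate(times)}
    a_index = {a: k for k, a in enumerate(ants)}
    shape = (len(times), len(ants))
    x = np.full(shape, np.nan)
    y = np.full(shape, np.nan)
    o = np.full(shape, np.nan)
    fr = trajs.frames
    ti = fr["time_s"].map(t_index).to_numpy()
    ai = fr["ant_id"].map(a_index).to_numpy()
    x[ti, ai] = fr["x_mm"].to_numpy()
    y[ti, ai] = fr["y_mm"].to_numpy()
    o[ti, ai] = fr["orientation_deg"].to_numpy()
    return times, ants, x, y, o


def detect_contacts(trajs: TrajectoryTable, theta_min_deg: float = 120.0,
                    spec: TrapezoidSpec | None = None) -> list[ContactEvent]:
    """Infer all pairwise contact events from a trajectory table.

    Returns events sorted by start time.  Frames where an ant is undetected
    contribute no geometry, so a gap in a trajectory closes any open contact
    involving that ant at the last seen frame.
    """
    spec = spec or TrapezoidSpec()
    times, ants, x, y, o = _pose_arrays(trajs)
    n_frames, n = x.shape
    if n_frames < 1:
        return []
    dt = 1.0 / trajs.frame_rate_hz
    ipx, ipy = _interaction_point(x, y, o, spec)

    events: list[ContactEvent] = []
    for a in range(n):
        for b in range(a + 1, n):
            geom = (_points_in_trapezoid(ipx[:, a], ipy[:, a],
                                         x[:, b], y[:, b], o[:, b], spec)
                    | _points_in_trapezoid(ipx[:, b], ipy[:, b],
                                           x[:, a], y[:, a], o[:, a], spec))
            if not geom.any():
                continue
            ang = angular_difference(o[:, a], o[:, b])
            gate = ~np.isnan(ang) & (ang >= theta_min_deg)
            # Episodes: maximal runs of consecutive geometric-contact frames.
            padded = np.concatenate(([False], geom, [False]))
            edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
            for s_idx, e_idx in zip(edges[::2], edges[1::2]):
                onset_candidates = np.flatnonzero(gate[s_idx:e_idx])
                if len(onset_candidates) == 0:
                    continue
                onset = s_idx + onset_candidates[0]
                t_start = float(times[onset])
                t_end = float(times[e_idx]) if e_idx < n_frames \
                    else float(times[-1]) + dt
                events.append(ContactEvent(int(ants[a]), int(ants[b]),
                                           t_start, t_end, float(ang[onset])))
    events.sort(key=lambda e: (e.t_start_s, e.ant_i, e.ant_j))
    return events


def events_to_dataframe(events: list[ContactEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.ant_i, e.ant_j, e.t_start_s, e.t_end_s, e.theta_deg) for e in events],
        columns=["ant_i", "ant_j", "t_start_s", "t_end_s", "theta_deg"])


def events_to_network(events: list[ContactEvent], trajs: TrajectoryTable) -> TemporalNetwork:
    """Package detected contacts as a temporal network over the full roster."""
    ev = events_to_dataframe(events)[["ant_i", "ant_j", "t_start_s", "t_end_s"]]
    return TemporalNetwork.from_events(ev, duration_s=trajs.duration_s,
                                       ants=trajs.ants)


def write_contacts_csv(events: list[ContactEvent], path: str | Path) -> None:
    events_to_dataframe(events).to_csv(path, index=False)
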