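"""Detect directed social interaction events from fly trajectories.

A fly A is *interacting toward* fly B at a frame when the two centroids are
within 2.5 body lengths (≈5 mm) and B lies inside A's field-of-view cone —
the angular offset between A's heading and the A→B bearing is at most half
the configured field-of-view angle (160° total by default, i.e. ±80°).
Maximal runs of consecutive interacting frames lasting at least 0.6 s become
directed :class:`InteractionEvent` records, which aggregate into a directed
graph with two edge weights: interaction ``count`` and total ``duration_s``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .trajectory_io import FlyTrack, wrap_angle

__all__ = [
    "InteractionCriteria",
    "InteractionEvent",
    "tracks_to_arrays",
    "pairwise_state",
    "interaction_state",
    "detect_events",
    "detect_events_arrays",
    "build_network",
    "events_to_frame",
    "write_edge_list",
]


@dataclass(frozen=True)
class InteractionCriteria:
    """Distance / orientation / duration thresholds for an interaction.

    ``angle_convention`` selects how the field-of-view angle is read:
    ``"half_cone"`` (default) treats it as the full cone width, so the actor
    interacts when its angular offset to the target is ≤ angle/2;
    ``"full"`` uses the stated angle as the offset bound directly.
    """

    max_distance_body_lengths: float = 2.5
    body_length_mm: float = 2.0
    max_facing_angle_deg: float = 160.0
    min_duration_s: float = 0.6
    angle_convention: str = "half_cone"

    def __post_init__(self):
        if min(self.max_distance_body_lengths, self.body_length_mm,
               self.max_facing_angle_deg, self.min_duration_s) <= 0:
            raise ValueError("all criteria must be strictly positive")
        if self.max_facing_angle_deg > 360:
            raise ValueError("max_facing_angle_deg must be <= 360")
        if self.angle_convention not in ("half_cone", "full"):
            raise ValueError("angle_convention must be 'half_cone' or 'full'")

    @property
    def max_distance_mm(self) -> float:
        return self.max_distance_body_lengths * self.body_length_mm

    @property
    def max_offset_rad(self) -> float:
        deg = self.max_facing_angle_deg
        if self.angle_convention == "half_cone":
            deg = deg / 2.0
        return np.deg2rad(deg)


@dataclass(frozen=True)
class InteractionEvent:
    """One directed interaction bout (actor toward target)."""

    actor_fly: int
    target_fly: int
    start_frame: int
    end_frame: int  # inclusive
    duration_s: float

    def __post_init__(self):
        if self.actor_fly == self.target_fly:
            raise ValueError("actor and target must differ")
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame < start_frame")


def tracks_to_arrays(tracks: Sequence[FlyTrack], n_frames: int | None = None):
    """Pack tracks onto a common frame grid.

    Returns ``(pos, heading, present)`` with shapes ``(T, N, 2)``, ``(T, N)``
    and boolean ``(T, N)``; frames a fly was not tracked at (gaps, splits)
    are marked absent.  Fly order follows the input sequence; array column i
    is ``tracks[i]``.
    """
    if n_frames is None:
        n_frames = 1 + max((int(t.frames[-1]) for t in tracks if len(t)), default=-1)
    n = len(tracks)
    pos = np.full((n_frames, n, 2), np.nan)
    heading = np.full((n_frames, n), np.nan)
    present = np.zeros((n_frames, n), dtype=bool)
    for i, t in enumerate(tracks):
        f = t.frames[t.frames < n_frames]
        k = len(f)
        pos[f, i, 0] = t.x[:k]
        pos[f, i, 1] = t.y[:k]
        heading[f, i] = t.heading[:k]
        present[f, i] = True
    return pos, heading, present


def interaction_state(pos, heading, present, criteria: InteractionCriteria,
                      block: int = 2000) -> np.ndarray:
    """Boolean state ``(T, N, N)``: ``state[t, i, j]`` = fly i interacting toward j.

    Computed in time blocks to bound memory on long recordings.
    """
    T, n = heading.shape
    dmax2 = criteria.max_distance_mm**2
    amax = criteria.max_offset_rad
    # |wrap(bearing - heading)| <= amax  <=>  cos(bearing - heading) >= cos(amax)
    # for amax in [0, pi]; the cosine of the offset is the projection of the
    # actor->target displacement onto the actor's heading over the distance.
    facing_free = amax >= np.pi
    cos_amax = np.cos(amax)
    state = np.zeros((T, n, n), dtype=bool)
    eye = np.eye(n, dtype=bool)
    with np.errstate(invalid="ignore"):
        cos_h, sin_h = np.cos(heading), np.sin(heading)
        for s in range(0, T, block):
            e = min(T, s + block)
            p = pos[s:e]
            dx = p[:, None, :, 0] - p[:, :, None, 0]  # displacement i -> j
            dy = p[:, None, :, 1] - p[:, :, None, 1]
            d2 = dx * dx + dy * dy
            ok = d2 <= dmax2
            if not facing_free:
                proj = dx * cos_h[s:e, :, None] + dy * sin_h[s:e, :, None]
                ok &= proj >= np.sqrt(d2) * cos_amax
            ok &= present[s:e, :, None] & present[s:e, None, :]
            ok &= ~eye
            state[s:e] = ok
    return state


def pairwise_state(tracks: Sequence[FlyTrack], criteria: InteractionCriteria,
                   frame: int) -> np.ndarray:
    """Per-ordered-pair interaction state at a single frame.

    A fly missing at the frame yields ``False`` in its row and column.
    """
    pos, heading, present = tracks_to_arrays(tracks, n_frames=frame + 1)
    return interaction_state(pos[frame : frame + 1], heading[frame : frame + 1],
                             present[frame : frame + 1], criteria)[0]


def _runs_bool(col: np.ndarray):
    """Start indices and lengths of maximal True runs in a 1-D boolean array."""
    t = np.diff(col.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(t == 1)
    ends = np.flatnonzero(t == -1)
    return starts, ends - starts


def detect_events_arrays(pos, heading, present, criteria: InteractionCriteria,
                         frame_rate_hz: float) -> list[InteractionEvent]:
    if frame_rate_hz <= 0:
        raise ValueError("frame_rate_hz must be positive")
    state = interaction_state(pos, heading, present, criteria)
    T, n, _ = state.shape
    # minimum run length in frames; the >= comparison is inclusive at 0.6 s
    min_frames = int(np.ceil(criteria.min_duration_s * frame_rate_hz - 1e-9))
    events = []
    flat = state.reshape(T, n * n)
    active = np.flatnonzero(flat.any(axis=0))
    for k in active:
        i, j = divmod(int(k), n)
        starts, lengths = _runs_bool(flat[:, k])
        for s, ln in zip(starts, lengths):
            if ln >= min_frames:
                events.append(
                    InteractionEvent(
                        actor_fly=i, target_fly=j,
                        start_frame=int(s), end_frame=int(s + ln - 1),
                        duration_s=ln / frame_rate_hz,
                    )
                )
    events.sort(key=lambda e: (e.start_frame, e.actor_fly, e.target_fly))
    return events


def detect_events(tracks: Sequence[FlyTrack], criteria: InteractionCriteria,
                  frame_rate_hz: float) -> list[InteractionEvent]:
    """Directed interaction events from a set of co-recorded tracks.

    Fly indices in the returned events refer to positions in ``tracks``.
    Gap frames break runs: an interaction interrupted by a tracking gap is
    two events (bridge short gaps beforehand with ``fill_gaps`` if desired).
    """
    pos, heading, present = tracks_to_arrays(tracks)
    return detect_events_arrays(pos, heading, present, criteria, frame_rate_hz)


def build_network(events: Sequence[InteractionEvent], n_flies: int,
                  recording_id: str = "", genotype: str = "") -> nx.DiGraph:
    """Aggregate events into a directed weighted graph on ``n_flies`` nodes.

    Isolated flies are retained as nodes.  Each edge A→B carries ``count``
    (number of events) and ``duration_s`` (summed event durations).
    """
    g = nx.DiGraph(recording_id=recording_id, genotype=genotype)
    g.add_nodes_from(range(n_flies))
    for ev in events:
        if ev.actor_fly >= n_flies or ev.target_fly >= n_flies:
            raise ValueError("event fly id out of range")
        if g.has_edge(ev.actor_fly, ev.target_fly):
            d = g[ev.actor_fly][ev.target_fly]
            d["count"] += 1
            d["duration_s"] += ev.duration_s
        else:
            g.add_edge(ev.actor_fly, ev.target_fly, count=1, duration_s=ev.duration_s)
    return g


def events_to_frame(events: Sequence[InteractionEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "actor": e.actor_fly,
                "target": e.target_fly,
                "start_frame": e.start_frame,
                "end_frame": e.end_frame,
                "duration_s": e.duration_s,
            }
            for e in events
        ],
        columns=["actor", "target", "start_frame", "end_frame", "duration_s"],
    )


def write_edge_list(g: nx.DiGraph, path) -> None:
    """Weighted edge list: actor, target, count, duration_s (CSV)."""
    rows = [
        {"actor": u, "target": v, "count": d["count"], "duration_s": d["duration_s"]}
        for u, v, d in sorted(g.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["actor", "target", "count", "duration_s"]).to_csv(
        path, index=False, float_format="%.17g"
    )
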