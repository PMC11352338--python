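"""Reading, writing and validating tracker-style fly trajectory tables.

The on-disk dialect is a plain delimited table with one header line and
columns ``frame, fly_id, x_mm, y_mm, heading_rad``:

* ``frame`` — 0-based integer frame index;
* ``fly_id`` — 0-based integer fly identity;
* ``x_mm, y_mm`` — arena-local coordinates in millimetres, origin at the
  arena centre;
* ``heading_rad`` — body orientation, counter-clockwise from the +x axis,
  wrapped to (−π, π].

Rows with an empty/NaN position are treated as tracking gaps: the frame is
simply absent from the resulting :class:`FlyTrack` (gaps are never
interpolated silently; see :func:`fill_gaps`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FlyTrack",
    "RecordingMeta",
    "TrajectoryParseError",
    "TrajectoryIntegrityError",
    "read_trajectories",
    "write_trajectories",
    "fill_gaps",
    "wrap_angle",
]

_COLUMNS = ["frame", "fly_id", "x_mm", "y_mm", "heading_rad"]


class TrajectoryParseError(ValueError):
    """Malformed trajectory row; carries the 1-based line number."""


class TrajectoryIntegrityError(ValueError):
    """Structurally valid file that violates track invariants."""


def wrap_angle(a):
    """Wrap angle(s) to the half-open interval (−π, π]."""
    a = np.asarray(a, dtype=float)
    out = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class RecordingMeta:
    """Recording-level metadata for one arena video."""

    frame_rate_hz: float = 30.0
    arena_diameter_mm: float = 61.0
    genotype: str = ""
    recording_id: str = ""
    adaptation_min: float = 10.0
    recording_min: float = 25.0

    def __post_init__(self):
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")


@dataclass
class FlyTrack:
    """One fly's per-frame position and heading.

    ``frames`` are strictly increasing but need not be contiguous — a jump
    marks a tracking gap.  ``split_frames`` records frame indices at which a
    gap too long to interpolate begins (set by :func:`fill_gaps`); event
    detection treats absent frames as "not interacting".
    """

    fly_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    split_frames: list = field(default_factory=list)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        n = len(self.frames)
        if not (len(self.x) == len(self.y) == len(self.heading) == n):
            raise TrajectoryIntegrityError("column length mismatch")
        if n and np.any(np.diff(self.frames) <= 0):
            raise TrajectoryIntegrityError(
                f"fly {self.fly_id}: frame indices not strictly increasing"
            )
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise TrajectoryIntegrityError(f"fly {self.fly_id}: non-finite position")
        if n and (np.any(self.heading <= -np.pi - 1e-12) or np.any(self.heading > np.pi + 1e-12)):
            raise TrajectoryIntegrityError(f"fly {self.fly_id}: heading outside (-pi, pi]")

    def __len__(self):
        return len(self.frames)

    @property
    def n_gaps(self) -> int:
        return int(np.sum(np.diff(self.frames) > 1)) if len(self) > 1 else 0


def read_trajectories(path, meta: Optional[RecordingMeta] = None,
                      column_map: Optional[dict] = None) -> list[FlyTrack]:
    """Read a trajectory table into one :class:`FlyTrack` per fly.

    Parameters
    ----------
    path : str or Path
        Delimited text file (comma or tab separated, sniffed) with a header.
    meta : RecordingMeta, optional
        Attached for provenance only; parsing does not depend on it.
    column_map : dict, optional
        Mapping from this file's column names to the canonical names, for
        importing tables exported by external trackers
        (e.g. ``{"pos x": "x_mm", "ori": "heading_rad", ...}``).
    """
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    # round_trip parsing so written tracks reload bit-identically
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise TrajectoryParseError(f"{path}: missing columns {missing}")
    for col in ("frame", "fly_id"):
        bad = df[col].isna() | (df[col] != df[col].astype("Int64").astype("float"))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise TrajectoryParseError(f"{path}: non-integer {col} at line {line}")
    dup = df.duplicated(subset=["frame", "fly_id"])
    if dup.any():
        line = int(np.flatnonzero(dup.to_numpy())[0]) + 2
        raise TrajectoryIntegrityError(f"{path}: duplicate (frame, fly_id) at line {line}")
    bad_heading = df["heading_rad"].notna() & (
        (df["heading_rad"] <= -np.pi - 1e-12) | (df["heading_rad"] > np.pi + 1e-12)
    )
    if bad_heading.any():
        line = int(np.flatnonzero(bad_heading.to_numpy())[0]) + 2
        raise TrajectoryParseError(f"{path}: heading outside (-pi, pi] at line {line}")

    tracks = []
    for fly_id, sub in df.groupby("fly_id", sort=True):
        sub = sub.sort_values("frame")
        ok = sub["x_mm"].notna() & sub["y_mm"].notna() & sub["heading_rad"].notna()
        sub = sub[ok]  # missing-position rows become gaps
        tracks.append(
            FlyTrack(
                fly_id=int(fly_id),
                frames=sub["frame"].to_numpy(dtype=np.int64),
                x=sub["x_mm"].to_numpy(dtype=float),
                y=sub["y_mm"].to_numpy(dtype=float),
                heading=sub["heading_rad"].to_numpy(dtype=float),
            )
        )
    return tracks


def write_trajectories(tracks: Sequence[FlyTrack], path, sep: str = ",") -> None:
    """Write tracks in the canonical dialect (sorted by frame, then fly)."""
    parts = [
        pd.DataFrame(
            {
                "frame": t.frames,
                "fly_id": t.fly_id,
                "x_mm": t.x,
                "y_mm": t.y,
                "heading_rad": t.heading,
            }
        )
        for t in tracks
    ]
    df = pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=_COLUMNS)
    df = df.sort_values(["frame", "fly_id"], kind="mergesort")
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def _interp_heading(h0: float, h1: float, f: np.ndarray) -> np.ndarray:
    # shorter circular arc; an exact pi tie is broken toward positive rotation
    d = h1 - h0
    d = -((-d + np.pi) % (2 * np.pi) - np.pi)
    if np.isclose(abs(d), np.pi):
        d = np.pi
    return wrap_angle(h0 + f * d)


def fill_gaps(track: FlyTrack, max_gap_frames: int) -> FlyTrack:
    """Interpolate tracking gaps of at most ``max_gap_frames`` missing frames.

    Position is interpolated linearly, heading along the shorter circular
    arc.  Longer gaps are left in place and their start frame is appended to
    ``split_frames`` so downstream interaction detection treats the track as
    split there.  Idempotent.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    if len(track) < 2:
        return replace(track, split_frames=list(track.split_frames))

    splits = []
    out_f, out_x, out_y, out_h = [track.frames[:1]], [track.x[:1]], [track.y[:1]], [track.heading[:1]]
    for i in range(1, len(track)):
        gap = int(track.frames[i] - track.frames[i - 1]) - 1
        if 0 < gap <= max_gap_frames:
            f = np.arange(1, gap + 1) / (gap + 1)
            out_f.append(np.arange(track.frames[i - 1] + 1, track.frames[i]))
            out_x.append(track.x[i - 1] + f * (track.x[i] - track.x[i - 1]))
            out_y.append(track.y[i - 1] + f * (track.y[i] - track.y[i - 1]))
            out_h.append(_interp_heading(track.heading[i - 1], track.heading[i], f))
        elif gap > max_gap_frames:
            splits.append(int(track.frames[i - 1]) + 1)
        out_f.append(track.frames[i : i + 1])
        out_x.append(track.x[i : i + 1])
        out_y.append(track.y[i : i + 1])
        out_h.append(track.heading[i : i + 1])
    return FlyTrack(
        fly_id=track.fly_id,
        frames=np.concatenate(out_f),
        x=np.concatenate(out_x),
        y=np.concatenate(out_y),
        heading=np.concatenate(out_h),
        split_frames=sorted(set(track.split_frames) | set(splits)),
    )
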