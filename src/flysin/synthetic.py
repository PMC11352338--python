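"""Synthetic generators for every raw input the pipeline consumes.

Four generators with exact ground truth:

* arena trajectories — a correlated random walk in a circular arena
  (61 mm diameter) with reflective walls and an optional attraction of each
  fly toward the centroid of its planted group-mates.  With
  ``attraction_strength = 0`` the flies are statistically independent, which
  is the null condition the random-network z-scores must be honest about.
* beam-break activity — per-minute Poisson counts modulated by a circadian
  rate profile with morning and evening peaks, a midday siesta, and planted
  sleep bouts injected as forced-zero windows (so sleep ground truth is
  exact, not emergent).
* negative-geotaxis trials — binomial climbing outcomes.
* plate-reader absorbances — a linear calibration series plus free/total
  glutathione reads, where the total read corresponds to GSH + 2·GSSG
  (each oxidized GSSG reduces to two GSH).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .activity import ActivitySeries, SleepBout
from .trajectory_io import FlyTrack, wrap_angle

__all__ = [
    "ArenaSpec",
    "SocialProfile",
    "ActivityProfile",
    "simulate_trajectories",
    "simulate_activity",
    "simulate_geotaxis",
    "simulate_assay_readings",
]


@dataclass(frozen=True)
class ArenaSpec:
    """Circular recording arena and sampling grid."""

    diameter_mm: float = 61.0
    fly_body_length_mm: float = 2.0  # 2.5 body lengths ~ 5 mm
    frame_rate_hz: float = 30.0
    duration_s: float = 60.0

    def __post_init__(self):
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.frame_rate_hz * self.duration_s))

    @property
    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0


@dataclass(frozen=True)
class SocialProfile:
    """Motion parameters of the trajectory generator.

    ``attraction_strength`` in [0, 1] is the fraction of the angular offset
    toward the group centroid corrected per frame; 0 gives independent
    correlated random walks (the null), 1 heads straight at the group.
    ``planted_group_assignment`` maps fly id -> group label; by default all
    flies share one group.
    """

    attraction_strength: float = 0.0
    step_speed_mm_s: float = 5.0
    turning_noise_rad: float = 0.2
    planted_group_assignment: Optional[dict] = None

    def __post_init__(self):
        if self.attraction_strength < 0:
            raise ValueError("attraction_strength must be >= 0")
        if self.step_speed_mm_s < 0 or self.turning_noise_rad < 0:
            raise ValueError("speed and turning noise must be >= 0")


def simulate_trajectories(arena: ArenaSpec, n_flies: int, profile: SocialProfile,
                          seed) -> list[FlyTrack]:
    """Correlated-random-walk trajectories for ``n_flies`` in the arena.

    Flies start uniformly placed in the disc with uniform headings.  Each
    frame the heading is first pulled toward the planted group's centroid
    (if attraction > 0), then perturbed by Gaussian turning noise; the fly
    steps ``speed/frame_rate`` along its heading and reflects off the wall.
    Deterministic given the seed.
    """
    if n_flies < 2:
        raise ValueError("n_flies must be >= 2")
    rng = np.random.default_rng(seed)
    R = arena.radius_mm
    T = arena.n_frames
    step = profile.step_speed_mm_s / arena.frame_rate_hz
    kappa = min(profile.attraction_strength, 1.0)

    groups = profile.planted_group_assignment or {i: 0 for i in range(n_flies)}
    labels = np.array([groups.get(i, -1 - i) for i in range(n_flies)])
    same_group = (labels[:, None] == labels[None, :]) & ~np.eye(n_flies, dtype=bool)

    r = R * np.sqrt(rng.uniform(size=n_flies))
    th = rng.uniform(-np.pi, np.pi, size=n_flies)
    pos = np.column_stack([r * np.cos(th), r * np.sin(th)])
    heading = rng.uniform(-np.pi, np.pi, size=n_flies)
    noise = rng.normal(0.0, profile.turning_noise_rad, size=(T, n_flies))

    out_pos = np.empty((T, n_flies, 2))
    out_head = np.empty((T, n_flies))
    for t in range(T):
        if kappa > 0:
            # pull each fly's heading toward the centroid of its group-mates
            with np.errstate(invalid="ignore"):
                nmates = same_group.sum(axis=1)
                cent = (same_group @ pos) / np.maximum(nmates, 1)[:, None]
            vec = cent - pos
            has = (nmates > 0) & (np.hypot(vec[:, 0], vec[:, 1]) > 1e-9)
            bearing = np.arctan2(vec[:, 1], vec[:, 0])
            dh = wrap_angle(bearing - heading)
            heading = np.where(has, heading + kappa * dh, heading)
        heading = wrap_angle(heading + noise[t])
        pos = pos + step * np.column_stack([np.cos(heading), np.sin(heading)])
        rad = np.hypot(pos[:, 0], pos[:, 1])
        outside = rad > R
        if np.any(outside):
            u = pos[outside] / rad[outside, None]
            pos[outside] -= 2.0 * (rad[outside] - R)[:, None] * u
            v = np.column_stack([np.cos(heading[outside]), np.sin(heading[outside])])
            v -= 2.0 * np.sum(v * u, axis=1)[:, None] * u
            heading[outside] = np.arctan2(v[:, 1], v[:, 0])
            heading = wrap_angle(heading)
        out_pos[t] = pos
        out_head[t] = heading

    frames = np.arange(T, dtype=np.int64)
    return [
        FlyTrack(fly_id=i, frames=frames, x=out_pos[:, i, 0], y=out_pos[:, i, 1],
                 heading=out_head[:, i])
        for i in range(n_flies)
    ]


@dataclass(frozen=True)
class ActivityProfile:
    """Circadian shape of the per-minute beam-break rate.

    The rate is ``mean_counts_per_min`` times a nonnegative profile of the
    circadian phase with Gaussian-shaped peaks at the morning and evening
    clock hours, a midday dip of depth ``siesta_depth`` (fraction of the
    baseline suppressed between the peaks) and a quiescent night.  Sleep
    bouts (zero-count windows) are planted on top at ``sleep_bout_rate_per_h``
    with mean length ``sleep_bout_len_min``.
    """

    period_h: float = 24.0
    morning_peak_h: float = 8.0
    evening_peak_h: float = 20.0
    siesta_depth: float = 0.6
    mean_counts_per_min: float = 2.0
    sleep_bout_rate_per_h: float = 0.25
    sleep_bout_len_min: float = 20.0
    peak_width_h: float = 1.5
    night_level: float = 0.15

    def __post_init__(self):
        if not (16.0 <= self.period_h <= 32.0):
            raise ValueError("period_h must be in [16, 32]")
        for name in ("siesta_depth",):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.mean_counts_per_min, self.sleep_bout_rate_per_h,
               self.sleep_bout_len_min) < 0:
            raise ValueError("rates and lengths must be >= 0")


def _circadian_shape(profile: ActivityProfile, minutes: np.ndarray) -> np.ndarray:
    """Relative rate (mean 1 over one period) at absolute minutes since t0."""
    period_min = profile.period_h * 60.0
    phase_h = (minutes % period_min) / 60.0 * (24.0 / profile.period_h)

    def bump(center, width):
        d = np.minimum(np.abs(phase_h - center), 24.0 - np.abs(phase_h - center))
        return np.exp(-0.5 * (d / width) ** 2)

    day = (phase_h >= profile.morning_peak_h) & (phase_h < profile.evening_peak_h)
    base = np.where(day, 1.0, profile.night_level)
    mid = 0.5 * (profile.morning_peak_h + profile.evening_peak_h)
    siesta = 1.0 - profile.siesta_depth * bump(mid, 2.5)
    shape = base * siesta + 2.0 * (bump(profile.morning_peak_h, profile.peak_width_h)
                                   + bump(profile.evening_peak_h, profile.peak_width_h))
    return shape / np.mean(shape) if np.mean(shape) > 0 else shape


def simulate_activity(profile: ActivityProfile, n_days: int,
                      lights_on_h: float = 8.0, lights_off_h: float = 20.0,
                      seed=None, constant_darkness: bool = False,
                      fly_id: int = 0) -> ActivitySeries:
    """Per-minute beam-break counts for ``n_days`` starting at midnight.

    Counts are Poisson with the circadian-shaped rate; planted sleep bouts
    force zeros and their flanking minutes are forced nonzero so the planted
    windows are recovered exactly by sleep detection.  The planted ground
    truth is attached as ``planted_sleep_bouts``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if not constant_darkness and lights_on_h == lights_off_h:
        raise ValueError("lights_on_h must differ from lights_off_h")
    rng = np.random.default_rng(seed)
    n_min = int(n_days * 24 * 60)
    minutes = np.arange(n_min, dtype=float)
    rate = profile.mean_counts_per_min * _circadian_shape(profile, minutes)
    counts = rng.poisson(rate).astype(np.int64)

    planted: list[SleepBout] = []
    if profile.sleep_bout_rate_per_h > 0 and profile.sleep_bout_len_min > 0:
        n_bouts = rng.poisson(profile.sleep_bout_rate_per_h * n_days * 24)
        taken = np.zeros(n_min, dtype=bool)
        for _ in range(int(n_bouts)):
            length = max(6, int(round(rng.exponential(profile.sleep_bout_len_min))))
            start = int(rng.integers(1, max(2, n_min - length - 1)))
            lo, hi = max(0, start - 2), min(n_min, start + length + 2)
            if taken[lo:hi].any():
                continue  # keep planted bouts disjoint and non-adjacent
            taken[lo:hi] = True
            counts[start : start + length] = 0
            if profile.mean_counts_per_min > 0:
                counts[start - 1] = max(1, counts[start - 1])
                if start + length < n_min:
                    counts[start + length] = max(1, counts[start + length])
            planted.append(SleepBout(start_min=start, length_min=length))
    planted.sort(key=lambda b: b.start_min)

    return ActivitySeries(
        fly_id=fly_id,
        start_min=0,
        counts=counts,
        lights_on_h=lights_on_h,
        lights_off_h=lights_off_h,
        constant_darkness=constant_darkness,
        planted_sleep_bouts=planted,
    )


def simulate_geotaxis(p_climb: float, n_groups: int, flies_per_group: int,
                      trials_per_group: int, seed=None,
                      genotype: str = "synthetic") -> pd.DataFrame:
    """Binomial climbing-trial table (genotype, group, trial, n_flies, n_climbed)."""
    if not (0.0 <= p_climb <= 1.0):
        raise ValueError("p_climb must be a probability")
    rng = np.random.default_rng(seed)
    rows = []
    for g in range(n_groups):
        climbed = rng.binomial(flies_per_group, p_climb, size=trials_per_group)
        for t, c in enumerate(climbed):
            rows.append(
                {"genotype": genotype, "group": g, "trial": t,
                 "n_flies": flies_per_group, "n_climbed": int(c)}
            )
    return pd.DataFrame(rows, columns=["genotype", "group", "trial", "n_flies", "n_climbed"])


def simulate_assay_readings(true_gsh_uM: float, true_gssg_uM: float,
                            calib_slope: float = 0.05, calib_intercept: float = 0.02,
                            noise_sd: float = 0.0, seed=None,
                            calib_concentrations_uM: Sequence[float] = (0, 2, 5, 10, 20, 40),
                            sample_id: str = "s0") -> pd.DataFrame:
    """Ellman-assay absorbance records for one sample plus its calibration.

    The free read reports the GSH concentration; the total (post-reduction)
    read reports GSH + 2·GSSG, since borohydride reduction converts each
    GSSG into two GSH before the DTNB reaction.  Returns the assay CSV
    dialect: sample_id, reading_type (free|total|calib), concentration
    (calibration rows only), value (A415).
    """
    if true_gsh_uM < 0 or true_gssg_uM < 0:
        raise ValueError("concentrations must be >= 0")
    if calib_slope <= 0:
        raise ValueError("calib_slope must be positive")
    rng = np.random.default_rng(seed)

    def read(conc):
        return calib_slope * conc + calib_intercept + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)

    rows = [
        {"sample_id": sample_id, "reading_type": "free", "concentration": np.nan,
         "value": read(true_gsh_uM)},
        {"sample_id": sample_id, "reading_type": "total", "concentration": np.nan,
         "value": read(true_gsh_uM + 2.0 * true_gssg_uM)},
    ]
    for c in calib_concentrations_uM:
        rows.append({"sample_id": sample_id, "reading_type": "calib",
                     "concentration": float(c), "value": read(c)})
    return pd.DataFrame(rows, columns=["sample_id", "reading_type", "concentration", "value"])
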