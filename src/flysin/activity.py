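"""Beam-break activity series: day/night summaries, sleep bouts, circadian period.

Activity is the number of times a fly crossed the monitor's infrared beam in
each one-minute interval.  Sleep is a maximal run of zero-count minutes
strictly longer than 5 minutes (the arousal-threshold-validated criterion;
the ``>=`` convention is switchable).  The free-running circadian period of
a constant-darkness recording is estimated with the Sokolove–Bushell
chi-square periodogram (autocorrelation available as an alternative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivitySeries",
    "SleepBout",
    "PeriodEstimate",
    "read_monitor",
    "write_activity_csv",
    "phase_summary",
    "detect_sleep",
    "sleep_by_phase",
    "estimate_period",
]

MIN_PER_DAY = 1440


@dataclass(frozen=True)
class SleepBout:
    """A maximal inactivity bout (start minute within the series, length)."""

    start_min: int
    length_min: int

    @property
    def end_min(self) -> int:  # exclusive
        return self.start_min + self.length_min


@dataclass
class ActivitySeries:
    """Contiguous per-minute beam-break counts for one fly/channel.

    ``start_min`` is the offset of the first sample from midnight of day 0,
    so minute-of-day arithmetic works for recordings not starting at 00:00.
    """

    fly_id: int
    start_min: int
    counts: np.ndarray
    lights_on_h: float = 8.0
    lights_off_h: float = 20.0
    constant_darkness: bool = False
    planted_sleep_bouts: Optional[list] = None
    gap_minutes: list = field(default_factory=list)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1 or len(self.counts) < 1:
            raise ValueError("counts must be a nonempty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    def __len__(self):
        return len(self.counts)

    def minute_of_day(self) -> np.ndarray:
        return (self.start_min + np.arange(len(self))) % MIN_PER_DAY

    def is_light(self) -> np.ndarray:
        """Boolean per minute: inside the light phase [lights_on, lights_off)."""
        if self.constant_darkness:
            return np.zeros(len(self), dtype=bool)
        on = int(round(self.lights_on_h * 60))
        off = int(round(self.lights_off_h * 60))
        mod = self.minute_of_day()
        if on < off:
            return (mod >= on) & (mod < off)
        return (mod >= on) | (mod < off)

    def complete_days(self) -> list[int]:
        """Civil days (index from day 0) fully covered by the series."""
        first = -(-self.start_min // MIN_PER_DAY)  # ceil
        last = (self.start_min + len(self)) // MIN_PER_DAY  # exclusive
        return list(range(first, last))


def write_activity_csv(series: Sequence[ActivitySeries], path) -> None:
    """Simplified CSV dialect: one ``minute`` column plus one column per fly."""
    series = list(series)
    n = len(series[0])
    start = series[0].start_min
    for s in series:
        if len(s) != n or s.start_min != start:
            raise ValueError("all series must share the time grid")
    df = pd.DataFrame({"minute": start + np.arange(n)})
    for s in series:
        df[f"fly_{s.fly_id}"] = s.counts
    df.to_csv(path, index=False)


def read_monitor(path, dialect: str = "csv", lights_on_h: float = 8.0,
                 lights_off_h: float = 20.0, constant_darkness: bool = False,
                 n_meta_cols: int = 10) -> list[ActivitySeries]:
    """Read activity series from the simplified CSV or a TriKinetics-style file.

    ``dialect="csv"``: header ``minute, fly_<id>, ...`` as written by
    :func:`write_activity_csv`.  ``dialect="dams"``: tab-separated monitor
    rows — reading index, date, time ``HH:MM:SS``, then ``n_meta_cols − 3``
    further status columns, then one integer count per channel, one row per
    minute.  Non-monotone timestamps raise; missing minutes are filled with
    zero counts and flagged in ``gap_minutes``.
    """
    if dialect == "csv":
        df = pd.read_csv(path)
        if "minute" not in df.columns:
            raise ValueError(f"{path}: simplified dialect needs a 'minute' column")
        minutes = df["minute"].to_numpy(dtype=np.int64)
        chan_cols = [c for c in df.columns if c != "minute"]
        counts_mat = df[chan_cols].to_numpy(dtype=np.int64).T
        ids = [int(str(c).split("_")[-1]) if str(c).split("_")[-1].isdigit() else k
               for k, c in enumerate(chan_cols)]
    elif dialect == "dams":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, start=1):
                parts = line.rstrip("\n").split("\t")
                if len(parts) <= n_meta_cols:
                    raise ValueError(f"{path}:{ln}: too few columns for DAMS dialect")
                hh, mm, _ss = parts[2].split(":")
                rows.append((parts[1], int(hh) * 60 + int(mm),
                             [int(v) for v in parts[n_meta_cols:]]))
        dates = sorted({r[0] for r in rows}, key=lambda d: [r[0] for r in rows].index(d))
        day_of = {d: i for i, d in enumerate(dates)}
        minutes = np.array([day_of[d] * MIN_PER_DAY + m for d, m, _ in rows], dtype=np.int64)
        counts_mat = np.array([r[2] for r in rows], dtype=np.int64).T
        ids = list(range(counts_mat.shape[0]))
    else:
        raise ValueError("dialect must be 'csv' or 'dams'")

    d = np.diff(minutes)
    if np.any(d <= 0):
        bad = int(np.flatnonzero(d <= 0)[0]) + 2
        raise ValueError(f"{path}: non-monotone timestamp at row {bad}")
    gaps = []
    if np.any(d > 1):
        full = np.arange(minutes[0], minutes[-1] + 1)
        filled = np.zeros((counts_mat.shape[0], len(full)), dtype=np.int64)
        idx = minutes - minutes[0]
        filled[:, idx] = counts_mat
        gaps = [int(m) for m in np.setdiff1d(full, minutes)]
        warnings.warn(f"{path}: {len(gaps)} missing minute(s) filled with 0 and flagged")
        counts_mat, minutes = filled, full
    return [
        ActivitySeries(fly_id=fid, start_min=int(minutes[0]), counts=row,
                       lights_on_h=lights_on_h, lights_off_h=lights_off_h,
                       constant_darkness=constant_darkness, gap_minutes=list(gaps))
        for fid, row in zip(ids, counts_mat)
    ]


def _complete_day_mask(series: ActivitySeries) -> np.ndarray:
    days = series.complete_days()
    if not days:
        raise ValueError("no complete day in series")
    abs_min = series.start_min + np.arange(len(series))
    day_idx = abs_min // MIN_PER_DAY
    return np.isin(day_idx, days)


def phase_summary(series: ActivitySeries, phase: str) -> float:
    """Mean beam breaks per minute over the 12 h phase, across complete days."""
    if series.constant_darkness:
        raise ValueError("phase summary requires a light schedule")
    if phase not in ("light", "dark"):
        raise ValueError("phase must be 'light' or 'dark'")
    mask = _complete_day_mask(series)
    in_phase = series.is_light() if phase == "light" else ~series.is_light()
    sel = mask & in_phase
    return float(np.mean(series.counts[sel]))


def detect_sleep(series: ActivitySeries, min_inactive_min: int = 5,
                 strict: bool = True) -> list[SleepBout]:
    """Maximal zero-count runs longer than 5 min (strictly, by default).

    With ``strict=True`` a run of exactly ``min_inactive_min`` minutes is NOT
    sleep ("longer than 5 min"); ``strict=False`` switches to the ≥
    convention.
    """
    if len(series) < min_inactive_min + 1:
        raise ValueError("series too short for sleep detection")
    zero = (series.counts == 0).astype(np.int8)
    t = np.diff(zero, prepend=0, append=0)
    starts = np.flatnonzero(t == 1)
    lengths = np.flatnonzero(t == -1) - starts
    keep = lengths > min_inactive_min if strict else lengths >= min_inactive_min
    return [SleepBout(int(s), int(ln)) for s, ln in zip(starts[keep], lengths[keep])]


def sleep_by_phase(series: ActivitySeries, bouts: Optional[list] = None) -> pd.DataFrame:
    """Per-day, per-phase sleep/awake minutes over complete days.

    A bout spanning a phase boundary is attributed minute by minute, i.e.
    split proportionally between the phases it covers.
    """
    if bouts is None:
        bouts = detect_sleep(series)
    asleep = np.zeros(len(series), dtype=bool)
    for b in bouts:
        asleep[b.start_min : b.end_min] = True
    abs_min = series.start_min + np.arange(len(series))
    day_idx = abs_min // MIN_PER_DAY
    light = series.is_light()
    rows = []
    for day in series.complete_days():
        in_day = day_idx == day
        for phase, sel in (("light", in_day & light), ("dark", in_day & ~light)):
            total = int(np.sum(sel))
            slept = int(np.sum(asleep & sel))
            rows.append({"day": day, "phase": phase, "sleep_min": slept,
                         "awake_min": total - slept, "total_min": total})
    return pd.DataFrame(rows, columns=["day", "phase", "sleep_min", "awake_min", "total_min"])


@dataclass(frozen=True)
class PeriodEstimate:
    """Circadian period estimate with its significance at the peak."""

    period_h: float
    statistic: float
    threshold: float
    significant: bool
    method: str
    periodogram: pd.DataFrame


def estimate_period(series: ActivitySeries, min_period_h: float = 16.0,
                    max_period_h: float = 32.0, step_h: float = 0.1,
                    method: str = "chi2", alpha: float = 0.01) -> PeriodEstimate:
    """Free-running period of a constant-darkness series.

    ``chi2``: Sokolove–Bushell chi-square periodogram on a 0.1 h grid; for
    each candidate period the series is folded and the between-column
    variance statistic Qp is referred to a chi-square with (columns − 1)
    degrees of freedom.  The reported period maximizes the excess of Qp over
    its significance line, which removes the trivial growth of Qp with the
    number of columns.  ``acf``: peak of the autocorrelation in the period
    window, with a three-point parabolic refinement.
    """
    if not series.constant_darkness:
        raise ValueError("period estimation expects a constant-darkness series")
    x = series.counts.astype(float)
    if len(x) < 3 * MIN_PER_DAY:
        raise ValueError("need at least 3 days of data")
    grand = float(np.mean(x))
    n = len(x)

    if method == "chi2":
        periods = np.round(np.arange(min_period_h, max_period_h + 1e-9, step_h) * 60).astype(int)
        denom = float(np.sum((x - grand) ** 2))
        qs, lines = [], []
        for p in periods:
            idx = np.arange(n) % p
            col_sum = np.bincount(idx, weights=x, minlength=p)
            col_n = np.bincount(idx, minlength=p).astype(float)
            col_mean = col_sum / col_n
            q = n * float(np.sum(col_n * (col_mean - grand) ** 2)) / denom if denom > 0 else 0.0
            qs.append(q)
            # Bonferroni over the candidate-period grid, so a rhythmless
            # series is called non-significant at the stated alpha overall
            lines.append(float(stats.chi2.ppf(1 - alpha / len(periods), p - 1)))
        qs, lines = np.array(qs), np.array(lines)
        k = int(np.argmax(qs - lines))
        pg = pd.DataFrame({"period_h": periods / 60.0, "statistic": qs, "threshold": lines})
        return PeriodEstimate(float(periods[k] / 60.0), float(qs[k]), float(lines[k]),
                              bool(qs[k] > lines[k]), "chi2", pg)

    if method == "acf":
        xc = x - grand
        lags = np.arange(int(min_period_h * 60), int(max_period_h * 60) + 1)
        var = float(np.dot(xc, xc))
        ac = np.array([np.dot(xc[:-l], xc[l:]) / var for l in lags])
        k = int(np.argmax(ac))
        lag = float(lags[k])
        if 0 < k < len(ac) - 1:  # parabolic refinement between minute lags
            y0, y1, y2 = ac[k - 1], ac[k], ac[k + 1]
            d = y0 - 2 * y1 + y2
            if d < 0:
                lag += 0.5 * (y0 - y2) / d
        # significance: large-sample null sd of the acf is 1/sqrt(n);
        # Bonferroni over the examined lags
        thr = float(stats.norm.ppf(1 - alpha / len(lags)) / np.sqrt(n))
        pg = pd.DataFrame({"period_h": lags / 60.0, "statistic": ac,
                           "threshold": np.full(len(ac), thr)})
        return PeriodEstimate(lag / 60.0, float(ac[k]), thr, bool(ac[k] > thr), "acf", pg)

    raise ValueError("method must be 'chi2' or 'acf'")
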