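"""Post-release events: the first dive, fast starts, and inactive days.

The first dive is the initial excursion deeper than 10 m lasting at least
20 s before returning above 10 m; its duration scales with fight time.
Fast starts are brief acceleration bursts defined as VeDBA strictly above
the 99th percentile of the entire deployment; days with less than 1 % of
time in fast starts are "inactive".  Events spanning midnight are split
across days so daily percentages account every second exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .accel import running_mean

__all__ = [
    "temperature_correct_depth",
    "smooth_depth",
    "detect_first_dive",
    "fast_start_threshold",
    "detect_fast_starts",
    "inactive_days",
    "DiveEvent",
    "FastStartSummary",
]

SECONDS_PER_DAY = 86400.0


@dataclass
class DiveEvent:
    start_s: float          # seconds since release
    end_s: float
    duration_s: float
    max_depth_m: float


@dataclass
class FastStartSummary:
    threshold_g: float
    events: list            # (start_s, duration_s) tuples
    percent_per_day: np.ndarray
    seconds_observed_per_day: np.ndarray
    inactive: np.ndarray = field(default=None)


def temperature_correct_depth(depth, temp, coeff_m_per_degc: float = 0.0,
                              ref_temp_degc: float = 15.0) -> np.ndarray:
    """Linear temperature correction: depth - coeff * (temp - ref).

    The published processing names a temperature correction without stating
    its model; the default coefficient of 0 is the identity, with the hook
    calibrated per tag when metadata supplies a coefficient.
    """
    depth = np.asarray(depth, dtype=float)
    temp = np.asarray(temp, dtype=float)
    return depth - coeff_m_per_degc * (temp - ref_temp_degc)


def smooth_depth(depth, fs: float, window_s: float = 10.0) -> np.ndarray:
    """10-s centered running mean, shrinking at the edges."""
    return running_mean(np.asarray(depth, dtype=float),
                        int(round(window_s * fs)))


def _runs_above(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is exclusive."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return []
    d = np.diff(m.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.concatenate(([0], starts))
    if m[-1]:
        stops = np.concatenate((stops, [len(m)]))
    return list(zip(starts, stops))


def detect_first_dive(depth, fs: float, threshold_m: float = 10.0,
                      min_duration_s: float = 20.0) -> DiveEvent | None:
    """First maximal run deeper than ``threshold_m`` lasting >= ``min_duration_s``.

    The depth series must start at release.  Returns ``None`` when no run
    qualifies.  Idempotent under re-smoothing with the same window (the run
    boundaries are where the smoothed trace crosses the threshold).
    """
    depth = np.asarray(depth, dtype=float)
    mask = np.where(np.isfinite(depth), depth > threshold_m, False)
    for start, stop in _runs_above(mask):
        dur = (stop - start) / fs
        if dur >= min_duration_s:
            return DiveEvent(start_s=start / fs, end_s=stop / fs,
                             duration_s=dur,
                             max_depth_m=float(np.nanmax(depth[start:stop])))
    return None


def fast_start_threshold(vedba, q: float = 0.99) -> float:
    """Empirical quantile (linear interpolation) of all non-missing VeDBA."""
    v = np.asarray(vedba, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite VeDBA samples")
    return float(np.quantile(v, q))


def detect_fast_starts(vedba, fs: float, threshold: float,
                       inactive_frac: float = 0.01) -> FastStartSummary:
    """Maximal runs of VeDBA strictly above the threshold.

    "Above the 99th percentile" is read as strictly greater, so a constant
    series produces no events.  Per-day percent time counts event seconds
    within each release-aligned day over seconds observed (non-missing) that
    day; events spanning midnight are split.
    """
    v = np.asarray(vedba, dtype=float)
    ok = np.isfinite(v)
    mask = np.where(ok, v > threshold, False)
    events = [(start / fs, (stop - start) / fs)
              for start, stop in _runs_above(mask)]

    n_days = int(np.ceil(len(v) / fs / SECONDS_PER_DAY))
    t = np.arange(len(v)) / fs
    day = np.minimum((t // SECONDS_PER_DAY).astype(int), n_days - 1)
    obs_sec = np.bincount(day[ok], minlength=n_days) / fs
    ev_sec = np.bincount(day[mask], minlength=n_days) / fs
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(obs_sec > 0, 100.0 * ev_sec / obs_sec, np.nan)
    summary = FastStartSummary(
        threshold_g=float(threshold), events=events,
        percent_per_day=percent, seconds_observed_per_day=obs_sec)
    summary.inactive, _ = inactive_days(percent, cutoff_percent=100 * inactive_frac)
    return summary


def inactive_days(percent_per_day, cutoff_percent: float = 1.0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Flag days below the fast-start time cutoff; count them per 7-day week.

    Returns ``(flags, weekly_counts)`` with weeks release-aligned (days 1-7,
    8-14, ...).  Days with missing percent are not flagged and not counted.
    """
    p = np.asarray(percent_per_day, dtype=float)
    flags = np.where(np.isfinite(p), p < cutoff_percent, False)
    n_weeks = int(np.ceil(len(p) / 7))
    week = np.arange(len(p)) // 7
    counts = np.bincount(week[flags], minlength=n_weeks)
    return flags, counts
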