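"""Tri-axial acceleration processing.

Turns raw tag-frame acceleration into calibrated body-frame signals, splits
static (gravity/posture) from dynamic (movement) components with a running
mean, computes VeDBA (the per-sample Euclidean norm of the dynamic triplet),
and summarises activity into release-aligned hourly means with a plateau
(stabilisation) detector for the immediate post-release burst.

Running means use shrinking (partial) windows at the edges rather than
reflection or zero padding: the most heavily analysed instant is the release
itself, and padding would fabricate data there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.transform import Rotation

from .io import SensorSeries

__all__ = [
    "running_mean",
    "decimate_to_20hz",
    "calibrate_orientation",
    "split_static_dynamic",
    "vedba",
    "smooth_vedba",
    "downsample_to",
    "hourly_means",
    "plateau_time",
    "burst_ratio",
    "ActivitySeries",
    "activity_series",
]

AXES = ("ax", "ay", "az")  # x = surge (anterior), y = sway (lateral), z = heave


def running_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Centered running mean with shrinking windows at the edges.

    NaNs are ignored inside the window; an all-NaN window yields NaN.  For
    even ``window`` the extra sample is taken from the past (causal side).
    """
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    n = len(x)
    ok = np.isfinite(x)
    vals = np.where(ok, x, 0.0)
    csum = np.concatenate(([0.0], np.cumsum(vals)))
    ccnt = np.concatenate(([0], np.cumsum(ok.astype(int))))
    half_lo = window // 2
    half_hi = window - half_lo - 1
    i = np.arange(n)
    lo = np.maximum(i - half_lo, 0)
    hi = np.minimum(i + half_hi, n - 1)
    cnt = ccnt[hi + 1] - ccnt[lo]
    with np.errstate(invalid="ignore"):
        out = (csum[hi + 1] - csum[lo]) / cnt
    out[cnt == 0] = np.nan
    return out


def decimate_to_20hz(series: SensorSeries) -> SensorSeries:
    """Decimate a 30 Hz series to 20 Hz by linear interpolation.

    A series already at 20 Hz passes through unchanged; any other rate is an
    error (the high-rate record classes are 20 or 30 Hz only).
    """
    if abs(series.fs - 20.0) < 1e-9:
        return series
    if abs(series.fs - 30.0) > 1e-9:
        raise ValueError(f"decimate_to_20hz expects 30 Hz input, got {series.fs} Hz")
    t_old = series.seconds_since_start()
    duration = len(series) / series.fs
    n_new = int(np.floor(duration * 20.0))
    t_new = np.arange(n_new) / 20.0
    channels = {}
    for name, x in series.channels.items():
        channels[name] = np.interp(t_new, t_old, x)
    return SensorSeries(series.start_epoch, 20.0, channels, dict(series.meta))


def calibrate_orientation(series: SensorSeries,
                          roll: float = 0.0,
                          pitch: float = 0.0,
                          yaw: float = 0.0) -> SensorSeries:
    """Rotate the acceleration triplet from tag frame to fish frame.

    Angles are degrees, composed intrinsically in z-y-x order
    (yaw about heave, then pitch about sway, then roll about surge),
    right-handed.  Per-sample vector norms are preserved exactly.
    """
    for a in (roll, pitch, yaw):
        if not np.isfinite(a):
            raise ValueError("calibration angles must be finite")
    rot = Rotation.from_euler("ZYX", [yaw, pitch, roll], degrees=True)
    xyz = np.column_stack([series[a] for a in AXES])
    ok = np.all(np.isfinite(xyz), axis=1)
    out = np.full_like(xyz, np.nan)
    out[ok] = rot.apply(xyz[ok])
    channels = dict(series.channels)
    for j, a in enumerate(AXES):
        channels[a] = out[:, j]
    return SensorSeries(series.start_epoch, series.fs, channels, dict(series.meta))


def split_static_dynamic(series: SensorSeries, window_s: float = 2.0
                         ) -> tuple[dict, dict]:
    """Split acceleration into static and dynamic triplets.

    Static = centered running mean of each axis over ``window_s`` (shrinking
    at the edges); dynamic = raw - static, exactly, per axis and sample.
    """
    window = int(round(window_s * series.fs))
    if window < 1:
        raise ValueError(
            f"window {window_s}s holds no sample at fs={series.fs} Hz")
    static, dynamic = {}, {}
    for a in AXES:
        s = running_mean(series[a], window)
        static[a] = s
        dynamic[a] = series[a] - s
    return static, dynamic


def vedba(dynamic: dict) -> np.ndarray:
    """Vectorial Dynamic Body Acceleration: per-sample norm of the dynamic triplet."""
    return np.sqrt(sum(np.asarray(dynamic[a], dtype=float) ** 2 for a in AXES))


def smooth_vedba(v: np.ndarray, fs: float, window_s: float = 10.0) -> np.ndarray:
    """10-s (default) centered running mean of VeDBA, shrinking at edges."""
    return running_mean(v, int(round(window_s * fs)))


def downsample_to(series: SensorSeries, target_fs: float = 0.2) -> SensorSeries:
    """Nearest-sample decimation onto the target grid.

    Mimics how a low-rate tag samples: an instantaneous reading every
    ``1/target_fs`` seconds, not a block average.
    """
    if target_fs > series.fs:
        raise ValueError("cannot downsample to a higher rate")
    n_new = int(np.floor(series.duration_s * target_fs))
    idx = np.round(np.arange(n_new) / target_fs * series.fs).astype(int)
    idx = np.minimum(idx, len(series) - 1)
    channels = {k: v[idx] for k, v in series.channels.items()}
    return SensorSeries(series.start_epoch, target_fs, channels, dict(series.meta))


# ---------------------------------------------------------------------------
# hourly summaries and the plateau detector
# ---------------------------------------------------------------------------

@dataclass
class ActivitySeries:
    """Derived activity channels at the source sampling rate."""

    fs: float
    vedba: np.ndarray
    vedba_smooth: np.ndarray
    static: dict
    dynamic: dict


def activity_series(series: SensorSeries,
                    static_window_s: float = 2.0,
                    vedba_smooth_s: float = 10.0) -> ActivitySeries:
    """Raw triplet -> static/dynamic split -> VeDBA -> smoothed VeDBA."""
    static, dynamic = split_static_dynamic(series, static_window_s)
    v = vedba(dynamic)
    return ActivitySeries(
        fs=series.fs,
        vedba=v,
        vedba_smooth=smooth_vedba(v, series.fs, vedba_smooth_s),
        static=static,
        dynamic=dynamic,
    )


def hourly_means(values: np.ndarray, fs: float, horizon_h: int = 24,
                 offset_s: float = 0.0) -> pd.DataFrame:
    """Release-aligned hourly means.

    Hour ``h`` (1-based) covers ``[(h-1)*3600, h*3600)`` seconds after
    release.  ``offset_s`` shifts the series start relative to release.
    Returns a frame with columns ``hour`` (1..horizon_h), ``mean`` and
    ``n_samples``; empty bins report NaN means.
    """
    values = np.asarray(values, dtype=float)
    t = offset_s + np.arange(len(values)) / fs
    hour = np.floor(t / 3600.0).astype(int)  # 0-based bin
    keep = (hour >= 0) & (hour < horizon_h) & np.isfinite(values)
    sums = np.bincount(hour[keep], weights=values[keep], minlength=horizon_h)
    cnts = np.bincount(hour[keep], minlength=horizon_h)
    with np.errstate(invalid="ignore"):
        means = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.DataFrame({
        "hour": np.arange(1, horizon_h + 1),
        "mean": means[:horizon_h],
        "n_samples": cnts[:horizon_h],
    })


def burst_ratio(hourly: pd.DataFrame) -> float:
    """First-hour mean over the mean of hours 2..24 (post-release activity burst)."""
    m = hourly.set_index("hour")["mean"]
    tail = m.loc[2:24].dropna()
    if not np.isfinite(m.get(1, np.nan)) or tail.empty:
        return np.nan
    return float(m.loc[1] / tail.mean())


def _exp_decay(h, A, k, C):
    return A * np.exp(-k * h) + C


def plateau_time(hourly: pd.DataFrame, frac: float = 0.05) -> int:
    """Hour at which an activity metric has stabilised (right-sided asymptote).

    Fits ``y(h) = A exp(-k h) + C`` to the first-24-h hourly means by least
    squares; the plateau hour is the smallest integer ``h`` with
    ``A exp(-k h) <= frac * A``, i.e. ``ceil(ln(1/frac) / k)``.  If the fit
    fails or decays the wrong way (k <= 0 or A <= 0), falls back to the first
    hour whose mean and all later means lie within +/-10 % of the late
    (hours 18-24) mean.
    """
    m = hourly.set_index("hour")["mean"]
    h = m.index.to_numpy(dtype=float)
    y = m.to_numpy(dtype=float)
    ok = np.isfinite(y)
    if not ok.any():
        raise ValueError("all hourly means missing")
    if ok.sum() < 12:
        raise ValueError("plateau detection needs at least 12 hourly means")
    h, y = h[ok], y[ok]
    span = float(np.ptp(y))
    if span < 1e-12 * max(1.0, abs(float(np.mean(y)))):
        return 1  # constant: immediately at plateau
    try:
        (A, k, C), _ = curve_fit(
            _exp_decay, h, y,
            p0=[y[0] - y[-1], 0.5, y[-1]],
            bounds=([-np.inf, 1e-6, -np.inf], [np.inf, 10.0, np.inf]),
            maxfev=10000)
        if A > 0 and k > 0:
            hour = int(np.ceil(np.log(1.0 / frac) / k))
            return max(1, min(hour, int(h[-1])))
    except RuntimeError:
        pass
    # fallback: first hour from which everything stays near the late mean
    late = y[h >= 18]
    ref = float(np.mean(late)) if late.size else float(y[-1])
    tol = 0.10 * abs(ref) if ref != 0 else 0.10 * span
    for i in range(len(h)):
        if np.all(np.abs(y[i:] - ref) <= tol):
            return int(h[i])
    return int(h[-1])
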