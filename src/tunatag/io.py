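"""Domain types and CSV I/O for tag records.

Two record classes are handled: high-rate archival accelerometer tags
("G7-style", 20-30 Hz tri-axial acceleration with 1 Hz depth/temperature)
and low-rate pop-up archival tags ("MiniPAT-style", 0.2 Hz throughout).
CSV is the canonical on-disk format; there is no community standard for
these vendors' records.  All timestamps are UTC.

Missing samples are masked with NaN, never interpolated (the only stated
interpolation in the processing chain is the 30 -> 20 Hz decimation, which
lives in :mod:`tunatag.accel`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SensorSeries",
    "TagDeployment",
    "read_tag_series",
    "write_tag_series",
    "read_deployment_table",
    "packaged_deployment_table",
    "parse_tow_time",
    "fight_weight_regression",
]


@dataclass
class SensorSeries:
    """Uniformly sampled, equal-length named channels.

    Sample ``i`` is taken at ``start_epoch + i / fs`` seconds.  Channels are
    float arrays with NaN marking missing samples.
    """

    start_epoch: pd.Timestamp
    fs: float
    channels: dict[str, np.ndarray]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be strictly positive")
        self.start_epoch = pd.Timestamp(self.start_epoch)
        if self.start_epoch.tzinfo is None:
            self.start_epoch = self.start_epoch.tz_localize("UTC")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        self.channels = {k: np.asarray(v, dtype=float)
                         for k, v in self.channels.items()}

    def __len__(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration_s(self) -> float:
        return len(self) / self.fs

    def times(self) -> pd.DatetimeIndex:
        return self.start_epoch + pd.to_timedelta(
            np.arange(len(self)) / self.fs, unit="s")

    def seconds_since_start(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def __getitem__(self, channel: str) -> np.ndarray:
        return self.channels[channel]

    def with_channels(self, **extra: np.ndarray) -> "SensorSeries":
        merged = dict(self.channels)
        merged.update(extra)
        return SensorSeries(self.start_epoch, self.fs, merged, dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times(), **self.channels})


@dataclass
class TagDeployment:
    """Per-fish deployment metadata (one printed-table row)."""

    fish_id: str
    tag_type: str                    # "highres" (G7-style) or "lowres" (MiniPAT-style)
    accel_fs: float                  # Hz
    release_epoch: pd.Timestamp | None = None
    release_lat: float = math.nan
    release_lon: float = math.nan
    curved_fork_length: float = math.nan   # cm
    est_weight: float = math.nan           # kg
    fight_time: float = math.nan           # min
    handling_time: float = math.nan        # min
    tow_time: float = math.nan             # min (decimal)
    deployment_days: float = math.nan

    def __post_init__(self) -> None:
        if self.tag_type not in ("highres", "lowres"):
            raise ValueError(f"tag_type must be highres/lowres, got {self.tag_type!r}")
        if not self.accel_fs > 0:
            raise ValueError("accel_fs must be strictly positive")
        cfl = self.curved_fork_length
        if np.isfinite(cfl) and not (100.0 <= cfl <= 300.0):
            raise ValueError(f"curved fork length {cfl} cm outside [100, 300]")
        for name in ("fight_time", "handling_time", "tow_time"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"{name} must be non-negative or missing")


# ---------------------------------------------------------------------------
# tag-series CSV dialect: time, then numeric channel columns
# ---------------------------------------------------------------------------

def _parse_times(col: pd.Series) -> pd.DatetimeIndex:
    if np.issubdtype(col.dtype, np.number):
        t = pd.to_datetime(col.to_numpy(dtype=float), unit="s", utc=True)
    else:
        t = pd.to_datetime(col, utc=True, format="ISO8601")
    return pd.DatetimeIndex(t)


def read_tag_series(path: str | Path, schema: dict | None = None) -> SensorSeries:
    """Read a tag-series CSV into a :class:`SensorSeries`.

    The first column (or a column named ``time``) holds ISO-8601 timestamps or
    epoch seconds; remaining columns are numeric channels.  The sampling rate
    is inferred from the median time delta and, when ``schema`` supplies
    ``fs``, validated against it.  Rows falling off the uniform grid leave NaN
    gaps; more than 5 % irregular deltas is an error.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty series")
    time_col = "time" if "time" in df.columns else df.columns[0]
    t = _parse_times(df[time_col])
    if len(t) > 1:
        deltas = np.diff(t.view("int64")) / 1e9
        if np.any(deltas <= 0):
            i = int(np.argmax(deltas <= 0))
            raise ValueError(
                f"{path}: non-monotonic or duplicated timestamps at row {i + 1} "
                f"({t[i + 1]})")
        dt = float(np.median(deltas))
        fs = 1.0 / dt
        irregular = np.abs(deltas - dt) > 0.01 * dt
        if irregular.mean() > 0.05:
            bad = np.flatnonzero(irregular)
            raise ValueError(
                f"{path}: {irregular.mean():.0%} irregular sampling deltas "
                f"(rows {bad[0] + 1}..{bad[-1] + 1})")
    else:
        fs = float((schema or {}).get("fs", 1.0))
    if schema and "fs" in schema:
        want = float(schema["fs"])
        if abs(fs - want) > 0.01 * want:
            raise ValueError(f"{path}: inferred fs {fs:.4g} Hz != schema fs {want:.4g} Hz")
        fs = want
    # place samples on the uniform grid; off-grid gaps stay NaN
    n = int(round((t[-1] - t[0]).total_seconds() * fs)) + 1
    idx = np.round((t - t[0]).total_seconds() * fs).astype(int)
    channels = {}
    for col in df.columns:
        if col == time_col:
            continue
        vals = np.full(n, np.nan)
        vals[idx] = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        channels[col] = vals
    return SensorSeries(start_epoch=t[0], fs=fs, channels=channels)


def write_tag_series(series: SensorSeries, path: str | Path) -> None:
    df = series.to_frame()
    df["time"] = df["time"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# deployment table (printed-table dialect)
# ---------------------------------------------------------------------------

_MISSING = {"", "NR", "NA", "NAN", "NONE"}


def parse_tow_time(text, row_id: str = "?") -> float:
    """Parse an ``mm:ss`` tow-duration string to decimal minutes.

    ``NR``/``NA`` (no complete record) parse to NaN.  Bare numbers are taken
    as decimal minutes already.
    """
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return math.nan
    s = str(text).strip()
    if s.upper() in _MISSING:
        return math.nan
    if ":" in s:
        parts = s.split(":")
        try:
            mm, ss = (float(p) for p in parts)
        except ValueError:
            raise ValueError(f"row {row_id}: unparsable tow time {text!r}") from None
        if len(parts) != 2 or ss < 0 or ss >= 60:
            raise ValueError(f"row {row_id}: unparsable tow time {text!r}")
        return mm + ss / 60.0
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"row {row_id}: unparsable tow time {text!r}") from None


def _num(value) -> float:
    if value is None:
        return math.nan
    s = str(value).strip().replace(",", "")
    if s.upper() in _MISSING:
        return math.nan
    return float(s)


def read_deployment_table(path: str | Path) -> list[TagDeployment]:
    """Read a deployment-metadata table (one fish per row).

    Expected columns mirror the printed deployment table: fish id, tag type,
    sampling rate, deployment date/duration, curved fork length (cm),
    estimated weight (kg), fight time (min) and tow time (mm:ss, ``NR`` for
    no record).
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        fid = row["fish_id"].strip()
        fs = _num(row["sampling_hz"])
        raw_type = row.get("tag_type", "").strip().lower()
        tag_type = "highres" if (fs >= 5 or raw_type in ("g7", "highres")) else "lowres"
        release = None
        if row.get("deployment_date", ""):
            release = pd.Timestamp(row["deployment_date"], tz="UTC")
        out.append(TagDeployment(
            fish_id=fid,
            tag_type=tag_type,
            accel_fs=fs,
            release_epoch=release,
            release_lat=_num(row.get("release_lat", "")),
            release_lon=_num(row.get("release_lon", "")),
            curved_fork_length=_num(row.get("curved_fork_length_cm", "")),
            est_weight=_num(row.get("est_weight_kg", "")),
            fight_time=_num(row.get("fight_time_min", "")),
            handling_time=_num(row.get("handling_time_min", "")),
            tow_time=parse_tow_time(row.get("tow_time", ""), row_id=fid),
            deployment_days=_num(row.get("deployment_days", "")),
        ))
    return out


def packaged_deployment_table() -> list[TagDeployment]:
    """The packaged copy of the published 20-fish deployment table."""
    with resources.as_file(
            resources.files("tunatag.data") / "deployments_published.csv") as p:
        return read_deployment_table(p)


def fight_weight_regression(deployments: list[TagDeployment]):
    """OLS of fight time (min) on estimated weight (kg).

    Rows missing either field are dropped.  Returns a fitted statsmodels
    results object (``params`` = [intercept, slope], ``rsquared``).
    """
    import statsmodels.api as sm

    w = np.array([d.est_weight for d in deployments])
    f = np.array([d.fight_time for d in deployments])
    keep = np.isfinite(w) & np.isfinite(f)
    if keep.sum() < 3:
        raise ValueError("need at least 3 rows with both weight and fight time")
    X = sm.add_constant(w[keep])
    return sm.OLS(f[keep], X).fit()
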