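"""Diel behaviour and the daily-similarity permutation test.

Each day's behaviour is summarised as a 24-hour profile of mean activity
(VeDBA) or depth.  Over a 30-day block, every day is correlated (zero-lag
Pearson, pairwise-complete hours) against every other day; a day's "daily
similarity value" is the median of its 29 pairwise correlations.  Days are
ranked 1 (most dissimilar) to 30, the ranks are shuffled 10,000 times
without replacement, and a day is flagged dissimilar when its observed rank
falls at or below the empirical 5th percentile of its resampled null.  The
first post-release week is "altered" when at least one of days 1-7 is
flagged and the mean rank of days 1-7 lies in the lower half of the scale
(<= 15 by default; the strict "< 15" reading is config-switchable).

Diel classification per day or block uses Welch t-tests when both the day
and night samples pass a Shapiro-Wilk normality screen and Wilcoxon
rank-sum tests otherwise; behaviour is diurnal/nocturnal only when the test
is significant.  The return of diel behaviour is the first day opening a
7-day window holding at least 3 diurnal days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import solar

__all__ = [
    "day_night_partition",
    "classify_diel",
    "diel_return_day",
    "hourly_profiles",
    "daily_similarity",
    "rank_days",
    "permutation_null",
    "classify_altered_week",
    "similarity_analysis",
    "compare_across_phases",
    "DielDay",
    "SimilarityResult",
]

SECONDS_PER_DAY = 86400.0


# ---------------------------------------------------------------------------
# day/night partition and diel classification
# ---------------------------------------------------------------------------

def day_night_partition(times: pd.DatetimeIndex,
                        sun_times_by_date: dict | None = None,
                        lat: float | None = None, lon: float | None = None,
                        day_start_hour: float = 6.0,
                        day_end_hour: float = 18.0) -> np.ndarray:
    """Boolean day mask: True where a timestamp falls in [sunrise, sunset).

    Sunrise/sunset come from ``sun_times_by_date`` (date -> (rise, set)),
    are computed from ``lat``/``lon`` via the NOAA routine, or default to
    fixed clock-hour boundaries.  A date with no sunset (polar day) is
    labelled all day, with a logged warning.
    """
    times = pd.DatetimeIndex(times)
    if sun_times_by_date is None and lat is not None and lon is not None:
        sun_times_by_date = {
            d: solar.sun_times(d, lat, lon)
            for d in np.unique(times.normalize())}
    if sun_times_by_date is None:
        h = (times.hour + times.minute / 60 + times.second / 3600
             + times.microsecond / 3.6e9)
        return (h >= day_start_hour) & (h < day_end_hour)
    is_day = np.zeros(len(times), dtype=bool)
    dates = times.normalize()
    for d in np.unique(dates):
        sel = dates == d
        rise, sets = sun_times_by_date.get(pd.Timestamp(d), (None, None))
        if rise is None or sets is None:
            warnings.warn(f"{pd.Timestamp(d).date()}: no sunset — whole date "
                          "labelled day")
            is_day[sel] = True
            continue
        if rise >= sets:
            raise ValueError(f"{pd.Timestamp(d).date()}: sunrise not before sunset")
        t = times[sel]
        is_day[sel] = (t >= rise) & (t < sets)
    return is_day


@dataclass
class DielDay:
    date: object
    day_mean: float
    night_mean: float
    classification: str        # diurnal / nocturnal / neither
    test: str                  # welch / wilcoxon
    p_value: float


def classify_diel(day_values, night_values, alpha: float = 0.05
                  ) -> tuple[str, str, float]:
    """Classify as diurnal, nocturnal or neither.

    Both groups are screened for normality (Shapiro-Wilk at 0.05); if both
    pass, a Welch t-test compares the means, otherwise a Wilcoxon rank-sum
    test.  Significance plus a larger day (night) mean gives diurnal
    (nocturnal); a non-significant test is always "neither".
    """
    d = np.asarray(day_values, dtype=float)
    n = np.asarray(night_values, dtype=float)
    d, n = d[np.isfinite(d)], n[np.isfinite(n)]
    if len(d) < 3 or len(n) < 3:
        return "neither", "none", np.nan
    normal = True
    for g in (d, n):
        if np.ptp(g) == 0:
            normal = False
            break
        if stats.shapiro(g[:5000]).pvalue < 0.05:
            normal = False
            break
    if normal:
        test = "welch"
        p = float(stats.ttest_ind(d, n, equal_var=False).pvalue)
    else:
        test = "wilcoxon"
        p = float(stats.ranksums(d, n).pvalue)
    if not np.isfinite(p) or p >= alpha:
        return "neither", test, p
    return ("diurnal" if d.mean() > n.mean() else "nocturnal"), test, p


def diel_return_day(diurnal_flags, window_days: int = 7, min_days: int = 3
                    ) -> int | None:
    """Day (1-based) on which regular diel behaviour resumed.

    The earliest *diurnal* day opening a ``window_days`` window that holds
    at least ``min_days`` diurnal days.  Anchoring the window at a diurnal
    day reports the day the pattern actually resumed rather than a
    non-diurnal day that merely precedes a qualifying run.
    """
    f = np.asarray(diurnal_flags, dtype=bool)
    for d in range(0, len(f) - window_days + 1):
        if f[d] and f[d: d + window_days].sum() >= min_days:
            return d + 1
    return None


# ---------------------------------------------------------------------------
# hourly profiles and daily similarity
# ---------------------------------------------------------------------------

def hourly_profiles(values, fs: float, release_epoch, n_days: int
                    ) -> np.ndarray:
    """Per-day 24-vectors of clock-hour means, NaN where a bin is empty.

    Days are release-aligned (day 1 = the 24 h from release); bins are
    calendar clock hours of the sample timestamps.
    """
    v = np.asarray(values, dtype=float)
    release = pd.Timestamp(release_epoch)
    t = np.arange(len(v)) / fs
    day = (t // SECONDS_PER_DAY).astype(int)
    clock = ((release.hour * 3600 + release.minute * 60 + release.second + t)
             // 3600).astype(int) % 24
    ok = np.isfinite(v) & (day < n_days)
    flat = day[ok] * 24 + clock[ok]
    sums = np.bincount(flat, weights=v[ok], minlength=n_days * 24)
    cnts = np.bincount(flat, minlength=n_days * 24)
    with np.errstate(invalid="ignore"):
        prof = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return prof.reshape(n_days, 24)


def daily_similarity(profiles: np.ndarray, min_common_hours: int = 3
                     ) -> np.ndarray:
    """Median pairwise zero-lag Pearson correlation per day.

    For each ordered pair of distinct days, the correlation is computed over
    their common non-missing hours; pairs with fewer than
    ``min_common_hours`` common hours or a constant profile are excluded.
    A day with every pair excluded gets NaN (and a warning).
    """
    P = np.asarray(profiles, dtype=float)
    n = P.shape[0]
    if n < 2:
        raise ValueError("need at least 2 daily profiles")
    corr = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            ok = np.isfinite(P[i]) & np.isfinite(P[j])
            if ok.sum() < min_common_hours:
                continue
            a, b = P[i, ok], P[j, ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            corr[i, j] = corr[j, i] = r
    values = np.full(n, np.nan)
    for i in range(n):
        row = corr[i, np.arange(n) != i]
        row = row[np.isfinite(row)]
        if row.size:
            values[i] = np.median(row)
        else:
            warnings.warn(f"day {i + 1}: all similarity pairs excluded")
    return values


def rank_days(values) -> np.ndarray:
    """Rank similarity values 1 (lowest = most dissimilar) upward.

    Ties break by earlier day.  Missing values get NaN ranks and do not
    consume a rank.
    """
    v = np.asarray(values, dtype=float)
    ok = np.isfinite(v)
    idx = np.flatnonzero(ok)
    order = idx[np.lexsort((idx, v[idx]))]
    ranks = np.full(len(v), np.nan)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def permutation_null(ranks, n_perm: int = 10000, window_days: int = 7,
                     seed: int | None = 0, q: float = 0.05,
                     inclusive: bool = True
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-day rank thresholds from shuffling, and the flagged-day set.

    The observed ranks are shuffled ``n_perm`` times without replacement;
    each day position accumulates a null distribution of resampled ranks,
    and a day is flagged when its observed rank is at or below (``inclusive``)
    the empirical ``q`` quantile of its null.  ``window_days`` is kept for
    interface symmetry: the first seven positions represent days 1-7, but
    thresholds and flags are reported for every day.
    """
    r = np.asarray(ranks, dtype=float)
    ok = np.isfinite(r)
    if n_perm < 1000:
        warnings.warn("n_perm < 1000 gives unstable null quantiles")
    rng = np.random.default_rng(seed)
    pool = r[ok]
    perms = rng.permuted(np.tile(pool, (n_perm, 1)), axis=1)
    thr_ok = np.quantile(perms, q, axis=0, method="inverted_cdf")
    thresholds = np.full(len(r), np.nan)
    thresholds[ok] = thr_ok
    if inclusive:
        flagged = np.where(ok, r <= thresholds, False)
    else:
        flagged = np.where(ok, r < thresholds, False)
    return thresholds, flagged


def classify_altered_week(flagged, ranks, window_days: int = 7,
                          rank_mean_cutoff: float = 15.0,
                          inclusive: bool = True) -> bool:
    """Altered first week: a flagged day within days 1-7 AND a low mean rank.

    The mean rank of days 1-7 must fall in the lower half of the 1-30 scale
    (<= 15 with the default inclusive reading, < 15 with the strict one).
    """
    f = np.asarray(flagged, dtype=bool)[:window_days]
    r = np.asarray(ranks, dtype=float)[:window_days]
    mean_rank = float(np.nanmean(r))
    low = mean_rank <= rank_mean_cutoff if inclusive else mean_rank < rank_mean_cutoff
    return bool(f.any() and low)


@dataclass
class SimilarityResult:
    """Daily-similarity test output for one fish and one 30-day block."""

    values: np.ndarray              # similarity value per day, in [-1, 1]
    ranks: np.ndarray               # 1 = most dissimilar
    thresholds: np.ndarray          # per-day null 5th-percentile rank
    flagged: np.ndarray             # dissimilar-day mask
    mean_rank_first_week: float
    altered_week: bool
    meta: dict = field(default_factory=dict)

    @property
    def flagged_days(self) -> list[int]:
        return list(np.flatnonzero(self.flagged) + 1)

    def to_row(self) -> dict:
        v = self.values[np.isfinite(self.values)]
        return {
            "corr_min": float(v.min()) if v.size else np.nan,
            "corr_max": float(v.max()) if v.size else np.nan,
            "dissimilar_days": ";".join(map(str, self.flagged_days)),
            "mean_rank_days_1_7": self.mean_rank_first_week,
            "altered_first_week": self.altered_week,
        }


def similarity_analysis(profiles: np.ndarray, n_perm: int = 10000,
                        seed: int | None = 0, q: float = 0.05,
                        window_days: int = 7,
                        rank_mean_cutoff: float = 15.0,
                        rank_mean_inclusive: bool = True,
                        flag_inclusive: bool = True,
                        min_common_hours: int = 3) -> SimilarityResult:
    """Full similarity pipeline: profiles -> values -> ranks -> null -> verdict."""
    values = daily_similarity(profiles, min_common_hours=min_common_hours)
    ranks = rank_days(values)
    thresholds, flagged = permutation_null(
        ranks, n_perm=n_perm, window_days=window_days, seed=seed, q=q,
        inclusive=flag_inclusive)
    mean_rank = float(np.nanmean(ranks[:window_days]))
    altered = classify_altered_week(
        flagged, ranks, window_days=window_days,
        rank_mean_cutoff=rank_mean_cutoff, inclusive=rank_mean_inclusive)
    return SimilarityResult(values=values, ranks=ranks, thresholds=thresholds,
                            flagged=flagged, mean_rank_first_week=mean_rank,
                            altered_week=altered)


def compare_across_phases(daily_means, dates) -> tuple[float, float]:
    """Kruskal-Wallis comparison of a daily metric across the four moon phases."""
    m = np.asarray(daily_means, dtype=float)
    phases = np.array([solar.lunar_phase(d) for d in dates])
    groups = [m[(phases == ph) & np.isfinite(m)]
              for ph in solar.PHASE_NAMES]
    groups = [g for g in groups if g.size >= 2]
    if len(groups) < 2:
        raise ValueError("need at least two moon-phase groups with data")
    H, p = stats.kruskal(*groups)
    return float(H), float(p)
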