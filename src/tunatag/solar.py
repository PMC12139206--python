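"""Solar and lunar timing for diel analyses.

Sunrise/sunset follow the NOAA solar-position algorithm (zenith 90.833 deg,
i.e. refraction plus the solar radius); lunar phase is the synodic-cycle
fraction measured from a reference new moon, adequate to the day-level
precision these analyses need (the true synodic anomaly is < +/-0.7 d).
"""

from __future__ import annotations

import math

import pandas as pd

__all__ = ["sun_times", "lunar_phase_angle", "lunar_phase"]

SYNODIC_DAYS = 29.530588853
# reference new moon: 2000-01-06 18:14 UTC
_NEW_MOON_EPOCH = pd.Timestamp("2000-01-06T18:14:00", tz="UTC")

PHASE_NAMES = ("new", "waxing", "full", "waning")


def _julian_day(ts: pd.Timestamp) -> float:
    return ts.to_julian_date()


def _sun_geometry(jd: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at a Julian day."""
    jc = (jd - 2451545.0) / 36525.0
    L0 = (280.46646 + jc * (36000.76983 + 0.0003032 * jc)) % 360.0
    M = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    e = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    Mr = math.radians(M)
    C = (math.sin(Mr) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
         + math.sin(2 * Mr) * (0.019993 - 0.000101 * jc)
         + math.sin(3 * Mr) * 0.000289)
    true_long = L0 + C
    omega = math.radians(125.04 - 1934.136 * jc)
    lam = math.radians(true_long - 0.00569 - 0.00478 * math.sin(omega))
    eps0 = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059
                    - 0.001813 * jc))) / 60.0) / 60.0
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))
    decl = math.degrees(math.asin(math.sin(eps) * math.sin(lam)))
    y = math.tan(eps / 2.0) ** 2
    L0r = math.radians(L0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * L0r) - 2 * e * math.sin(Mr)
        + 4 * e * y * math.sin(Mr) * math.cos(2 * L0r)
        - 0.5 * y * y * math.sin(4 * L0r)
        - 1.25 * e * e * math.sin(2 * Mr))
    return decl, eot


def sun_times(date, lat: float, lon: float
              ) -> tuple[pd.Timestamp | None, pd.Timestamp | None]:
    """UTC sunrise and sunset for a calendar date and position.

    Returns ``(None, None)`` under polar day/night (the sun never crosses
    the horizon).  Longitude is positive east.
    """
    day = pd.Timestamp(date)
    if day.tzinfo is None:
        day = day.tz_localize("UTC")
    noon_guess = day.normalize() + pd.Timedelta(hours=12)
    decl, eot = _sun_geometry(_julian_day(noon_guess))
    latr, declr = math.radians(lat), math.radians(decl)
    cos_ha = (math.cos(math.radians(90.833))
              / (math.cos(latr) * math.cos(declr))
              - math.tan(latr) * math.tan(declr))
    if not -1.0 <= cos_ha <= 1.0:
        return None, None
    ha_deg = math.degrees(math.acos(cos_ha))
    noon_min = 720.0 - 4.0 * lon - eot
    rise = day.normalize() + pd.Timedelta(minutes=noon_min - 4.0 * ha_deg)
    sets = day.normalize() + pd.Timedelta(minutes=noon_min + 4.0 * ha_deg)
    return rise, sets


def lunar_phase_angle(date) -> float:
    """Phase angle in degrees: 0 = new, 90 = first quarter, 180 = full."""
    ts = pd.Timestamp(date)
    if ts.tzinfo is None:
        ts = ts.tz_localize("UTC")
    age = (ts - _NEW_MOON_EPOCH).total_seconds() / 86400.0
    return float((age % SYNODIC_DAYS) / SYNODIC_DAYS * 360.0)


def lunar_phase(date) -> str:
    """Four-class synodic phase: new / waxing / full / waning.

    Class boundaries at 45/135/225/315 degrees of phase angle.
    """
    ang = lunar_phase_angle(date)
    if ang < 45.0 or ang >= 315.0:
        return "new"
    if ang < 135.0:
        return "waxing"
    if ang < 225.0:
        return "full"
    return "waning"
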