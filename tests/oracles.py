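"""Independent oracles used by the test suite.

These deliberately re-derive quantities through different algorithms or
brute-force constructions than the package uses, so agreement is evidence
of correctness rather than repetition.
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

import numpy as np


def julian_day(dt_utc: datetime) -> float:
    y, m = dt_utc.year, dt_utc.month
    d = dt_utc.day + (dt_utc.hour + dt_utc.minute / 60
                      + (dt_utc.second + dt_utc.microsecond / 1e6) / 3600) / 24
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def psa_solar_position(latitude: float, longitude: float,
                       timestamp: datetime) -> tuple[float, float]:
    """PSA solar ephemeris (Blanco-Muriel et al. 2001): an algorithm
    independent of the Astronomical Almanac formulation in the package.

    Returns (zenith, azimuth-from-north-clockwise) in degrees, without
    refraction but with the algorithm's parallax correction.
    """
    utc = timestamp.astimezone(timezone.utc)
    n = julian_day(utc) - 2451545.0
    hour = utc.hour + utc.minute / 60 + (utc.second + utc.microsecond / 1e6) / 3600
    omega = 2.1429 - 0.0010394594 * n
    mean_long = 4.8950630 + 0.017202791698 * n
    mean_anom = 6.2400600 + 0.0172019699 * n
    ecl_long = (mean_long + 0.03341607 * math.sin(mean_anom)
                + 0.00034894 * math.sin(2 * mean_anom)
                - 0.0001134 - 0.0000203 * math.sin(omega))
    obliquity = 0.4090928 - 6.2140e-9 * n + 0.0000396 * math.cos(omega)
    ra = math.atan2(math.cos(obliquity) * math.sin(ecl_long), math.cos(ecl_long))
    ra %= 2 * math.pi
    dec = math.asin(math.sin(obliquity) * math.sin(ecl_long))
    gmst = 6.6974243242 + 0.0657098283 * n + hour
    lmst = math.radians(gmst * 15 + longitude)
    ha = lmst - ra
    lat = math.radians(latitude)
    zen = math.acos(math.cos(lat) * math.cos(ha) * math.cos(dec)
                    + math.sin(dec) * math.sin(lat))
    az = math.atan2(-math.sin(ha),
                    math.tan(dec) * math.cos(lat) - math.sin(lat) * math.cos(ha))
    zen += (6371.01 / 149597890.0) * math.sin(zen)  # parallax
    return math.degrees(zen), math.degrees(az) % 360.0


def cone_average_linear(a: float, b: float, half_angle_rad: float) -> float:
    """Closed-form solid-angle average of f(α) = a + b·α over a cone of
    half-angle h about its axis:  a + b·(sin h − h·cos h)/(1 − cos h)."""
    h = half_angle_rad
    return a + b * (math.sin(h) - h * math.cos(h)) / (1.0 - math.cos(h))


def mad_outliers(levels: np.ndarray, multiple: float) -> np.ndarray:
    """Direct median-absolute-deviation outlier mask (brute force)."""
    med = np.median(levels)
    mad = np.median(np.abs(levels - med))
    if mad == 0:
        return levels != med
    return np.abs(levels - med) > multiple * mad
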