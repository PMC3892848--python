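"""Angular computation for goniometer sessions.

Covers the measurement scheme (the ordered set of view zenith/azimuth
positions the sensor sled visits), solar ephemeris, per-ring principal-plane
correction offsets, ground-footprint (GIFOV) geometry, and the hot-spot
feasibility check.

Conventions
-----------
* View azimuth ``phi_r`` is referenced to the solar principal plane:
  0° is the backward-scattering direction (sensor on the antisolar side of
  the target, sun behind the sensor), increasing clockwise when viewed from
  above.  Absolute (north-referenced) azimuths can be recovered by adding
  the solar azimuth at the reference instant.
* Solar azimuth is measured from geographic north, clockwise (east = 90°).
* All angles are degrees; all distances are metres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ViewGeometry",
    "SolarGeometry",
    "MeasurementScheme",
    "FootprintEllipse",
    "default_scheme",
    "solar_position",
    "solar_position_arrays",
    "principal_plane_correction",
    "footprint",
    "hotspot_possible",
    "min_solar_zenith_over_year",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ViewGeometry:
    """Sensor viewing direction.

    ``view_zenith`` in [0, 30] degrees; ``view_azimuth`` in [0, 360)
    referenced to the solar principal plane (0° = backward scatter).
    Nadir is ``view_zenith == 0`` with azimuth conventionally 0.
    """

    view_zenith: float
    view_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.view_zenith <= 90.0:
            raise ValueError(f"view_zenith out of range: {self.view_zenith}")
        object.__setattr__(self, "view_azimuth", self.view_azimuth % 360.0)


@dataclass(frozen=True)
class SolarGeometry:
    """Solar direction: zenith angle and north-referenced clockwise azimuth.

    ``sun_zenith`` > 90° means the sun is below the horizon (valid state,
    not an error).
    """

    sun_zenith: float
    sun_azimuth: float

    @property
    def elevation(self) -> float:
        return 90.0 - self.sun_zenith


@dataclass(frozen=True)
class MeasurementScheme:
    """Ordered rings of (zenith, azimuth positions), nadir first.

    ``rings`` maps ring zenith (deg) to its ordered azimuth list (deg,
    principal-plane referenced).  The nadir ring is the singleton
    ``(0.0, (0.0,))``.
    """

    rings: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        for zen, azs in self.rings:
            if len(set(azs)) != len(azs):
                raise ValueError(f"duplicate azimuths in ring {zen}")

    @property
    def n_positions(self) -> int:
        return sum(len(azs) for _, azs in self.rings)

    @property
    def ring_zeniths(self) -> tuple[float, ...]:
        return tuple(zen for zen, _ in self.rings)

    def positions(self) -> list[ViewGeometry]:
        """All positions in acquisition order (nadir, then ring by ring)."""
        out: list[ViewGeometry] = []
        for zen, azs in self.rings:
            out.extend(ViewGeometry(zen, az) for az in azs)
        return out

    def restricted(self, zeniths: Iterable[float]) -> "MeasurementScheme":
        keep = set(zeniths)
        return MeasurementScheme(tuple((z, a) for z, a in self.rings if z in keep))


@dataclass(frozen=True)
class FootprintEllipse:
    """Ground footprint of the conical sensor field of view.

    ``major_axis``/``minor_axis`` are full extents (m) of the ellipse the
    view cone cuts on a horizontal plane; ``center_offset`` is the distance
    (m) from the plot centre to the ellipse centre, along the view-azimuth
    ground direction (away from the sensor).
    """

    center_offset: float
    major_axis: float
    minor_axis: float

    def __post_init__(self) -> None:
        if not self.major_axis >= self.minor_axis > 0:
            raise ValueError("require major_axis >= minor_axis > 0")

    @property
    def area(self) -> float:
        return math.pi * self.major_axis * self.minor_axis / 4.0


# ---------------------------------------------------------------------------
# Measurement scheme
# ---------------------------------------------------------------------------

# Default azimuth layouts (principal-plane referenced).  The ring population
# is fixed (12 at 5°, 16 at 10/20/30°); the angles themselves are a
# configurable convention: symmetric about the principal plane (0°/180°),
# containing the principal and orthogonal planes, with spacing tightened
# toward 0°/180° where canopy anisotropy is strongest.
_AZ12: tuple[float, ...] = (
    0.0, 25.0, 55.0, 90.0, 125.0, 155.0,
    180.0, 205.0, 235.0, 270.0, 305.0, 335.0,
)
_AZ16: tuple[float, ...] = (
    0.0, 15.0, 35.0, 60.0, 90.0, 120.0, 145.0, 165.0,
    180.0, 195.0, 215.0, 240.0, 270.0, 300.0, 325.0, 345.0,
)


def default_scheme() -> MeasurementScheme:
    """The default 61-position hemisphere sampling scheme.

    Nadir, a 12-position ring at 5° view zenith, and 16-position rings at
    10°, 20° and 30°, with azimuth density increased around the solar
    principal plane.
    """
    return MeasurementScheme((
        (0.0, (0.0,)),
        (5.0, _AZ12),
        (10.0, _AZ16),
        (20.0, _AZ16),
        (30.0, _AZ16),
    ))


# ---------------------------------------------------------------------------
# Solar ephemeris (Michalsky 1988 / Astronomical Almanac algorithm)
# ---------------------------------------------------------------------------

def _julian_day(dt_utc: datetime) -> float:
    """Julian day from a UTC datetime (Fliegel-Van Flandern style)."""
    y, m = dt_utc.year, dt_utc.month
    frac = (dt_utc.hour + dt_utc.minute / 60.0
            + (dt_utc.second + dt_utc.microsecond / 1e6) / 3600.0) / 24.0
    d = dt_utc.day + frac
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def _to_utc(timestamp: datetime) -> datetime:
    if timestamp.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware (explicit UTC offset)")
    return timestamp.astimezone(timezone.utc)


def solar_position_arrays(
    latitude: float, longitude: float, jd: np.ndarray, hour_ut: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised solar zenith/azimuth (degrees) for Julian days + UT hours.

    Low-precision Astronomical Almanac ephemeris (Michalsky), accurate to
    ~0.01° over 1950-2050; atmospheric refraction is not applied.
    """
    n = jd - 2451545.0
    mean_long = (280.460 + 0.9856474 * n) % 360.0
    mean_anom = np.radians((357.528 + 0.9856003 * n) % 360.0)
    ecl_long = np.radians(
        (mean_long + 1.915 * np.sin(mean_anom) + 0.020 * np.sin(2.0 * mean_anom)) % 360.0
    )
    obliquity = np.radians(23.439 - 4.0e-7 * n)
    ra = np.arctan2(np.cos(obliquity) * np.sin(ecl_long), np.cos(ecl_long))
    dec = np.arcsin(np.sin(obliquity) * np.sin(ecl_long))
    gmst = (6.697375 + 0.0657098242 * n + hour_ut) % 24.0
    lmst = np.radians((gmst * 15.0 + longitude) % 360.0)
    ha = lmst - ra
    lat = math.radians(latitude)
    sin_el = np.sin(dec) * math.sin(lat) + np.cos(dec) * math.cos(lat) * np.cos(ha)
    zenith = 90.0 - np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))
    azimuth = np.degrees(
        np.arctan2(-np.sin(ha), np.tan(dec) * math.cos(lat) - math.sin(lat) * np.cos(ha))
    ) % 360.0
    return zenith, azimuth


def solar_position(latitude: float, longitude: float, timestamp: datetime) -> SolarGeometry:
    """Solar zenith/azimuth at a site and instant.

    Parameters
    ----------
    latitude, longitude : decimal degrees (east positive).
    timestamp : timezone-aware datetime.

    A pure function of its inputs; a sun below the horizon is returned as
    ``sun_zenith > 90``, not raised.
    """
    if abs(latitude) > 90.0:
        raise ValueError(f"|latitude| must be <= 90, got {latitude}")
    utc = _to_utc(timestamp)
    # Julian day at 0h UT plus the UT hour, as the algorithm expects.
    midnight = utc.replace(hour=0, minute=0, second=0, microsecond=0)
    jd0 = _julian_day(midnight)
    hour = (utc - midnight).total_seconds() / 3600.0
    zen, az = solar_position_arrays(
        latitude, longitude, np.asarray(jd0 + hour / 24.0), np.asarray(hour)
    )
    return SolarGeometry(float(zen), float(az))


def _angdiff(a: float, b: float) -> float:
    """Signed difference a - b wrapped to (-180, 180]."""
    d = (a - b) % 360.0
    return d - 360.0 if d > 180.0 else d


def principal_plane_correction(
    scheme: MeasurementScheme,
    start_time: datetime,
    latitude: float,
    longitude: float,
    ring_times: Sequence[datetime],
) -> list[float]:
    """Per-ring azimuth offsets that track the drifting principal plane.

    The scheme is aligned with the solar principal plane at ``start_time``;
    as the session progresses the sun's azimuth moves, so each ring
    (visited at ``ring_times[i]``) needs its azimuth zero rotated by the
    solar azimuth change accumulated since the start.  Returns one signed
    offset (degrees) per ring, in scheme order.
    """
    if len(ring_times) != len(scheme.rings):
        raise ValueError("need one ring time per ring")
    prev = start_time
    for t in ring_times:
        if t < prev:
            raise ValueError("ring times must be ordered and >= start_time")
        prev = t
    az0 = solar_position(latitude, longitude, start_time).sun_azimuth
    return [
        _angdiff(solar_position(latitude, longitude, t).sun_azimuth, az0)
        for t in ring_times
    ]


# ---------------------------------------------------------------------------
# GIFOV footprint
# ---------------------------------------------------------------------------

def footprint(view_zenith: float, slant_distance: float, ifov: float) -> FootprintEllipse:
    """Ground footprint ellipse from the edge-ray construction.

    The sensor sits ``slant_distance`` from the plot centre along the view
    direction; the cone of half-angle ``ifov/2`` about that direction is
    intersected with the horizontal ground plane.  The major extent is the
    distance between the ground hits of the rays at ``view_zenith ± ifov/2``;
    the minor extent is the cross-track width of the cone on the ground.
    """
    if slant_distance <= 0:
        raise ValueError("slant_distance must be positive")
    half = math.radians(ifov) / 2.0
    theta = math.radians(view_zenith)
    if not 0.0 <= view_zenith < 90.0 - math.degrees(half):
        raise ValueError("view zenith too close to grazing for this IFOV")
    height = slant_distance * math.cos(theta)  # sensor height above ground
    major = height * (math.tan(theta + half) - math.tan(theta - half))
    # Cross-track half-width: maximise the lateral ground coordinate of the
    # cone's boundary rays; the maximum is at boundary angle psi* with
    # cos(psi*) = tan(half)·tan(theta).
    cos_psi = math.tan(half) * math.tan(theta)
    sin_psi = math.sqrt(max(0.0, 1.0 - cos_psi * cos_psi))
    minor = 2.0 * height * math.sin(half) * sin_psi / (
        math.cos(half) * math.cos(theta) - math.sin(half) * cos_psi * math.sin(theta)
    )
    # Ellipse centre: midpoint of the along-track extent, relative to the
    # plot centre (which the cone axis hits at height·tan(theta)).
    mid = height * (math.tan(theta + half) + math.tan(theta - half)) / 2.0
    offset = mid - height * math.tan(theta)
    return FootprintEllipse(center_offset=offset, major_axis=major, minor_axis=minor)


# ---------------------------------------------------------------------------
# Hot spot
# ---------------------------------------------------------------------------

def hotspot_possible(max_view_zenith: float, min_sun_zenith: float) -> bool:
    """Whether the sensor can reach the hot-spot (sun-aligned) geometry.

    The hot spot needs the view direction to coincide with the illumination
    direction, which requires the solar zenith to be within the
    instrument's view-zenith range.
    """
    if not (0.0 <= max_view_zenith <= 90.0 and 0.0 <= min_sun_zenith <= 90.0):
        raise ValueError("angles must be in [0, 90]")
    return min_sun_zenith <= max_view_zenith


def min_solar_zenith_over_year(
    latitude: float,
    longitude: float = 0.0,
    year: int = 2012,
    step_minutes: float = 5.0,
) -> float:
    """Minimum solar zenith angle (deg) over one year of ephemeris samples."""
    start = datetime(year, 1, 1, tzinfo=timezone.utc)
    n_steps = int(366 * 24 * 60 / step_minutes)
    hours = np.arange(n_steps) * (step_minutes / 60.0)
    jd0 = _julian_day(start)
    jd = jd0 + hours / 24.0
    zen, _ = solar_position_arrays(latitude, longitude, jd, hours % 24.0)
    return float(zen.min())
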