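"""Topocentric solar position from the NOAA solar-calculator equations.

Implements the low-precision ephemeris of Meeus as adopted by the NOAA solar
calculator: geometric mean solar longitude/anomaly, equation of centre,
apparent longitude with nutation correction, corrected obliquity, declination
and the equation of time, then the hour angle for the requested instant and
site.  Accuracy is better than 0.1 degree between 1950 and 2100, well inside
the 0.5 degree needed for metre-scale shadow geometry.

Azimuth is measured clockwise from true north; elevation above the horizon.
Atmospheric refraction (NOAA's piecewise formula) is applied by default; it
matters only within a few degrees of the horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timezone

__all__ = ["SunPosition", "solar_position"]

_DEG = math.pi / 180.0


@dataclass(frozen=True)
class SunPosition:
    """Sun direction: azimuth (deg, clockwise from north) and elevation (deg)."""

    azimuth: float
    elevation: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.azimuth < 360.0:
            raise ValueError(f"azimuth must lie in [0, 360), got {self.azimuth!r}")
        if not -90.0 <= self.elevation <= 90.0:
            raise ValueError(f"elevation must lie in [-90, 90], got {self.elevation!r}")

    @property
    def direction(self) -> tuple[float, float, float]:
        """Unit vector toward the sun in a local ENU frame (x east, y north, z up)."""
        az, el = self.azimuth * _DEG, self.elevation * _DEG
        return (
            math.sin(az) * math.cos(el),
            math.cos(az) * math.cos(el),
            math.sin(el),
        )


def _julian_day(instant: datetime) -> float:
    t = instant.astimezone(timezone.utc)
    y, m = t.year, t.month
    day = (
        t.day
        + (t.hour + t.minute / 60.0 + (t.second + t.microsecond / 1e6) / 3600.0) / 24.0
    )
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + day + b - 1524.5


def _refraction_correction(elevation_deg: float) -> float:
    """NOAA atmospheric refraction correction, degrees, added to elevation."""
    e = elevation_deg
    if e > 85.0:
        return 0.0
    te = math.tan(e * _DEG)
    if e > 5.0:
        corr = 58.1 / te - 0.07 / te**3 + 0.000086 / te**5
    elif e > -0.575:
        corr = 1735.0 + e * (-518.2 + e * (103.4 + e * (-12.79 + e * 0.711)))
    else:
        corr = -20.774 / te
    return corr / 3600.0


def solar_position(
    site_latitude: float,
    site_longitude: float,
    instant: datetime,
    *,
    apply_refraction: bool = True,
) -> SunPosition:
    """Topocentric sun azimuth/elevation for a site and timezone-aware instant.

    Parameters
    ----------
    site_latitude, site_longitude
        Geographic coordinates in degrees; longitude positive east.
    instant
        Timezone-aware timestamp of the observation.  Naive timestamps are
        rejected: a wrong implicit zone would move the sun by tens of degrees.
    """
    if instant.tzinfo is None or instant.tzinfo.utcoffset(instant) is None:
        raise ValueError("instant must be timezone-aware (naive 'instant' given)")
    if not -90.0 <= site_latitude <= 90.0:
        raise ValueError(f"site_latitude out of range: {site_latitude!r}")
    if not -180.0 <= site_longitude <= 180.0:
        raise ValueError(f"site_longitude out of range: {site_longitude!r}")
    if not 1950 <= instant.year <= 2100:
        raise ValueError(f"instant year {instant.year} outside supported range 1950-2100")

    jd = _julian_day(instant)
    jc = (jd - 2451545.0) / 36525.0

    gml = (280.46646 + jc * (36000.76983 + jc * 0.0003032)) % 360.0
    gma = 357.52911 + jc * (35999.05029 - 0.0001537 * jc)
    ecc = 0.016708634 - jc * (0.000042037 + 0.0000001267 * jc)
    eq_ctr = (
        math.sin(gma * _DEG) * (1.914602 - jc * (0.004817 + 0.000014 * jc))
        + math.sin(2 * gma * _DEG) * (0.019993 - 0.000101 * jc)
        + math.sin(3 * gma * _DEG) * 0.000289
    )
    true_long = gml + eq_ctr
    omega = 125.04 - 1934.136 * jc
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega * _DEG)

    mean_obliq = 23.0 + (26.0 + (21.448 - jc * (46.815 + jc * (0.00059 - jc * 0.001813))) / 60.0) / 60.0
    obliq = mean_obliq + 0.00256 * math.cos(omega * _DEG)

    declination = math.asin(math.sin(obliq * _DEG) * math.sin(app_long * _DEG)) / _DEG

    var_y = math.tan(obliq / 2.0 * _DEG) ** 2
    eq_time_min = 4.0 / _DEG * (
        var_y * math.sin(2 * gml * _DEG)
        - 2.0 * ecc * math.sin(gma * _DEG)
        + 4.0 * ecc * var_y * math.sin(gma * _DEG) * math.cos(2 * gml * _DEG)
        - 0.5 * var_y**2 * math.sin(4 * gml * _DEG)
        - 1.25 * ecc**2 * math.sin(2 * gma * _DEG)
    )

    utc = instant.astimezone(timezone.utc)
    minutes_utc = utc.hour * 60.0 + utc.minute + (utc.second + utc.microsecond / 1e6) / 60.0
    true_solar_min = (minutes_utc + eq_time_min + 4.0 * site_longitude) % 1440.0
    hour_angle = true_solar_min / 4.0 - 180.0
    if hour_angle < -180.0:
        hour_angle += 360.0

    lat, dec, ha = site_latitude * _DEG, declination * _DEG, hour_angle * _DEG
    cos_zenith = math.sin(lat) * math.sin(dec) + math.cos(lat) * math.cos(dec) * math.cos(ha)
    cos_zenith = min(1.0, max(-1.0, cos_zenith))
    zenith = math.acos(cos_zenith) / _DEG
    elevation = 90.0 - zenith

    sin_zenith = math.sin(zenith * _DEG)
    if sin_zenith < 1e-9:
        azimuth = 0.0  # sun at the zenith: azimuth degenerate
    else:
        cos_az = (math.sin(lat) * cos_zenith - math.sin(dec)) / (math.cos(lat) * sin_zenith)
        cos_az = min(1.0, max(-1.0, cos_az))
        az = math.acos(cos_az) / _DEG
        azimuth = (az + 180.0) % 360.0 if hour_angle > 0 else (540.0 - az) % 360.0

    if apply_refraction:
        elevation = min(90.0, elevation + _refraction_correction(elevation))

    return SunPosition(azimuth=azimuth, elevation=elevation)
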