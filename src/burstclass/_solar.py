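"""Sunrise/sunset times from the standard NOAA solar-position approximation.

Accurate to a couple of minutes at mid-latitudes, which is ample for drawing
day/night boundaries on activity plots. All times are UTC.
"""
from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import numpy as np

_ZENITH_OFFICIAL = 90.833  # degrees; includes refraction + solar radius


def _solar_params(day: date):
    doy = day.timetuple().tm_yday
    gamma = 2.0 * np.pi / 365.0 * (doy - 1 + 0.5)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(gamma)
                       - 0.032077 * np.sin(gamma)
                       - 0.014615 * np.cos(2 * gamma)
                       - 0.040849 * np.sin(2 * gamma))
    decl = (0.006918 - 0.399912 * np.cos(gamma) + 0.070257 * np.sin(gamma)
            - 0.006758 * np.cos(2 * gamma) + 0.000907 * np.sin(2 * gamma)
            - 0.002697 * np.cos(3 * gamma) + 0.00148 * np.sin(3 * gamma))
    return eqtime, decl


def sunrise_sunset(day: date, lat: float, lon: float):
    """(sunrise, sunset) as UTC datetimes, or (None, None) for polar day/night."""
    eqtime, decl = _solar_params(day)
    lat_r = np.radians(lat)
    cos_ha = (np.cos(np.radians(_ZENITH_OFFICIAL))
              / (np.cos(lat_r) * np.cos(decl))
              - np.tan(lat_r) * np.tan(decl))
    if cos_ha < -1.0 or cos_ha > 1.0:
        return None, None
    ha = np.degrees(np.arccos(cos_ha))
    # minutes past UTC midnight
    rise_min = 720.0 - 4.0 * (lon + ha) - eqtime
    set_min = 720.0 - 4.0 * (lon - ha) - eqtime
    midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    return (midnight + timedelta(minutes=float(rise_min)),
            midnight + timedelta(minutes=float(set_min)))


def is_night(t: datetime, lat: float, lon: float) -> bool:
    """True when ``t`` (UTC) falls between that day's sunset and sunrise."""
    if t.tzinfo is None:
        t = t.replace(tzinfo=timezone.utc)
    rise, sset = sunrise_sunset(t.date(), lat, lon)
    if rise is None:
        # polar: no sunrise -> permanent night or permanent day; decide by
        # solar declination vs latitude sign
        _, decl = _solar_params(t.date())
        return (lat > 0) == (decl < 0)
    return t < rise or t > sset
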