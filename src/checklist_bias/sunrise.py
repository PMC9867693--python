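"""Local sunrise times from the NOAA solar-position approximation.

Checklist alignment keeps only events started between local sunrise and
four hours after it, so a sunrise provider is part of the filtering
contract.  The default provider implements the NOAA general solar
equations (fractional-year Fourier expansion for the equation of time and
solar declination, zenith 90.833 deg for refraction and the solar disc),
accurate to about +/-2 minutes at mid latitudes — well inside the 4-hour
window it gates.  A precomputed-sunrise column on the input overrides it
when present.
"""

from __future__ import annotations

import datetime as dt
import math

ZENITH_DEG = 90.833  # official sunrise: refraction + solar semi-diameter


def sunrise_utc_minutes(date: dt.date, latitude: float, longitude: float) -> float:
    """Minutes after 00:00 UTC of sunrise at (latitude, longitude) on ``date``.

    Raises ValueError in polar day/night where no sunrise exists.
    """
    day_of_year = date.timetuple().tm_yday
    # fractional year, radians (midday anchor is accurate enough at +/-2 min)
    gamma = 2.0 * math.pi / 365.0 * (day_of_year - 1 + 0.5)

    eqtime = 229.18 * (
        0.000075
        + 0.001868 * math.cos(gamma)
        - 0.032077 * math.sin(gamma)
        - 0.014615 * math.cos(2 * gamma)
        - 0.040849 * math.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * math.cos(gamma)
        + 0.070257 * math.sin(gamma)
        - 0.006758 * math.cos(2 * gamma)
        + 0.000907 * math.sin(2 * gamma)
        - 0.002697 * math.cos(3 * gamma)
        + 0.00148 * math.sin(3 * gamma)
    )

    lat = math.radians(latitude)
    cos_ha = (
        math.cos(math.radians(ZENITH_DEG)) / (math.cos(lat) * math.cos(decl))
        - math.tan(lat) * math.tan(decl)
    )
    if cos_ha < -1.0 or cos_ha > 1.0:
        raise ValueError(f"no sunrise at latitude {latitude} on {date}")
    ha_deg = math.degrees(math.acos(cos_ha))
    return 720.0 - 4.0 * (longitude + ha_deg) - eqtime


class NoaaSunriseProvider:
    """Callable (date, lat, lon) -> local sunrise as a datetime.time.

    ``utc_offset_hours`` is the fixed clock offset of the study region
    (default +8, Taiwan standard time; there is no daylight saving).
    """

    def __init__(self, utc_offset_hours: float = 8.0):
        self.utc_offset_hours = utc_offset_hours

    def __call__(self, date: dt.date, latitude: float, longitude: float) -> dt.time:
        minutes = sunrise_utc_minutes(date, latitude, longitude)
        seconds = round((minutes + self.utc_offset_hours * 60.0) * 60.0) % 86400
        hour, rem = divmod(seconds, 3600)
        minute, sec = divmod(rem, 60)
        return dt.time(hour, minute, sec)
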