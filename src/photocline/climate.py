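"""Civil-twilight photoperiods, annual photoperiod-temperature ellipses and
the predicted critical photoperiod (pCPP).

The pCPP of a locality is the day length, measured dawn-to-dusk at civil
twilight (sun center 6 degrees below the horizon), on the spring day when the
interpolated daily mean temperature rises through a fixed threshold (default
6.6 degC, a proxy for the onset of grass growth). Day length is a pure
function of latitude and date; the annual temperature cycle is anchored at
mid-month days and interpolated linearly in between, wrapping December to
January.
"""

from __future__ import annotations

import numpy as np

from .types import (
    ClimateEllipse,
    InputError,
    Locality,
    MonthlyTemperatureSeries,
    NoCrossingError,
    Pcpp,
)

DEFAULT_THRESHOLD_C = 6.6

#: Civil twilight: sun center 6 degrees below the geometric horizon.
CIVIL_DEPRESSION_DEG = 6.0

#: Mid-month anchor days of a 365-day year (Jan 15 .. Dec 15).
_MONTH_LEN = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_ANCHOR_DAYS = np.cumsum(_MONTH_LEN) - _MONTH_LEN + 15  # day 15 of each month


def solar_declination(day_of_year) -> float:
    """Solar declination (degrees) for a day of the 365-day year.

    Spencer-type Fourier series; accurate to ~0.3 degrees, which keeps the
    derived day lengths within about a minute. Accepts fractional days for
    internal interpolation; the public contract is day 1..365.
    """
    day = np.asarray(day_of_year, dtype=float)
    if np.any(day < 1.0) or np.any(day > 365.0):
        raise InputError("day_of_year must lie in [1, 365]")
    g = 2.0 * np.pi * (day - 1.0) / 365.0
    decl_rad = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    out = np.degrees(decl_rad)
    return float(out) if out.ndim == 0 else out


def civil_daylength(latitude: float, day_of_year) -> float:
    """Hours of light per 24 h between civil dawn and civil dusk.

    Uses the standard hour-angle formula at solar altitude -6 degrees
    (zenith 96). The hour-angle cosine is clamped to [-1, 1], so polar day
    yields 24 h and polar night 0 h.
    """
    if not -90.0 <= latitude <= 90.0:
        raise InputError(f"latitude {latitude} outside [-90, 90]")
    decl = np.radians(solar_declination(day_of_year))
    phi = np.radians(latitude)
    zenith = np.radians(90.0 + CIVIL_DEPRESSION_DEG)
    denom = np.cos(phi) * np.cos(decl)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos_h = (np.cos(zenith) - np.sin(phi) * np.sin(decl)) / denom
    cos_h = np.where(denom == 0.0, np.sign(-np.sin(phi) * np.sin(decl)), cos_h)
    cos_h = np.clip(cos_h, -1.0, 1.0)
    hours = 2.0 * np.degrees(np.arccos(cos_h)) / 15.0
    return float(hours) if np.ndim(hours) == 0 else hours


def interpolate_daily_temperature(series: MonthlyTemperatureSeries) -> np.ndarray:
    """365 daily temperatures from 12 monthly means.

    Periodic piecewise-linear interpolation through mid-month anchor days;
    by construction the daily extremes never exceed the monthly extremes.
    """
    temps = np.asarray(series.temps, dtype=float)
    # wrap one anchor on each side for Dec -> Jan periodicity
    xs = np.concatenate(([MONTH_ANCHOR_DAYS[-1] - 365.0], MONTH_ANCHOR_DAYS,
                         [MONTH_ANCHOR_DAYS[0] + 365.0]))
    ys = np.concatenate(([temps[-1]], temps, [temps[0]]))
    days = np.arange(1, 366, dtype=float)
    return np.interp(days, xs, ys)


def build_ellipse(loc: Locality, series: MonthlyTemperatureSeries) -> ClimateEllipse:
    """Daily (photoperiod, temperature) pairs for one locality."""
    if series.locality_id != loc.id:
        raise InputError(
            f"temperature series {series.locality_id!r} does not match "
            f"locality {loc.id!r}"
        )
    days = np.arange(1, 366)
    pp = civil_daylength(loc.latitude, days)
    tt = interpolate_daily_temperature(series)
    return ClimateEllipse(locality_id=loc.id, days=days,
                          photoperiod_h=pp, temperature_c=tt)


def ellipse_signed_area(ellipse: ClimateEllipse) -> float:
    """Shoelace signed area of the annual loop in the (photoperiod,
    temperature) plane, positive for counter-clockwise traversal. With
    temperature lagging photoperiod (the Northern-Hemisphere norm) the loop
    is counter-clockwise."""
    x = ellipse.photoperiod_h
    y = ellipse.temperature_c
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def predicted_critical_photoperiod(
    ellipse: ClimateEllipse, threshold_c: float = DEFAULT_THRESHOLD_C
) -> Pcpp:
    """pCPP: photoperiod on the spring day temperature rises through the
    threshold.

    For a unimodal annual cycle there are exactly two crossings; the spring
    one is the rising (upward) crossing, taken as the last rising crossing
    before the annual temperature maximum. The crossing day is refined by
    linear interpolation between adjacent days, and the photoperiod is
    interpolated at that fractional day.
    """
    tt = ellipse.temperature_c
    if not tt.min() < threshold_c < tt.max():
        raise NoCrossingError(ellipse.locality_id, threshold_c)

    # rising crossings on the periodic daily trajectory: T[i] < thr <= T[i+1]
    t_next = np.roll(tt, -1)
    rising = np.flatnonzero((tt < threshold_c) & (t_next >= threshold_c))
    if rising.size == 0:
        raise NoCrossingError(ellipse.locality_id, threshold_c)

    peak = int(np.argmax(tt))
    # last rising crossing strictly before the annual maximum, in the cyclic
    # order that ends at the peak
    offsets = (peak - rising) % 365
    offsets[offsets == 0] = 365
    i = int(rising[np.argmin(offsets)])

    j = (i + 1) % 365
    frac = (threshold_c - tt[i]) / (tt[j] - tt[i])
    day_f = ellipse.days[i] + frac  # may exceed 365 at the Dec->Jan seam
    pp = ellipse.photoperiod_h
    pcpp_h = float(pp[i] + frac * (pp[j] - pp[i]))
    crossing_day = float(day_f) if day_f <= 365.0 else float(day_f - 365.0)
    return Pcpp(
        locality_id=ellipse.locality_id,
        threshold_c=float(threshold_c),
        pcpp_h=pcpp_h,
        crossing_day=crossing_day,
    )


def pcpp_for_locality(
    loc: Locality,
    series: MonthlyTemperatureSeries,
    threshold_c: float = DEFAULT_THRESHOLD_C,
) -> Pcpp:
    """Convenience wrapper: ellipse construction plus pCPP extraction."""
    return predicted_critical_photoperiod(build_ellipse(loc, series), threshold_c)
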