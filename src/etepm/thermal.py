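"""Perceived-temperature metrics: NWS heat index and Steadman apparent temperature.

The heat index (HI) combines air temperature and relative humidity into the
temperature a human would perceive in the shade.  The implementation follows
the US National Weather Service algorithm as implemented by the widely used
``weathermetrics`` convention:

* temperatures at or below 40 °F are returned unchanged (humidity is
  irrelevant in the cold);
* otherwise the simple averaged formula
  ``0.5 * (T + 61 + (T - 68) * 1.2 + RH * 0.094)`` (°F) is used;
* when the simple value exceeds 79 °F the Rothfusz regression replaces it,
  with the two documented NWS corrections for very dry (RH < 13 %,
  80–112 °F) and very humid (RH > 85 %, 80–87 °F) conditions.

All internal arithmetic is in °F; the public interface is °C with exact 5/9
conversion factors.

The apparent temperature (AT) is Steadman's outdoor formulation
``AT = Ta + 0.33 e - 0.70 ws - 4.00`` with the vapour pressure ``e`` (hPa)
derived from specific humidity and surface pressure.
"""

from __future__ import annotations

import numpy as np

__all__ = ["heat_index", "apparent_temperature"]

# Rothfusz (1990) regression coefficients, °F
_ROTHFUSZ = (
    -42.379,
    2.04901523,
    10.14333127,
    -0.22475541,
    -6.83783e-3,
    -5.481717e-2,
    1.22874e-3,
    8.5282e-4,
    -1.99e-6,
)


def _c_to_f(t):
    return t * 9.0 / 5.0 + 32.0


def _f_to_c(t):
    return (t - 32.0) * 5.0 / 9.0


def heat_index(temperature, relative_humidity):
    """Heat index (°C) from air temperature (°C) and relative humidity (%).

    Parameters
    ----------
    temperature : array_like
        Daily mean air temperature in °C.  Must be finite.
    relative_humidity : array_like
        Relative humidity in percent, within [0, 100].

    Returns
    -------
    ndarray or float
        Heat index in °C, same shape as the broadcast inputs.
    """
    t = np.asarray(temperature, dtype=float)
    rh = np.asarray(relative_humidity, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("temperature contains non-finite values")
    if not np.all(np.isfinite(rh)):
        raise ValueError("relative_humidity contains non-finite values")
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative_humidity must lie in [0, 100] percent")

    tf, rh = np.broadcast_arrays(_c_to_f(t), rh)
    tf = tf.astype(float)

    simple = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + rh * 0.094)

    c0, c1, c2, c3, c4, c5, c6, c7, c8 = _ROTHFUSZ
    roth = (
        c0
        + c1 * tf
        + c2 * rh
        + c3 * tf * rh
        + c4 * tf * tf
        + c5 * rh * rh
        + c6 * tf * tf * rh
        + c7 * tf * rh * rh
        + c8 * tf * tf * rh * rh
    )
    # low-humidity correction: subtract; high-humidity correction: add
    with np.errstate(invalid="ignore"):
        adj_dry = ((13.0 - rh) / 4.0) * np.sqrt(
            np.clip((17.0 - np.abs(tf - 95.0)) / 17.0, 0.0, None)
        )
    dry = (rh < 13.0) & (tf >= 80.0) & (tf <= 112.0)
    humid = (rh > 85.0) & (tf >= 80.0) & (tf <= 87.0)
    adj_humid = ((rh - 85.0) / 10.0) * ((87.0 - tf) / 2.0)
    roth = roth - np.where(dry, adj_dry, 0.0) + np.where(humid, adj_humid, 0.0)

    hi_f = np.where(simple > 79.0, roth, simple)
    hi_f = np.where(tf <= 40.0, tf, hi_f)
    out = _f_to_c(hi_f)
    return out if out.ndim else float(out)


def apparent_temperature(temperature, specific_humidity, wind_speed, surface_pressure):
    """Steadman apparent temperature (°C).

    Parameters
    ----------
    temperature : array_like
        Air temperature, °C.
    specific_humidity : array_like
        Specific humidity, kg/kg.
    wind_speed : array_like
        10 m wind speed, m/s; must be nonnegative.
    surface_pressure : array_like
        Surface pressure, Pa; must be positive.

    Notes
    -----
    Vapour pressure e (hPa) = q * P / (0.622 + 0.378 * q) with P in hPa;
    AT = Ta + 0.33 * e - 0.70 * ws - 4.00.
    """
    ta = np.asarray(temperature, dtype=float)
    q = np.asarray(specific_humidity, dtype=float)
    ws = np.asarray(wind_speed, dtype=float)
    p = np.asarray(surface_pressure, dtype=float)
    for name, arr in (("temperature", ta), ("specific_humidity", q),
                      ("wind_speed", ws), ("surface_pressure", p)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    if np.any(ws < 0.0):
        raise ValueError("wind_speed must be nonnegative")
    if np.any(p <= 0.0):
        raise ValueError("surface_pressure must be positive")

    p_hpa = p / 100.0
    e = q * p_hpa / (0.622 + 0.378 * q)
    out = ta + 0.33 * e - 0.70 * ws - 4.00
    return out if out.ndim else float(out)
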