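"""Minimal solar geometry: daylength from latitude and day of year."""

from __future__ import annotations

import numpy as np

__all__ = ["daylength_hours", "solar_declination"]


def solar_declination(doy):
    """Solar declination (radians) for day of year ``doy`` (0-based or 1-based
    both acceptable at the accuracy needed here)."""
    return np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + np.asarray(doy, dtype=float)) / 365.0)


def daylength_hours(latitude, doy):
    """Astronomical daylength in hours.

    Parameters
    ----------
    latitude : float or array
        Degrees north (negative south).
    doy : int or array
        Day of year.

    Returns polar day/night as 24/0 hours respectively.
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    decl = solar_declination(doy)
    cos_h0 = -np.tan(lat) * np.tan(decl)
    cos_h0 = np.clip(cos_h0, -1.0, 1.0)
    h0 = np.arccos(cos_h0)
    return 24.0 * h0 / np.pi
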