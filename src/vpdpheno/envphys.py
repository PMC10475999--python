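"""Vapour-pressure physics shared by every stage of the pipeline.

Air (or leaf-to-air) vapour pressure deficit (VPD) is the difference
between the saturation vapour pressure at the relevant temperature and
the actual vapour pressure of the air.  Saturation vapour pressure is
computed with the Tetens formula

    es(T) = 0.6108 * exp(17.27 * T / (T + 237.3))   [kPa, T in deg C]

which agrees with Magnus- and Buck-type fits to well under 1% over the
0-60 deg C range used here.  The constant set is exposed at module level
so an alternative fit can be swapped in via configuration.

Leaf-to-air VPD is the same computation applied with leaf temperature
in place of air temperature; no energy-balance modelling is done (leaf
temperature is always a measured or configured input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AirState",
    "saturation_vapour_pressure",
    "vpd",
    "relative_humidity_from_vpd",
    "intrinsic_wue",
    "MOLAR_MASS_WATER",
]

#: Tetens coefficients (kPa, dimensionless, deg C).
TETENS_A = 0.6108
TETENS_B = 17.27
TETENS_C = 237.3

#: Valid temperature range for the Tetens fit as used here (deg C).
T_MIN = 0.0
T_MAX = 60.0

#: Molar mass of water, g mol^-1 (used for gravimetric conversions).
MOLAR_MASS_WATER = 18.015


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    return arr, arr.ndim == 0


def saturation_vapour_pressure(temperature):
    """Saturation vapour pressure es(T) in kPa by the Tetens formula.

    Parameters
    ----------
    temperature : float or array-like
        Temperature in degrees Celsius, within [0, 60].

    Returns
    -------
    float or ndarray
        es(T) in kPa; strictly increasing in T.
    """
    t, scalar = _as_array(temperature)
    if np.any(~np.isfinite(t)) or np.any(t < T_MIN) or np.any(t > T_MAX):
        raise ValueError(
            f"temperature must lie in [{T_MIN}, {T_MAX}] degC, got {temperature!r}"
        )
    es = TETENS_A * np.exp(TETENS_B * t / (t + TETENS_C))
    return float(es) if scalar else es


def vpd(temperature, relative_humidity):
    """Vapour pressure deficit es(T) * (1 - RH) in kPa.

    ``relative_humidity`` is a fraction in [0, 1] (convert percent at the
    boundary, before calling).  Applied with leaf temperature this yields
    the leaf-to-air VPD.
    """
    rh, scalar = _as_array(relative_humidity)
    if np.any(~np.isfinite(rh)) or np.any(rh < 0.0) or np.any(rh > 1.0):
        raise ValueError(
            f"relative_humidity must be a fraction in [0, 1], got {relative_humidity!r}"
        )
    out = saturation_vapour_pressure(temperature) * (1.0 - rh)
    return float(out) if scalar and np.ndim(temperature) == 0 else out


def relative_humidity_from_vpd(temperature, vpd_kpa):
    """Invert :func:`vpd` for the relative-humidity fraction at fixed T."""
    es = saturation_vapour_pressure(temperature)
    rh = 1.0 - np.asarray(vpd_kpa, dtype=float) / es
    if np.any(rh < 0.0) or np.any(rh > 1.0):
        raise ValueError("vpd_kpa outside the physical range for this temperature")
    return float(rh) if np.ndim(vpd_kpa) == 0 and np.ndim(temperature) == 0 else rh


@dataclass(frozen=True)
class AirState:
    """Temperature (deg C) and relative humidity (fraction in [0, 1]).

    With leaf temperature this describes the leaf boundary condition and
    :meth:`vpd` returns the leaf-to-air VPD.
    """

    temperature: float
    relative_humidity: float

    def __post_init__(self):
        if not (T_MIN <= self.temperature <= T_MAX):
            raise ValueError(
                f"temperature must lie in [{T_MIN}, {T_MAX}] degC, "
                f"got {self.temperature}"
            )
        if not (0.0 <= self.relative_humidity <= 1.0):
            raise ValueError(
                f"relative_humidity must lie in [0, 1], got {self.relative_humidity}"
            )

    def vpd(self) -> float:
        return vpd(self.temperature, self.relative_humidity)


def intrinsic_wue(a, gs):
    """Intrinsic water use efficiency iWUE = A / gs.

    Parameters
    ----------
    a : float or array-like
        Net photosynthetic rate, umol CO2 m^-2 s^-1.
    gs : float or array-like
        Stomatal conductance to water vapour, mol H2O m^-2 s^-1; must be
        positive for the ratio to be defined.

    Returns
    -------
    float or ndarray
        A/gs in umol CO2 per mol H2O; NaN (with a warning) wherever
        gs <= 0.
    """
    a_arr, a_scalar = _as_array(a)
    gs_arr, gs_scalar = _as_array(gs)
    a_arr, gs_arr = np.broadcast_arrays(a_arr, gs_arr)
    bad = ~(gs_arr > 0.0)
    if np.any(bad):
        warnings.warn(
            "iWUE undefined for gs <= 0; returning NaN", RuntimeWarning, stacklevel=2
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, a_arr / np.where(bad, 1.0, gs_arr))
    if a_scalar and gs_scalar:
        return float(out)
    return out
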