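"""Psychrometric conversion between relative and absolute humidity.

Saturation vapor pressure follows the Magnus formula over liquid water;
vapor density then comes from the ideal gas law with the specific gas
constant of water vapor. Constants are fixed and documented so the
standardization of humidity profiles is reproducible to the last digit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

#: specific gas constant of water vapor, J/(kg K)
RV = 461.5

#: Magnus coefficients (hPa, dimensionless, degC); valid roughly -20..50 degC
MAGNUS_A = 6.112
MAGNUS_B = 17.62
MAGNUS_C = 243.12

TEMP_RANGE_C = (-20.0, 50.0)


@dataclass(frozen=True)
class HumidityModel:
    """Saturation-pressure + ideal-gas model for absolute humidity.

    Parameters are the Magnus constants (``a`` in hPa, ``b`` dimensionless,
    ``c`` in degC) and the water-vapor gas constant ``rv`` in J/(kg K).
    Saturation vapor density is strictly increasing in temperature over
    the supported range.
    """

    a: float = MAGNUS_A
    b: float = MAGNUS_B
    c: float = MAGNUS_C
    rv: float = RV

    def saturation_pressure(self, temp_c):
        """Saturation vapor pressure in Pa at ``temp_c`` degC."""
        t = np.asarray(temp_c, dtype=float)
        return 100.0 * self.a * np.exp(self.b * t / (self.c + t))

    def absolute_humidity(self, temp_c, rh_percent):
        """Vapor density in kg/m^3 at ``temp_c`` degC and ``rh_percent`` %RH."""
        t = np.asarray(temp_c, dtype=float)
        rh = np.asarray(rh_percent, dtype=float)
        if np.any(t < TEMP_RANGE_C[0]) or np.any(t > TEMP_RANGE_C[1]):
            raise ValidationError(
                f"temperature outside supported range {TEMP_RANGE_C} degC: {temp_c}"
            )
        if np.any(rh < 0.0) or np.any(rh > 100.0):
            raise ValidationError(f"relative humidity outside [0, 100] %: {rh_percent}")
        es = self.saturation_pressure(t)
        rho = (rh / 100.0) * es / (self.rv * (t + 273.15))
        return float(rho) if rho.ndim == 0 else rho


_DEFAULT = HumidityModel()


def absolute_humidity(temp_c, rh_percent, model: HumidityModel = _DEFAULT):
    """Absolute humidity (kg/m^3) from temperature (degC) and %RH."""
    return model.absolute_humidity(temp_c, rh_percent)
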