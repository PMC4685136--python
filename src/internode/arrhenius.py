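"""Normalized Arrhenius-type temperature response for plant development.

Development and growth of many species respond to temperature with a single
Arrhenius-type curve once rates are normalized by their value at a common
reference temperature.  The curve combines an exponential activation term
with a high-temperature deactivation term controlled by the temperature
``T0`` at which half of the (enzymatic) system is active:

    F(T) = A * T * exp(-dH_A / (R*T)) / (1 + exp(-dH_A / (R*T)) ** (alpha * (1 - T/T0)))

Only the *normalized* factor F_av(T) = F(T) / F(T_ref) is ever used: it
multiplies rates and divides durations, and the scaling coefficient ``A``
cancels in the ratio, so it is never computed.  The default parameters are
the 18-species averages (cereal and horticultural crops plus Arabidopsis):
dH_A = 69350 J/mol, T0 = 305 K, alpha = 3.5, normalized at 20 degC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "R_GAS",
    "CELSIUS_OFFSET",
    "ArrheniusParams",
    "raw_response",
    "normalized_response",
    "SPECIES_TABLE",
]

#: Universal gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Additive offset between Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15

# Soft physiological validity range (degC): outside it a warning is issued.
_SOFT_MIN_C = 0.0
_SOFT_MAX_C = 40.0
# Hard domain bounds (degC): outside them a ValueError is raised.
_HARD_MIN_C = -20.0
_HARD_MAX_C = 60.0


@dataclass(frozen=True)
class ArrheniusParams:
    """Parameters of the Arrhenius-type developmental temperature response.

    Attributes
    ----------
    deltaH_A : float
        Enthalpy of activation, J mol^-1.  Must be positive.
    T0 : float
        Temperature at which half of the system is in the active state, K.
    alpha : float
        Dimensionless shape exponent of the deactivation term.
    T_ref_celsius : float
        Reference temperature (degC) at which the normalized response
        equals exactly 1.  Default 20 degC.
    """

    deltaH_A: float = 69350.0
    T0: float = 305.0
    alpha: float = 3.5
    T_ref_celsius: float = 20.0
    R_gas: float = field(default=R_GAS, repr=False)

    def __post_init__(self) -> None:
        if self.deltaH_A <= 0:
            raise ValueError(f"deltaH_A must be positive, got {self.deltaH_A}")
        if self.T0 <= CELSIUS_OFFSET:
            raise ValueError(f"T0 must exceed 273.15 K, got {self.T0}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.T_ref_celsius + CELSIUS_OFFSET <= 0:
            raise ValueError("reference temperature must be above 0 K")

    @property
    def T_ref_kelvin(self) -> float:
        return self.T_ref_celsius + CELSIUS_OFFSET


#: Shipped species parameter table.  Only the 18-species average entry is
#: bundled; species-specific entries can be supplied through configuration.
SPECIES_TABLE: dict[str, ArrheniusParams] = {
    "18-species-average": ArrheniusParams(),
}


def raw_response(T_kelvin: float, params: ArrheniusParams | None = None) -> float:
    """Un-normalized Arrhenius-type response at absolute temperature ``T_kelvin``.

    The scaling coefficient is taken as 1, so the absolute value is on an
    arbitrary scale; only ratios of this function are meaningful.  The
    denominator exponent is evaluated directly in log space,
    ``exp(-(dH_A/(R*T)) * alpha * (1 - T/T0))``, because
    ``exp(-dH_A/(R*T))`` itself underflows toward ~1e-13 at room
    temperature and raising it to a power would lose precision.

    Parameters
    ----------
    T_kelvin : float
        Absolute temperature, K.  Must be positive.
    params : ArrheniusParams, optional
        Response parameters; the 18-species averages by default.

    Returns
    -------
    float
        Positive response value on an arbitrary scale.
    """
    if params is None:
        params = ArrheniusParams()
    if T_kelvin <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T_kelvin} K")
    x = -params.deltaH_A / (params.R_gas * T_kelvin)
    numerator = T_kelvin * math.exp(x)
    denominator = 1.0 + math.exp(x * params.alpha * (1.0 - T_kelvin / params.T0))
    return numerator / denominator


def normalized_response(T_celsius: float, params: ArrheniusParams | None = None) -> float:
    """Temperature response factor F_av normalized to 1 at the reference.

    ``F_av(T) = raw_response(T) / raw_response(T_ref)``; it multiplies
    rates (elongation, organ appearance) and divides durations.  With the
    default parameters F_av rises from 1 at 20 degC to ~1.4 at 24 degC and
    peaks just below ``T0``.

    Parameters
    ----------
    T_celsius : float
        Air temperature in degC.  Values outside the physiological range
        0-40 degC trigger a warning; values outside -20 to 60 degC raise.
    params : ArrheniusParams, optional
        Response parameters; the 18-species averages by default.

    Returns
    -------
    float
        Dimensionless factor, exactly 1 at the reference temperature.
    """
    if params is None:
        params = ArrheniusParams()
    if not (_HARD_MIN_C <= T_celsius <= _HARD_MAX_C):
        raise ValueError(
            f"temperature {T_celsius} degC outside hard bounds "
            f"[{_HARD_MIN_C}, {_HARD_MAX_C}] degC"
        )
    if not (_SOFT_MIN_C <= T_celsius <= _SOFT_MAX_C):
        warnings.warn(
            f"temperature {T_celsius} degC outside the physiological validity "
            f"range {_SOFT_MIN_C}-{_SOFT_MAX_C} degC; response is an extrapolation",
            stacklevel=2,
        )
    return raw_response(T_celsius + CELSIUS_OFFSET, params) / raw_response(
        params.T_ref_kelvin, params
    )
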