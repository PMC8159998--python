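"""Air-sea CO2 flux from the pCO2 disequilibrium.

F = k * K0 * (pCO2_sea - pCO2_atm), positive seaward-to-air.  The gas
transfer velocity k comes from a pluggable registry (quadratic or cubic
wind-speed laws with Schmidt-number normalization, or a fixed value), and
``calibrate_k`` inverts the flux equation so that a published flux can be
reproduced exactly when the underlying wind parameterization is unknown.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .budget import surface_density
from .carbonate import solubility_k0

__all__ = [
    "FluxInputs",
    "schmidt_number",
    "transfer_velocity",
    "co2_flux",
    "calibrate_k",
    "TRANSFER_VELOCITY_REGISTRY",
]

CM_PER_H_TO_M_PER_D = 0.24


def schmidt_number(temperature: float) -> float:
    """CO2 Schmidt number in seawater (S = 35 polynomial in temperature,
    degC); an adequate approximation over reef salinities."""
    t = temperature
    return (
        2116.8 - 136.25 * t + 4.7353 * t**2 - 0.092307 * t**3 + 0.0007555 * t**4
    )


def _k_quadratic(wind: float, temperature: float) -> float:
    # k660 = 0.251 u^2 (cm h-1), Schmidt-normalized
    return 0.251 * wind**2 * (schmidt_number(temperature) / 660.0) ** -0.5


def _k_cubic(wind: float, temperature: float) -> float:
    # k660 = 0.0283 u^3 (cm h-1)
    return 0.0283 * wind**3 * (schmidt_number(temperature) / 660.0) ** -0.5


TRANSFER_VELOCITY_REGISTRY: dict[str, Callable[[float, float], float]] = {
    "quadratic": _k_quadratic,
    "cubic": _k_cubic,
}


def transfer_velocity(
    wind_speed: float,
    temperature: float,
    salinity: float = 35.0,
    parameterization: str | float = "quadratic",
) -> float:
    """Gas transfer velocity k in cm h-1.

    ``parameterization`` is a registry name or a number, which is returned
    as a fixed k regardless of wind.
    """
    if isinstance(parameterization, (int, float)):
        k = float(parameterization)
        if k < 0:
            raise ValueError("fixed k must be non-negative")
        return k
    if wind_speed < 0:
        raise ValueError("wind speed must be non-negative")
    try:
        fn = TRANSFER_VELOCITY_REGISTRY[parameterization]
    except KeyError:
        raise KeyError(
            f"unknown transfer-velocity parameterization {parameterization!r}; "
            f"registered: {sorted(TRANSFER_VELOCITY_REGISTRY)} or a fixed value"
        ) from None
    return fn(wind_speed, temperature)


@dataclass(frozen=True)
class FluxInputs:
    """Inputs of one flux evaluation.  pCO2 in uatm, wind in m s-1."""

    pco2_sea: float
    pco2_atm: float
    salinity: float
    temperature: float
    wind_speed: float = 0.0
    parameterization: str | float = "quadratic"

    def __post_init__(self):
        if self.pco2_sea <= 0 or self.pco2_atm <= 0:
            raise ValueError("pCO2 values must be positive")
        if self.wind_speed < 0:
            raise ValueError("wind speed must be non-negative")


def co2_flux(inputs: FluxInputs) -> float:
    """Air-sea CO2 flux in mmol C m-2 d-1, positive = efflux to atmosphere.

    F = k [m d-1] * K0*rho [mol m-3 atm-1] * dpCO2 [atm] * 1000.
    """
    k_m_d = transfer_velocity(
        inputs.wind_speed, inputs.temperature, inputs.salinity,
        inputs.parameterization,
    ) * CM_PER_H_TO_M_PER_D
    k0_vol = (
        solubility_k0(inputs.salinity, inputs.temperature)
        * surface_density(inputs.salinity, inputs.temperature)
    )  # mol m-3 atm-1
    dp_atm = (inputs.pco2_sea - inputs.pco2_atm) * 1e-6
    return k_m_d * k0_vol * dp_atm * 1000.0


def calibrate_k(
    target_flux: float,
    pco2_sea: float,
    pco2_atm: float,
    salinity: float,
    temperature: float,
) -> float:
    """Fixed transfer velocity (cm h-1) reproducing a target flux exactly.

    Use when a published flux must be honoured but its wind
    parameterization is not identifiable.  Raises on zero disequilibrium,
    where no finite k can produce a nonzero flux.
    """
    dp = pco2_sea - pco2_atm
    if dp == 0:
        raise ValueError("cannot calibrate k at zero pCO2 disequilibrium")
    k0_vol = solubility_k0(salinity, temperature) * surface_density(
        salinity, temperature
    )
    k_m_d = target_flux / (k0_vol * dp * 1e-6 * 1000.0)
    return k_m_d / CM_PER_H_TO_M_PER_D
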