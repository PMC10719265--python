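"""Air-sea N2O exchange: solubility, saturation, transfer velocity, flux.

Solubility follows the Weiss & Price (1980) moist-air formulation for N2O;
the Schmidt number uses the Wanninkhof (2014) 4th-order polynomials with
linear fresh/seawater interpolation in salinity; the transfer velocity is
the quadratic wind-speed law k = 0.251 u^2 (Sc/660)^-0.5 in cm h-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SurfaceRecord",
    "FluxResult",
    "OutOfRangeError",
    "equilibrium_concentration",
    "saturation",
    "schmidt_number",
    "transfer_velocity",
    "air_sea_flux",
    "oxygen_mgL_to_umol",
    "HYPOXIA_THRESHOLD_UMOL",
]

#: hypoxia threshold: 2 mg L-1 O2 == 62.5 umol L-1
HYPOXIA_THRESHOLD_UMOL = 62.5

#: mg L-1 -> umol L-1 conversion for O2 (molar mass 32.0 g mol-1, so that
#: the conventional 2 mg L-1 threshold maps to exactly 62.5 umol L-1)
_O2_UMOL_PER_MG = 1000.0 / 32.0

# Weiss & Price (1980) Table 2: moist-air solubility function F for N2O,
# mol L-1 atm-1; valid roughly T 0-40 degC, S 0-40.
_WP80_A = (-165.8806, 222.8743, 92.0792, -1.48425)
_WP80_B = (-0.056235, 0.031619, -0.0048472)

# Wanninkhof (2014) Table 1 Schmidt-number polynomials for N2O,
# Sc = A + B t + C t^2 + D t^3 + E t^4 with t in degC; valid 0-40 degC.
_SC_N2O_SEAWATER = (2356.2, -166.38, 6.3952, -0.13422, 0.0011506)
_SC_N2O_FRESH = (2141.2, -152.56, 5.8963, -0.12411, 0.0010655)

_K_COEF = 0.251  # cm h-1 per (m s-1)^2 at Sc = 660

#: k [cm h-1] * dC [nmol L-1] -> flux [umol m-2 d-1]
_FLUX_UNIT_FACTOR = 0.24


class OutOfRangeError(ValueError):
    """Inputs outside the fitted range of a published parameterization."""


@dataclass(frozen=True)
class SurfaceRecord:
    """Surface water sample with the drivers of air-sea exchange."""

    temperature: float  # degC
    salinity: float  # psu
    c_obs: float  # dissolved N2O, nmol L-1
    x_air: float  # atmospheric N2O dry mole fraction, ppb
    wind_u10: float  # wind speed at 10 m, m s-1
    pressure: float = 1.0  # atm

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise OutOfRangeError(f"temperature {self.temperature} outside [-2, 40]")
        if not (0.0 <= self.salinity <= 42.0):
            raise OutOfRangeError(f"salinity {self.salinity} outside [0, 42]")
        if self.c_obs < 0:
            raise ValueError("c_obs must be >= 0")
        if self.x_air < 0:
            raise ValueError("x_air must be >= 0")
        if self.wind_u10 < 0:
            raise ValueError("wind_u10 must be >= 0")
        if self.pressure <= 0:
            raise ValueError("pressure must be > 0")


@dataclass(frozen=True)
class FluxResult:
    c_eq: float  # nmol L-1
    saturation_pct: float
    schmidt: float
    k: float  # cm h-1
    flux: float  # umol m-2 d-1


def n2o_solubility(temperature: float, salinity: float) -> float:
    """Weiss & Price (1980) moist-air solubility F(T, S) in mol L-1 atm-1.

    Multiplying by the dry-air mole fraction and total pressure gives the
    equilibrium dissolved concentration.
    """
    if not (0.0 <= temperature <= 40.0):
        raise OutOfRangeError(
            f"temperature {temperature} degC outside solubility fit range 0-40"
        )
    if not (0.0 <= salinity <= 40.0):
        raise OutOfRangeError(
            f"salinity {salinity} outside solubility fit range 0-40"
        )
    tk = temperature + 273.15
    t100 = tk / 100.0
    a1, a2, a3, a4 = _WP80_A
    b1, b2, b3 = _WP80_B
    ln_f = (
        a1
        + a2 / t100
        + a3 * math.log(t100)
        + a4 * t100**2
        + salinity * (b1 + b2 * t100 + b3 * t100**2)
    )
    return math.exp(ln_f)


def equilibrium_concentration(record: SurfaceRecord) -> float:
    """Air-equilibrium dissolved N2O, nmol L-1.

    c_eq = F(T, S) [mol L-1 atm-1] * x_air [ppb -> atm] * pressure, with
    the 1e-9 (ppb) and 1e9 (mol -> nmol) factors cancelling.
    """
    sol = n2o_solubility(record.temperature, record.salinity)
    return sol * record.x_air * record.pressure


def saturation(record: SurfaceRecord, c_eq: float) -> float:
    """Percent saturation, 100 * c_obs / c_eq."""
    if c_eq <= 0:
        raise ValueError(f"c_eq must be > 0, got {c_eq}")
    return 100.0 * record.c_obs / c_eq


def schmidt_number(temperature: float, salinity: float) -> float:
    """Schmidt number of N2O at (T, S).

    Evaluates the Wanninkhof (2014) freshwater and seawater (S = 35)
    polynomials and interpolates linearly in salinity.
    """
    if not (0.0 <= temperature <= 40.0):
        raise OutOfRangeError(
            f"temperature {temperature} degC outside Schmidt fit range 0-40"
        )
    if salinity < 0:
        raise ValueError("salinity must be >= 0")

    def poly(coefs: tuple[float, ...]) -> float:
        return sum(c * temperature**i for i, c in enumerate(coefs))

    sc_fresh = poly(_SC_N2O_FRESH)
    sc_sea = poly(_SC_N2O_SEAWATER)
    return sc_fresh + (salinity / 35.0) * (sc_sea - sc_fresh)


def transfer_velocity(wind_u10: float, sc: float) -> float:
    """Gas transfer velocity k = 0.251 u^2 (Sc/660)^-0.5, cm h-1."""
    if sc <= 0:
        raise ValueError(f"Schmidt number must be > 0, got {sc}")
    if wind_u10 < 0:
        raise ValueError("wind speed must be >= 0")
    return _K_COEF * wind_u10**2 * (sc / 660.0) ** -0.5


def air_sea_flux(record: SurfaceRecord) -> FluxResult:
    """Full air-sea N2O flux computation for one surface record.

    flux = k * (c_obs - c_eq), converted to umol m-2 d-1 with the exact
    factor 0.24 (cm h-1 * nmol L-1 basis).  Positive flux is outgassing.
    """
    c_eq = equilibrium_concentration(record)
    sat = saturation(record, c_eq)
    sc = schmidt_number(record.temperature, record.salinity)
    k = transfer_velocity(record.wind_u10, sc)
    flux = k * (record.c_obs - c_eq) * _FLUX_UNIT_FACTOR
    return FluxResult(c_eq=c_eq, saturation_pct=sat, schmidt=sc, k=k, flux=flux)


def oxygen_mgL_to_umol(
    do_mgL: float, threshold_umol: float = HYPOXIA_THRESHOLD_UMOL
) -> tuple[float, bool]:
    """Convert dissolved O2 from mg L-1 to umol L-1 and flag hypoxia.

    Returns ``(do_umol, hypoxic)`` where hypoxic means below the threshold
    (default 62.5 umol L-1, i.e. 2 mg L-1).
    """
    if do_mgL < 0:
        raise ValueError("dissolved oxygen must be >= 0")
    do_umol = do_mgL * _O2_UMOL_PER_MG
    return do_umol, do_umol < threshold_umol
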