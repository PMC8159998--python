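"""Seawater CO2-system speciation from the (TA, DIC) pair.

Solves the full marine carbonate system on the total pH scale given total
alkalinity and dissolved inorganic carbon, the pair actually measured by
bottle sampling.  The equilibrium constants are the classic CO2SYS-era
choices: Weiss (1974) CO2 solubility, the Mehrbach et al. (1973) carbonic
acid constants as refit by Dickson & Millero (1987), Dickson (1990) boric
acid and bisulfate, Millero (1995) water, Dickson & Riley (1979) hydrogen
fluoride, and Mucci (1983) aragonite solubility.  All constants are
evaluated at surface pressure and converted onto the total scale before
use; pH is found by bracketed root finding on the alkalinity balance, which
converges unconditionally on [3, 12].

Concentrations are micromol per kg of seawater at the user-facing surface;
internally everything is mol kg-1.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ConstantSet",
    "CarbonateState",
    "build_constants",
    "solve_ta_dic",
    "speciate_station",
    "pco2_isoline",
    "alkalinity_model",
    "solubility_k0",
    "UnsolvableSampleError",
]

logger = logging.getLogger(__name__)

# pH bracket and tolerance for the alkalinity root; bisection/Brent on this
# interval cannot miss the single sign change of TA(pH) - TA_obs.
PH_BRACKET = (3.0, 12.0)
PH_TOL = 1e-8

#: salinity / temperature ranges over which the constant fits are trusted
FIT_RANGE_S = (19.0, 43.0)
FIT_RANGE_T = (2.0, 35.0)


class UnsolvableSampleError(ValueError):
    """Raised when no pH in the bracket balances the alkalinity equation."""

    def __init__(self, msg: str, ta: float | None = None, dic: float | None = None):
        super().__init__(msg)
        self.ta = ta
        self.dic = dic


def solubility_k0(salinity: float, temperature: float) -> float:
    """CO2 solubility K0 (Weiss 1974), mol kg-1 atm-1.

    Decreases with temperature (warming degasses) and with salinity
    (salting-out).
    """
    _check_ranges(salinity, temperature)
    tk = temperature + 273.15
    tk100 = tk / 100.0
    ln_k0 = (
        -60.2409
        + 93.4517 / tk100
        + 23.3585 * math.log(tk100)
        + salinity * (0.023517 - 0.023656 * tk100 + 0.0047036 * tk100**2)
    )
    return math.exp(ln_k0)


def _check_ranges(salinity: float, temperature: float) -> None:
    if not (FIT_RANGE_S[0] <= salinity <= FIT_RANGE_S[1]):
        warnings.warn(
            f"salinity {salinity} outside constant-fit range {FIT_RANGE_S}",
            stacklevel=3,
        )
    if not (FIT_RANGE_T[0] <= temperature <= FIT_RANGE_T[1]):
        warnings.warn(
            f"temperature {temperature} outside constant-fit range {FIT_RANGE_T}",
            stacklevel=3,
        )


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants for one (S, T) condition, total pH scale.

    K1/K2/KW are converted from their native seawater scale; KS and KF stay
    on the free scale because they appear only in the free-hydrogen terms of
    the alkalinity balance and in the scale conversions themselves.
    """

    salinity: float
    temperature: float          # degC
    K0: float                   # mol kg-1 atm-1
    K1: float                   # total scale
    K2: float                   # total scale
    KB: float                   # total scale
    KW: float                   # total scale, (mol kg-1)^2
    KS: float                   # free scale
    KF: float                   # free scale
    Ksp_arag: float             # (mol kg-1)^2
    BT: float                   # total boron, mol kg-1
    ST: float                   # total sulfate, mol kg-1
    FT: float                   # total fluoride, mol kg-1
    Ca: float                   # total calcium, mol kg-1
    fugacity_factor: float      # pCO2 = fCO2 / fugacity_factor
    choice: str = "mehrbach_dm87"
    ph_scale: str = "total"
    # optional nutrient system (seawater-scale fits converted like K1/K2)
    KP1: float = 0.0
    KP2: float = 0.0
    KP3: float = 0.0
    KSi: float = 0.0

    @property
    def free_to_total(self) -> float:
        """[H+]_total / [H+]_free = 1 + ST/KS."""
        return 1.0 + self.ST / self.KS

    @property
    def sws_to_total(self) -> float:
        """Multiplier taking an H+ concentration from seawater to total scale."""
        return (1.0 + self.ST / self.KS) / (
            1.0 + self.ST / self.KS + self.FT / self.KF
        )


_CONSTANT_CHOICES: dict[str, Callable[[float, float], "ConstantSet"]] = {}


def _register(name: str):
    def deco(fn):
        _CONSTANT_CHOICES[name] = fn
        return fn
    return deco


def build_constants(
    salinity: float,
    temperature: float,
    constant_choice: str = "mehrbach_dm87",
) -> ConstantSet:
    """Evaluate the named equilibrium-constant set at (S, T), surface pressure.

    Parameters
    ----------
    salinity : practical salinity.
    temperature : in-situ temperature, degC.
    constant_choice : registered set name; the default is the Mehrbach
        carbonic-acid constants refit by Dickson & Millero with Mucci
        aragonite solubility.

    Raises
    ------
    KeyError if ``constant_choice`` is not registered.  Out-of-range S or T
    raises a warning, not an error: the fits extrapolate smoothly near their
    edges and a hard failure would drop real samples.
    """
    try:
        builder = _CONSTANT_CHOICES[constant_choice]
    except KeyError:
        raise KeyError(
            f"unknown constant_choice {constant_choice!r}; "
            f"registered: {sorted(_CONSTANT_CHOICES)}"
        ) from None
    _check_ranges(salinity, temperature)
    return builder(salinity, temperature)


@_register("mehrbach_dm87")
def _mehrbach_dm87(S: float, T: float) -> ConstantSet:
    tk = T + 273.15
    ln_tk = math.log(tk)
    sqrt_s = math.sqrt(S)
    # ionic strength from practical salinity
    ion = 19.924 * S / (1000.0 - 1.005 * S)

    # --- totals from salinity (mol kg-sw-1) ---
    BT = 0.0004157 * S / 35.0                    # Uppstrom (1974) boron
    ST = 0.14 / 96.062 * S / 1.80655             # Morris & Riley sulfate
    FT = 0.000067 / 18.998 * S / 1.80655         # Riley fluoride
    Ca = 0.01028 * S / 35.0                      # conservative calcium

    # --- bisulfate, Dickson (1990a), free scale ---
    ln_ks = (
        -4276.1 / tk + 141.328 - 23.093 * ln_tk
        + (-13856.0 / tk + 324.57 - 47.986 * ln_tk) * math.sqrt(ion)
        + (35474.0 / tk - 771.54 + 114.723 * ln_tk) * ion
        - 2698.0 / tk * ion**1.5
        + 1776.0 / tk * ion**2
        + math.log(1.0 - 0.001005 * S)
    )
    KS = math.exp(ln_ks)

    # --- hydrogen fluoride, Dickson & Riley (1979), free scale ---
    ln_kf = 1590.2 / tk - 12.641 + 1.525 * math.sqrt(ion) + math.log(
        1.0 - 0.001005 * S
    )
    KF = math.exp(ln_kf)

    sws_to_total = (1.0 + ST / KS) / (1.0 + ST / KS + FT / KF)

    # --- carbonic acid, Mehrbach refit by Dickson & Millero (1987), SWS ---
    pk1 = 3670.7 / tk - 62.008 + 9.7944 * ln_tk - 0.0118 * S + 0.000116 * S**2
    pk2 = 1394.7 / tk + 4.777 - 0.0184 * S + 0.000118 * S**2
    K1 = 10.0**-pk1 * sws_to_total
    K2 = 10.0**-pk2 * sws_to_total

    # --- boric acid, Dickson (1990b), native total scale ---
    ln_kb = (
        (-8966.90 - 2890.53 * sqrt_s - 77.942 * S + 1.728 * S**1.5 - 0.0996 * S**2)
        / tk
        + 148.0248 + 137.1942 * sqrt_s + 1.62142 * S
        + (-24.4344 - 25.085 * sqrt_s - 0.2474 * S) * ln_tk
        + 0.053105 * sqrt_s * tk
    )
    KB = math.exp(ln_kb)

    # --- water, Millero (1995), SWS ---
    ln_kw = (
        148.9802 - 13847.26 / tk - 23.6521 * ln_tk
        + (118.67 / tk - 5.977 + 1.0495 * ln_tk) * sqrt_s
        - 0.01615 * S
    )
    KW = math.exp(ln_kw) * sws_to_total

    # --- aragonite solubility, Mucci (1983) ---
    log_ksp = (
        -171.945 - 0.077993 * tk + 2903.293 / tk + 71.595 * math.log10(tk)
        + (-0.068393 + 0.0017276 * tk + 88.135 / tk) * sqrt_s
        - 0.10018 * S + 0.0059415 * S**1.5
    )
    Ksp = 10.0**log_ksp

    # --- phosphoric acid and silicate, Millero (1995), SWS ---
    ln_kp1 = (
        -4576.752 / tk + 115.525 - 18.453 * ln_tk
        + (-106.736 / tk + 0.69171) * sqrt_s
        + (-0.65643 / tk - 0.01844) * S
    )
    ln_kp2 = (
        -8814.715 / tk + 172.0883 - 27.927 * ln_tk
        + (-160.340 / tk + 1.3566) * sqrt_s
        + (0.37335 / tk - 0.05778) * S
    )
    ln_kp3 = (
        -3070.75 / tk - 18.141
        + (17.27039 / tk + 2.81197) * sqrt_s
        + (-44.99486 / tk - 0.09984) * S
    )
    ln_ksi = (
        -8904.2 / tk + 117.385 - 19.334 * ln_tk
        + (-458.79 / tk + 3.5913) * math.sqrt(ion)
        + (188.74 / tk - 1.5998) * ion
        + (-12.1652 / tk + 0.07871) * ion**2
        + math.log(1.0 - 0.001005 * S)
    )
    KP1 = math.exp(ln_kp1) * sws_to_total
    KP2 = math.exp(ln_kp2) * sws_to_total
    KP3 = math.exp(ln_kp3) * sws_to_total
    KSi = math.exp(ln_ksi) * sws_to_total

    # --- fugacity factor, Weiss (1974) virial fit ---
    delta = 57.7 - 0.118 * tk
    b_vir = -1636.75 + 12.0408 * tk - 0.0327957 * tk**2 + 3.16528e-5 * tk**3
    p1atm = 1.01325  # bar
    rgas = 83.14462618  # cm3 bar mol-1 K-1
    fugfac = math.exp((b_vir + 2.0 * delta) * p1atm / (rgas * tk))

    return ConstantSet(
        salinity=S, temperature=T,
        K0=solubility_k0(S, T),
        K1=K1, K2=K2, KB=KB, KW=KW, KS=KS, KF=KF,
        Ksp_arag=Ksp, BT=BT, ST=ST, FT=FT, Ca=Ca,
        fugacity_factor=fugfac,
        KP1=KP1, KP2=KP2, KP3=KP3, KSi=KSi,
    )


def convert_scale(
    k: float, constants: ConstantSet, from_scale: str, to_scale: str
) -> float:
    """Convert an acid-dissociation constant between pH scales.

    Scales: 'total', 'sws' (seawater), 'free'.  The conversion multiplies by
    the ratio of hydrogen-ion conventions, built from KS, KF, ST and FT.
    """
    s = constants.ST / constants.KS
    f = constants.FT / constants.KF
    to_free = {"free": 1.0, "total": 1.0 + s, "sws": 1.0 + s + f}
    try:
        return k * to_free[to_scale] / to_free[from_scale]
    except KeyError as exc:
        raise KeyError(f"unknown pH scale {exc}") from None


@dataclass(frozen=True)
class CarbonateState:
    """Full speciation of one sample.  Concentrations in umol kg-1."""

    ph_total: float
    pco2: float                 # uatm
    fco2: float                 # uatm
    omega_arag: float
    co2_star: float             # aqueous CO2 + H2CO3
    hco3: float
    co3: float
    residual_ta: float          # umol kg-1, alkalinity closure diagnostic
    constants: ConstantSet = field(repr=False, compare=False, default=None)

    @property
    def dic(self) -> float:
        return self.co2_star + self.hco3 + self.co3


def alkalinity_model(
    ph_total: float,
    dic: float,
    constants: ConstantSet,
    *,
    total_phosphate: float = 0.0,
    total_silicate: float = 0.0,
) -> float:
    """Total alkalinity (umol kg-1) at a given total-scale pH and DIC.

    TA = [HCO3-] + 2[CO3--] + [B(OH)4-] + [OH-] - [H+]F - [HSO4-] - [HF]
    with optional phosphate ([HPO4--] + 2[PO4---] - [H3PO4]) and silicate
    ([SiO(OH)3-]) contributions.  DIC and nutrient totals in umol kg-1.
    """
    c = constants
    h = 10.0 ** (-ph_total)
    h_free = h / c.free_to_total
    dic_mol = dic * 1e-6

    denom = h * h + c.K1 * h + c.K1 * c.K2
    hco3 = dic_mol * c.K1 * h / denom
    co3 = dic_mol * c.K1 * c.K2 / denom
    boh4 = c.BT * c.KB / (c.KB + h)
    oh = c.KW / h
    hso4 = c.ST * h_free / (c.KS + h_free)
    hf = c.FT * h_free / (c.KF + h_free)

    ta = hco3 + 2.0 * co3 + boh4 + oh - h_free - hso4 - hf

    if total_phosphate > 0.0:
        tp = total_phosphate * 1e-6
        d = (
            h**3 + c.KP1 * h**2 + c.KP1 * c.KP2 * h + c.KP1 * c.KP2 * c.KP3
        )
        h3po4 = tp * h**3 / d
        hpo4 = tp * c.KP1 * c.KP2 * h / d
        po4 = tp * c.KP1 * c.KP2 * c.KP3 / d
        ta += hpo4 + 2.0 * po4 - h3po4
    if total_silicate > 0.0:
        tsi = total_silicate * 1e-6
        ta += tsi * c.KSi / (c.KSi + h)

    return ta * 1e6


def solve_ta_dic(
    ta: float,
    dic: float,
    constants: ConstantSet,
    *,
    total_phosphate: float = 0.0,
    total_silicate: float = 0.0,
) -> CarbonateState:
    """Speciate a sample from its (TA, DIC) pair.

    Finds the total-scale pH at which the modelled alkalinity matches the
    measured one (Brent's method on [3, 12], 1e-8 pH tolerance), then reads
    off the carbonate species, pCO2 and the aragonite saturation state.

    Parameters
    ----------
    ta, dic : umol kg-1.
    constants : from :func:`build_constants` at the sample's S and T.
    total_phosphate, total_silicate : umol kg-1; include nutrient
        alkalinity when nonzero.

    Raises
    ------
    UnsolvableSampleError
        if the alkalinity balance has no root in the pH bracket, which
        happens only for physically inconsistent (TA, DIC) pairs.
    """
    if ta <= 0 or dic <= 0:
        raise ValueError(f"TA and DIC must be positive, got TA={ta}, DIC={dic}")
    c = constants

    def f(ph: float) -> float:
        return (
            alkalinity_model(
                ph, dic, c,
                total_phosphate=total_phosphate,
                total_silicate=total_silicate,
            )
            - ta
        )

    lo, hi = PH_BRACKET
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise UnsolvableSampleError(
            f"no pH in [{lo}, {hi}] balances TA={ta}, DIC={dic} "
            f"(S={c.salinity}, T={c.temperature})",
            ta=ta, dic=dic,
        )
    ph = brentq(f, lo, hi, xtol=PH_TOL, maxiter=200)

    h = 10.0**-ph
    dic_mol = dic * 1e-6
    denom = h * h + c.K1 * h + c.K1 * c.K2
    co2_star = dic_mol * h * h / denom
    hco3 = dic_mol * c.K1 * h / denom
    co3 = dic_mol * c.K1 * c.K2 / denom
    fco2 = co2_star / c.K0 * 1e6                 # uatm
    pco2 = fco2 / c.fugacity_factor
    omega = c.Ca * co3 / c.Ksp_arag

    return CarbonateState(
        ph_total=ph,
        pco2=pco2,
        fco2=fco2,
        omega_arag=omega,
        co2_star=co2_star * 1e6,
        hco3=hco3 * 1e6,
        co3=co3 * 1e6,
        residual_ta=f(ph),
        constants=c,
    )


def speciate_station(
    ta: float,
    dic: float,
    salinity: float,
    temperature: float,
    constant_choice: str = "mehrbach_dm87",
    **kwargs,
) -> CarbonateState:
    """Convenience wrapper: build constants at (S, T) and solve (TA, DIC)."""
    return solve_ta_dic(
        ta, dic, build_constants(salinity, temperature, constant_choice), **kwargs
    )


def pco2_isoline(
    pco2_target: float,
    dic_grid: Sequence[float],
    constants: ConstantSet,
    *,
    tol_uatm: float = 0.1,
) -> np.ndarray:
    """TA(DIC) curve of constant pCO2, for TA-DIC diagram contours.

    For each DIC on the (ascending) grid, finds the TA at which the
    speciated pCO2 equals ``pco2_target`` within ``tol_uatm``.  pCO2 is
    strictly decreasing in TA at fixed DIC, so the root is unique; grid
    points where the target is unreachable inside the TA search window are
    omitted and logged.

    Returns an (n, 2) array of [DIC, TA] rows, TA monotonically increasing
    with DIC.
    """
    if pco2_target <= 0:
        raise ValueError("pCO2 target must be positive")
    dic_grid = np.asarray(dic_grid, dtype=float)
    if np.any(np.diff(dic_grid) <= 0):
        raise ValueError("DIC grid must be strictly ascending")

    points = []
    for dic in dic_grid:
        def g(ta: float) -> float:
            return solve_ta_dic(ta, dic, constants).pco2 - pco2_target

        # TA window wide enough for any oceanographically plausible target
        lo, hi = 0.3 * dic, 2.5 * dic
        try:
            if g(lo) * g(hi) > 0:
                raise UnsolvableSampleError("target outside TA window")
            ta = brentq(g, lo, hi, xtol=1e-6, maxiter=200)
        except (UnsolvableSampleError, ValueError):
            logger.info(
                "pCO2 isoline %.0f uatm unreachable at DIC=%.1f; point omitted",
                pco2_target, dic,
            )
            continue
        if abs(g(ta)) <= tol_uatm:
            points.append((dic, ta))
    return np.array(points).reshape(-1, 2)
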