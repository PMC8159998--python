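"""Bay-scale carbon budget from TA/DIC anomalies and a residence-time box model.

The bay is treated as a single box exchanging with offshore water on a
mean residence time tau.  Salinity-normalized TA and DIC anomalies of the
bay interior relative to an offshore end-member are split into a
calcification component (which draws down TA and DIC in a 2:1 ratio) and
an organic component (photosynthesis/respiration, which moves DIC only).
Assuming the anomalies accumulated over one residence time in a water
column of mean depth d and density rho, the areal rates follow:

    Gn = -(dTA/2) * rho * d / tau / 1000     [mmol CaCO3 m-2 d-1]
    Pn = -(dDIC - dTA/2) * rho * d / tau / 1000   [mmol C m-2 d-1]

Positive Gn is net calcification; negative Pn is net heterotrophy.  An
air-sea CO2 efflux F removes DIC that would otherwise be attributed to
weaker heterotrophy, so the gas-corrected production is Pn - F.

`CarbonBudgetModel` wraps the whole chain for a station table:
normalization, per-site day/night midpoint averaging, group means, the
decomposition and the rates, with standard errors propagated from the
between-station spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "BayGeometry",
    "EndMember",
    "Decomposition",
    "BudgetResult",
    "surface_density",
    "normalize_salinity",
    "diel_average",
    "decompose_ta_dic",
    "box_model_rates",
    "correct_for_gas_exchange",
    "CarbonBudgetModel",
    "CarbonBudgetResults",
]

STATION_ROLES = ("bay_interior", "end_member", "excluded")


def surface_density(salinity: float, temperature: float) -> float:
    """Surface seawater density (kg m-3), one-atmosphere equation of state
    of Millero & Poisson (1981)."""
    t = temperature
    s = salinity
    if not 0 <= s <= 42:
        raise ValueError(f"salinity {s} outside EOS validity")
    rho_w = (
        999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5
    )
    a = (
        0.824493 - 4.0899e-3 * t + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3 + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return rho_w + a * s + b * s**1.5 + c * s**2


@dataclass(frozen=True)
class BayGeometry:
    """Box-model geometry and hydrography.

    rho defaults to the surface density at (reference_salinity,
    mean_temperature) so the budget is reproducible without an explicit
    density choice.
    """

    residence_time_days: float
    mean_depth_m: float
    reference_salinity: float
    mean_temperature: float = 30.0
    seawater_density: float | None = None

    def __post_init__(self):
        if self.residence_time_days <= 0:
            raise ValueError("residence time must be positive")
        if self.mean_depth_m <= 0:
            raise ValueError("mean depth must be positive")
        if self.seawater_density is None:
            object.__setattr__(
                self, "seawater_density",
                surface_density(self.reference_salinity, self.mean_temperature),
            )
        if not 1000 < self.seawater_density < 1035:
            raise ValueError(
                f"density {self.seawater_density} kg m-3 implausible for seawater"
            )


@dataclass(frozen=True)
class EndMember:
    """Salinity-normalized offshore reference water."""

    nTA: float
    nDIC: float

    def __post_init__(self):
        if self.nTA <= 0 or self.nDIC <= 0:
            raise ValueError("end-member TA and DIC must be positive")


def normalize_salinity(value, salinity, reference_salinity):
    """Scale a concentration to a reference salinity: nX = X * S_ref / S.

    Removes evaporation/dilution signals so that only biogeochemical
    processes move TA and DIC.
    """
    salinity = np.asarray(salinity, dtype=float)
    if np.any(salinity <= 0):
        raise ValueError("salinity must be positive")
    return np.asarray(value, dtype=float) * reference_salinity / salinity


def diel_average(day_value: float, night_value: float) -> float:
    """Daily mean as the midpoint of the sunset and sunrise samples.

    In a closed system TA and DIC bottom out near sunset (production and
    calcification cease at the light compensation point) and peak near
    sunrise, so the midpoint of the two extremes estimates the daily mean.
    """
    if day_value is None or night_value is None or (
        np.isnan(day_value) or np.isnan(night_value)
    ):
        raise ValueError("both day and night values are required for a diel mean")
    return 0.5 * (day_value + night_value)


@dataclass(frozen=True)
class Decomposition:
    """TA/DIC anomaly split into calcification and organic vectors.

    dDIC_calc + dDIC_org == dDIC exactly, by construction.
    """

    dTA: float
    dDIC: float

    @property
    def dDIC_calc(self) -> float:
        return self.dTA / 2.0

    @property
    def dDIC_org(self) -> float:
        return self.dDIC - self.dTA / 2.0


def decompose_ta_dic(
    bay_nta: float, bay_ndic: float, end_member: EndMember
) -> Decomposition:
    """Anomaly of the bay interior against the offshore end-member.

    Calcification moves (TA, DIC) along a slope-2 vector (2 mol TA per mol
    CaCO3), so the calcification share of the DIC anomaly is dTA/2; the
    organic (photosynthesis/respiration) vector leaves TA unchanged and
    takes the remainder.  All inputs must already be normalized to the same
    reference salinity.
    """
    return Decomposition(
        dTA=bay_nta - end_member.nTA, dDIC=bay_ndic - end_member.nDIC
    )


def _anomaly_to_rate(anomaly_umol_kg: float, geometry: BayGeometry) -> float:
    """Convert a per-mass anomaly accumulated over one residence time into
    an areal rate.  The single place where umol kg-1 becomes mmol m-2 d-1:

        rate = anomaly * rho * d / tau / 1000
    """
    return (
        anomaly_umol_kg
        * geometry.seawater_density
        * geometry.mean_depth_m
        / geometry.residence_time_days
        / 1000.0
    )


def box_model_rates(
    dta: float, ddic: float, geometry: BayGeometry
) -> tuple[float, float]:
    """Net ecosystem calcification Gn and net production Pn from anomalies.

    Returns (Gn, Pn) in mmol CaCO3 m-2 d-1 and mmol C m-2 d-1.  A TA
    drawdown (dTA < 0) gives positive Gn; a DIC excess beyond the
    calcification share gives negative Pn (net heterotrophy).
    """
    d = Decomposition(dta, ddic)
    gn = -_anomaly_to_rate(d.dDIC_calc, geometry)
    pn = -_anomaly_to_rate(d.dDIC_org, geometry)
    return gn, pn


def correct_for_gas_exchange(pn: float, gas_flux: float) -> float:
    """Remove the air-sea CO2 flux from net production.

    gas_flux > 0 is efflux to the atmosphere: DIC lost to the air was not
    lost to photosynthesis, so the true production is Pn - F (more
    heterotrophic than the uncorrected estimate when the bay outgasses).
    """
    return pn - gas_flux


@dataclass
class BudgetResult:
    """Point estimates of one budget evaluation."""

    dTA: float
    dDIC: float
    dDIC_calc: float
    dDIC_org: float
    Gn: float
    Pn: float
    gas_flux: float | None = None
    Pn_corrected: float | None = None


class CarbonBudgetModel:
    """Residence-time carbon budget of a semi-enclosed bay.

    Parameters
    ----------
    stations : DataFrame with columns site_id, phase ('day'|'night'),
        salinity, ta_umol_kg, dic_umol_kg and station_role
        ('bay_interior' | 'end_member' | 'excluded').
    geometry : BayGeometry.
    pooling : 'midpoint' (default) computes per-site day/night midpoints
        first and averages sites; 'pooled' averages all samples of a group
        directly.
    gas_flux : optional air-sea CO2 flux (mmol C m-2 d-1, positive =
        efflux) used to correct Pn.

    Examples
    --------
    >>> model = CarbonBudgetModel.from_dataframe(stations, geometry)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        stations: pd.DataFrame,
        geometry: BayGeometry,
        *,
        pooling: str = "midpoint",
        variance: str = "pooled",
        gas_flux: float | None = None,
    ):
        required = {"site_id", "phase", "salinity", "ta_umol_kg",
                    "dic_umol_kg", "station_role"}
        missing = required - set(stations.columns)
        if missing:
            raise ValueError(f"station table missing columns: {sorted(missing)}")
        bad_roles = set(stations["station_role"]) - set(STATION_ROLES)
        if bad_roles:
            raise ValueError(f"unknown station roles: {sorted(bad_roles)}")
        if pooling not in ("midpoint", "pooled"):
            raise ValueError("pooling must be 'midpoint' or 'pooled'")
        if variance not in ("pooled", "per_group"):
            raise ValueError("variance must be 'pooled' or 'per_group'")
        self.stations = stations.copy()
        self.geometry = geometry
        self.pooling = pooling
        self.variance = variance
        self.gas_flux = gas_flux

    @classmethod
    def from_dataframe(cls, stations: pd.DataFrame, geometry: BayGeometry, **kw):
        return cls(stations, geometry, **kw)

    # -- internal -----------------------------------------------------------
    def _normalized(self) -> pd.DataFrame:
        df = self.stations[self.stations.station_role != "excluded"].copy()
        s_ref = self.geometry.reference_salinity
        df["nta"] = normalize_salinity(df.ta_umol_kg, df.salinity, s_ref)
        df["ndic"] = normalize_salinity(df.dic_umol_kg, df.salinity, s_ref)
        return df

    def _group_stats(self, df: pd.DataFrame, role: str):
        """Mean, SE and n of normalized TA/DIC for one station role."""
        g = df[df.station_role == role]
        dropped: list[str] = []
        if self.pooling == "midpoint":
            wide = g.pivot_table(
                index="site_id", columns="phase", values=["nta", "ndic"],
                aggfunc="mean",
            )
            have_both = wide.notna().all(axis=1)
            dropped = sorted(wide.index[~have_both])
            wide = wide[have_both]
            nta = 0.5 * (wide[("nta", "day")] + wide[("nta", "night")])
            ndic = 0.5 * (wide[("ndic", "day")] + wide[("ndic", "night")])
        else:
            nta, ndic = g.nta, g.ndic
        n = len(nta)
        if n == 0:
            raise ValueError(f"no usable stations with role {role!r}")
        sd = lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
        return {
            "nta": float(np.mean(nta)), "ndic": float(np.mean(ndic)),
            "sd_nta": sd(nta), "sd_ndic": sd(ndic),
            "se_nta": sd(nta) / np.sqrt(n), "se_ndic": sd(ndic) / np.sqrt(n),
            "n": n, "dropped_sites": dropped,
        }

    @staticmethod
    def _pool_se(bay: dict, off: dict, key: str) -> None:
        """Replace per-group SEs with ones from the pooled within-group SD.

        The measurement noise of the titration is the same for every
        station, so under homoskedasticity the pooled estimate has far
        more degrees of freedom than the handful of offshore stations can
        provide on their own.
        """
        n1, n2 = bay["n"], off["n"]
        df = n1 + n2 - 2
        if df <= 0:
            return
        s2 = ((n1 - 1) * bay[f"sd_{key}"] ** 2 + (n2 - 1) * off[f"sd_{key}"] ** 2) / df
        bay[f"se_{key}"] = float(np.sqrt(s2 / n1))
        off[f"se_{key}"] = float(np.sqrt(s2 / n2))

    def fit(self) -> "CarbonBudgetResults":
        df = self._normalized()
        bay = self._group_stats(df, "bay_interior")
        off = self._group_stats(df, "end_member")
        if self.variance == "pooled":
            self._pool_se(bay, off, "nta")
            self._pool_se(bay, off, "ndic")
        em = EndMember(nTA=off["nta"], nDIC=off["ndic"])
        dec = decompose_ta_dic(bay["nta"], bay["ndic"], em)
        gn, pn = box_model_rates(dec.dTA, dec.dDIC, self.geometry)

        se_dta = float(np.hypot(bay["se_nta"], off["se_nta"]))
        se_ddic = float(np.hypot(bay["se_ndic"], off["se_ndic"]))
        se_gn = _anomaly_to_rate(se_dta / 2.0, self.geometry)
        # var(dDIC - dTA/2) assuming independent TA and DIC errors
        se_pn = _anomaly_to_rate(
            float(np.hypot(se_ddic, se_dta / 2.0)), self.geometry
        )

        result = BudgetResult(
            dTA=dec.dTA, dDIC=dec.dDIC,
            dDIC_calc=dec.dDIC_calc, dDIC_org=dec.dDIC_org,
            Gn=gn, Pn=pn,
        )
        if self.gas_flux is not None:
            result.gas_flux = self.gas_flux
            result.Pn_corrected = correct_for_gas_exchange(pn, self.gas_flux)
        return CarbonBudgetResults(
            model=self, result=result, bay=bay, end_member=off,
            se_Gn=abs(se_gn), se_Pn=abs(se_pn),
            se_dTA=se_dta, se_dDIC=se_ddic,
        )


@dataclass
class CarbonBudgetResults:
    """Fitted budget: rates, their standard errors and the anomaly audit trail.

    Standard errors reflect between-station spread of the diel-averaged,
    salinity-normalized values, propagated linearly through the box model
    (the model is linear in the anomalies, so this is exact given the
    group SEs).
    """

    model: CarbonBudgetModel
    result: BudgetResult
    bay: dict
    end_member: dict
    se_Gn: float
    se_Pn: float
    se_dTA: float
    se_dDIC: float

    @property
    def Gn(self) -> float:
        return self.result.Gn

    @property
    def Pn(self) -> float:
        return self.result.Pn

    @property
    def Pn_corrected(self) -> float | None:
        return self.result.Pn_corrected

    def to_frame(self) -> pd.DataFrame:
        r = self.result
        rows = [
            ("dTA", r.dTA, "umol kg-1", self.se_dTA),
            ("dDIC", r.dDIC, "umol kg-1", self.se_dDIC),
            ("dDIC_calc", r.dDIC_calc, "umol kg-1", np.nan),
            ("dDIC_org", r.dDIC_org, "umol kg-1", np.nan),
            ("Gn", r.Gn, "mmol CaCO3 m-2 d-1", self.se_Gn),
            ("Pn", r.Pn, "mmol C m-2 d-1", self.se_Pn),
        ]
        if r.gas_flux is not None:
            rows += [
                ("gas_flux", r.gas_flux, "mmol C m-2 d-1", np.nan),
                ("Pn_corrected", r.Pn_corrected, "mmol C m-2 d-1", self.se_Pn),
            ]
        return pd.DataFrame(rows, columns=["quantity", "value", "units", "se"])

    def summary(self) -> str:
        g = self.model.geometry
        lines = [
            "Residence-time carbon budget",
            "=" * 60,
            f"geometry: tau = {g.residence_time_days:g} d, "
            f"d = {g.mean_depth_m:g} m, rho = {g.seawater_density:.1f} kg m-3, "
            f"S_ref = {g.reference_salinity:g}",
            f"bay interior: n = {self.bay['n']}  "
            f"(nTA = {self.bay['nta']:.1f} +/- {self.bay['se_nta']:.1f}, "
            f"nDIC = {self.bay['ndic']:.1f} +/- {self.bay['se_ndic']:.1f})",
            f"end member:   n = {self.end_member['n']}  "
            f"(nTA = {self.end_member['nta']:.1f}, "
            f"nDIC = {self.end_member['ndic']:.1f})",
        ]
        if self.bay["dropped_sites"]:
            lines.append(
                "dropped (missing day or night): "
                + ", ".join(map(str, self.bay["dropped_sites"]))
            )
        lines.append("-" * 60)
        for _, row in self.to_frame().iterrows():
            se = "" if np.isnan(row.se) else f" +/- {row.se:.2f}"
            lines.append(f"{row.quantity:>14s} = {row.value:9.2f}{se}  [{row.units}]")
        return "\n".join(lines)
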