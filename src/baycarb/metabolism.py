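"""Coral metabolic rates from buoyant weights and closed-chamber O2 incubations.

Calcification is measured by buoyant-weight calcimetry: a coral weighed in
seawater registers only the weight its skeleton exceeds the displaced
water, so the dry skeletal mass follows from Archimedes with the aragonite
density, and the rate is the dry-mass change normalized to surface area
and time.  Photosynthesis and respiration come from O2 concentration
changes in a sealed, stirred chamber under light (net photosynthesis, Pn)
or dark (respiration, R):

    rate = slope(O2 vs time) * (V_chamber - V_coral) / SA

Dark O2 consumption makes R negative; gross photosynthesis is
Pg = Pn - R, and the energy-balance ratio is Pg : |R|.

`TransplantExperiment` assembles per-nubbin rates from the nubbin and
incubation tables of a reciprocal transplant design.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARAGONITE_DENSITY",
    "NubbinRecord",
    "IncubationSeries",
    "MetabolicResult",
    "buoyant_to_dry_weight",
    "calcification_rate",
    "o2_slope",
    "incubation_rate",
    "gross_photosynthesis",
    "TransplantExperiment",
    "TransplantResults",
]

logger = logging.getLogger(__name__)

ARAGONITE_DENSITY = 2.94  # g cm-3


def buoyant_to_dry_weight(
    buoyant_weight: float,
    seawater_density: float,
    skeletal_density: float = ARAGONITE_DENSITY,
) -> float:
    """Dry skeletal mass (g) from buoyant weight via Archimedes.

    W_dry = W_buoyant / (1 - rho_sw / rho_skeleton); densities in g cm-3.
    """
    if not skeletal_density > seawater_density > 0:
        raise ValueError(
            f"need skeletal density ({skeletal_density}) > seawater density "
            f"({seawater_density}) > 0"
        )
    return buoyant_weight / (1.0 - seawater_density / skeletal_density)


@dataclass(frozen=True)
class NubbinRecord:
    """One coral fragment of the transplant design.

    Replicate weighings may be supplied as sequences; they are averaged
    before the density conversion.
    """

    nubbin_id: str
    colony_id: str
    origin_site: str
    transplant_site: str
    buoyant_weight_initial: float   # g, or mean of replicates
    buoyant_weight_final: float
    duration_days: float
    surface_area: float             # cm2
    seawater_density_at_weighing: float = 1.023  # g cm-3

    def __post_init__(self):
        if self.surface_area <= 0:
            raise ValueError("surface area must be positive")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.buoyant_weight_initial <= 0 or self.buoyant_weight_final <= 0:
            raise ValueError("buoyant weights must be positive")


def calcification_rate(record: NubbinRecord) -> float:
    """Calcification in mg CaCO3 cm-2 d-1; negative means net dissolution."""
    w0 = buoyant_to_dry_weight(
        record.buoyant_weight_initial, record.seawater_density_at_weighing
    )
    w1 = buoyant_to_dry_weight(
        record.buoyant_weight_final, record.seawater_density_at_weighing
    )
    return (w1 - w0) * 1000.0 / (record.surface_area * record.duration_days)


@dataclass(frozen=True)
class IncubationSeries:
    """Timed O2 readings of one sealed chamber.

    readings: sequence of (time_min, o2_umol_l); is_blank marks the
    coral-free control chamber.
    """

    nubbin_id: str
    phase: str                      # 'light' | 'dark'
    chamber_volume_ml: float
    coral_volume_ml: float
    readings: tuple[tuple[float, float], ...]
    is_blank: bool = False

    def __post_init__(self):
        if self.phase not in ("light", "dark"):
            raise ValueError(f"phase must be 'light' or 'dark', got {self.phase!r}")
        if len(self.readings) < 2:
            raise ValueError("need at least two O2 readings")
        times = [t for t, _ in self.readings]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("reading times must be strictly increasing")
        if not self.chamber_volume_ml > self.coral_volume_ml >= 0:
            raise ValueError("need chamber volume > coral volume >= 0")


def o2_slope(
    series: IncubationSeries,
    blank_series: IncubationSeries | None = None,
    method: str = "ols",
) -> float:
    """Blank-corrected O2 slope in umol L-1 h-1.

    method='ols' fits ordinary least squares through all readings (robust
    to noise on the middle point); method='endpoint' uses only the first
    and last readings.  The blank chamber's slope, when given, is
    subtracted to remove ambient drift.
    """
    def slope_of(s: IncubationSeries) -> float:
        t = np.array([r[0] for r in s.readings]) / 60.0  # hours
        y = np.array([r[1] for r in s.readings])
        if method == "ols":
            return float(np.polyfit(t, y, 1)[0])
        if method == "endpoint":
            return float((y[-1] - y[0]) / (t[-1] - t[0]))
        raise ValueError("method must be 'ols' or 'endpoint'")

    s = slope_of(series)
    if blank_series is not None:
        if blank_series.phase != series.phase:
            raise ValueError("blank and sample series must share a phase")
        s -= slope_of(blank_series)
    return s


def incubation_rate(
    slope: float,
    chamber_volume_ml: float,
    coral_volume_ml: float,
    surface_area: float,
) -> float:
    """Areal O2 flux, umol O2 cm-2 h-1: slope * (V_chamber - V_coral) / SA
    with the net water volume in litres."""
    if not chamber_volume_ml > coral_volume_ml >= 0:
        raise ValueError("need chamber volume > coral volume >= 0")
    if surface_area <= 0:
        raise ValueError("surface area must be positive")
    return slope * (chamber_volume_ml - coral_volume_ml) / 1000.0 / surface_area


def gross_photosynthesis(pn: float, r: float) -> tuple[float, float]:
    """Gross photosynthesis and the Pg:R ratio.

    Pg = Pn - R with R <= 0 under the consumption-negative convention, so
    Pg >= Pn.  Returns (Pg, Pg/|R|); the ratio is NaN (with a log record)
    when R = 0, and a positive dark slope (R > 0) is flagged.
    """
    if r > 0:
        logger.warning("positive dark slope (R = %.3g): O2 produced in the dark?", r)
    pg = pn - r
    if r == 0:
        logger.warning("R = 0: Pg:R undefined, reported as NaN")
        return pg, math.nan
    return pg, pg / abs(r)


@dataclass
class MetabolicResult:
    """Per-nubbin rates.  Units: calcification mg CaCO3 cm-2 d-1; Pn, R,
    Pg umol O2 cm-2 h-1."""

    nubbin_id: str
    origin_site: str
    transplant_site: str
    calcification: float | None = None
    Pn: float | None = None
    R: float | None = None
    Pg: float | None = None
    Pg_to_R: float | None = None


class TransplantExperiment:
    """Reciprocal-transplant metabolic assay.

    Parameters
    ----------
    nubbins : DataFrame with columns nubbin_id, colony_id, origin_site,
        transplant_site, buoyant_weight_initial_g, buoyant_weight_final_g,
        duration_days, surface_area_cm2 and optionally
        seawater_density_g_cm3.
    incubations : optional long-format DataFrame with columns nubbin_id,
        phase ('light'|'dark'), chamber_volume_ml, coral_volume_ml,
        time_min, o2_umol_l, is_blank.
    slope_method : 'ols' | 'endpoint'.
    blank_correction : subtract the control-chamber slope (default True
        when blanks are present).
    """

    def __init__(
        self,
        nubbins: pd.DataFrame,
        incubations: pd.DataFrame | None = None,
        *,
        slope_method: str = "ols",
        blank_correction: bool = True,
        skeletal_density: float = ARAGONITE_DENSITY,
    ):
        required = {
            "nubbin_id", "colony_id", "origin_site", "transplant_site",
            "buoyant_weight_initial_g", "buoyant_weight_final_g",
            "duration_days", "surface_area_cm2",
        }
        missing = required - set(nubbins.columns)
        if missing:
            raise ValueError(f"nubbin table missing columns: {sorted(missing)}")
        self.nubbins = nubbins.copy()
        self.incubations = None if incubations is None else incubations.copy()
        if self.incubations is not None and "is_blank" not in self.incubations:
            self.incubations["is_blank"] = False
        self.slope_method = slope_method
        self.blank_correction = blank_correction
        self.skeletal_density = skeletal_density

    @classmethod
    def from_tables(cls, nubbins, incubations=None, **kw):
        return cls(nubbins, incubations, **kw)

    def _series_for(self, sub: pd.DataFrame) -> IncubationSeries:
        first = sub.iloc[0]
        return IncubationSeries(
            nubbin_id=str(first.nubbin_id),
            phase=first.phase,
            chamber_volume_ml=float(first.chamber_volume_ml),
            coral_volume_ml=float(first.coral_volume_ml),
            readings=tuple(
                (float(t), float(o)) for t, o in
                sorted(zip(sub.time_min, sub.o2_umol_l))
            ),
            is_blank=bool(first.get("is_blank", False)),
        )

    def fit(self) -> "TransplantResults":
        rows = []
        inc = self.incubations
        blanks: dict[str, IncubationSeries] = {}
        if inc is not None and self.blank_correction:
            for phase, sub in inc[inc.is_blank].groupby("phase"):
                blanks[phase] = self._series_for(sub)

        for rec in self.nubbins.itertuples():
            density = getattr(rec, "seawater_density_g_cm3", 1.023)
            nr = NubbinRecord(
                nubbin_id=str(rec.nubbin_id), colony_id=str(rec.colony_id),
                origin_site=rec.origin_site, transplant_site=rec.transplant_site,
                buoyant_weight_initial=rec.buoyant_weight_initial_g,
                buoyant_weight_final=rec.buoyant_weight_final_g,
                duration_days=rec.duration_days,
                surface_area=rec.surface_area_cm2,
                seawater_density_at_weighing=density,
            )
            res = MetabolicResult(
                nubbin_id=nr.nubbin_id, origin_site=nr.origin_site,
                transplant_site=nr.transplant_site,
                calcification=calcification_rate(nr),
            )
            if inc is not None:
                mine = inc[(inc.nubbin_id.astype(str) == nr.nubbin_id)
                           & ~inc.is_blank]
                rates = {}
                for phase, sub in mine.groupby("phase"):
                    series = self._series_for(sub)
                    slope = o2_slope(series, blanks.get(phase), self.slope_method)
                    rates[phase] = incubation_rate(
                        slope, series.chamber_volume_ml,
                        series.coral_volume_ml, nr.surface_area,
                    )
                if "light" in rates:
                    res.Pn = rates["light"]
                if "dark" in rates:
                    res.R = rates["dark"]
                if res.Pn is not None and res.R is not None:
                    res.Pg, res.Pg_to_R = gross_photosynthesis(res.Pn, res.R)
            rows.append(res)
        return TransplantResults(model=self, results=rows)


@dataclass
class TransplantResults:
    """Per-nubbin metabolic rates with origin/transplant labels."""

    model: TransplantExperiment
    results: list[MetabolicResult]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "nubbin_id": r.nubbin_id,
                    "origin_site": r.origin_site,
                    "transplant_site": r.transplant_site,
                    "calcification_mg_cm2_d": r.calcification,
                    "pn_umol_cm2_h": r.Pn,
                    "r_umol_cm2_h": r.R,
                    "pg_umol_cm2_h": r.Pg,
                    "pg_to_r": r.Pg_to_R,
                }
                for r in self.results
            ]
        )

    def group_means(self) -> pd.DataFrame:
        """Mean, SD, SE and n per origin x transplant group."""
        df = self.to_frame()
        value_cols = [c for c in df.columns if c.endswith(("_d", "_h", "_to_r"))]
        g = df.groupby(["origin_site", "transplant_site"])[value_cols]
        out = g.agg(["mean", "std", "count"])
        for col in value_cols:
            out[(col, "se")] = out[(col, "std")] / np.sqrt(out[(col, "count")])
        return out.sort_index(axis=1)

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Reciprocal transplant metabolic rates",
            "=" * 60,
            f"nubbins: {len(df)}  "
            f"(with incubations: {int(df.pn_umol_cm2_h.notna().sum())})",
        ]
        gm = self.group_means()
        for (origin, site), row in gm.iterrows():
            lines.append(
                f"origin {origin} -> site {site}: "
                f"G = {row[('calcification_mg_cm2_d', 'mean')]:.3f} "
                f"+/- {row[('calcification_mg_cm2_d', 'se')]:.3f} mg cm-2 d-1"
                + (
                    f", Pg:R = {row[('pg_to_r', 'mean')]:.2f}"
                    if not np.isnan(row[("pg_to_r", "mean")])
                    else ""
                )
            )
        return "\n".join(lines)
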