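"""Ground-truth synthetic data for every pipeline stage.

Each generator is the exact inverse of its estimator: a bay station table
is produced from prescribed net calcification and production rates by
running the residence-time box model backwards, transplant tables from
prescribed per-group metabolic rates via the Archimedes and chamber
equations, and point-count tables from prescribed percent cover.  With
all noise terms at zero the corresponding estimator recovers the
generating parameters to machine precision, which anchors the test suite;
with realistic noise the generators emulate the field campaign: ~40
stations sampled at sunset and sunrise with titrator-grade TA/DIC noise,
12 colonies per origin reciprocally transplanted for 18 days, and
five 50-photo transects of 5-point annotations per site.

All randomness flows from a single scenario seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .budget import BayGeometry
from .metabolism import ARAGONITE_DENSITY, buoyant_to_dry_weight

__all__ = [
    "BayScenario",
    "generate_bay",
    "generate_transplant",
    "generate_point_counts",
    "DEFAULT_GROUP_RATES",
]


@dataclass(frozen=True)
class BayScenario:
    """Prescription of a two-end-member bay.

    Defaults mirror the study conditions the package is built around: a
    71-day residence time over an 18 m deep bay, reference salinity 33.02,
    net calcification 22.7 mmol CaCO3 m-2 d-1 and net production
    -6.9 mmol C m-2 d-1, sampled at 37 interior and 3 offshore stations at
    sunset and sunrise (74 interior samples), with TA/DIC measurement noise
    at the titrator accuracies (2 and 3 umol kg-1).
    """

    true_Gn: float = 22.7              # mmol CaCO3 m-2 d-1
    true_Pn: float = -6.9              # mmol C m-2 d-1
    geometry: BayGeometry = field(
        default_factory=lambda: BayGeometry(
            residence_time_days=71.0, mean_depth_m=18.0,
            reference_salinity=33.02, mean_temperature=30.0,
        )
    )
    end_member_nTA: float = 2250.0     # umol kg-1 at S_ref
    end_member_nDIC: float = 1930.0
    n_interior_sites: int = 37
    n_offshore_sites: int = 3
    diel_amplitude_TA: float = 0.0     # umol kg-1, half day-night range
    diel_amplitude_DIC: float = 0.0
    noise_sd_TA: float = 0.0           # umol kg-1 per sample
    noise_sd_DIC: float = 0.0
    salinity_spread: float = 0.0       # SD of per-station salinity
    interior_temperature: float = 31.8
    offshore_temperature: float = 30.4
    seed: int = 0

    def __post_init__(self):
        if self.n_interior_sites < 1:
            raise ValueError("need at least one interior site")
        if min(self.noise_sd_TA, self.noise_sd_DIC, self.salinity_spread) < 0:
            raise ValueError("noise SDs must be non-negative")

    @property
    def interior_nTA(self) -> float:
        """Normalized interior TA implied by true_Gn via the box model."""
        g = self.geometry
        dta = (
            -2000.0 * self.true_Gn * g.residence_time_days
            / (g.seawater_density * g.mean_depth_m)
        )
        return self.end_member_nTA + dta

    @property
    def interior_nDIC(self) -> float:
        """Normalized interior DIC implied by (true_Gn, true_Pn)."""
        g = self.geometry
        dta = self.interior_nTA - self.end_member_nTA
        ddic_org = (
            -1000.0 * self.true_Pn * g.residence_time_days
            / (g.seawater_density * g.mean_depth_m)
        )
        return self.end_member_nDIC + dta / 2.0 + ddic_org


def generate_bay(scenario: BayScenario) -> pd.DataFrame:
    """Station table for a prescribed bay, schema-compatible with
    :class:`~baycarb.budget.CarbonBudgetModel`.

    Sunset ('day') samples sit at mean minus the diel amplitude and
    sunrise ('night') samples at mean plus it, so the per-site midpoint
    equals the daily mean by construction.  Normalized values are
    de-normalized to each station's salinity before noise is added, making
    the table look like raw bottle data.
    """
    sc = scenario
    if sc.interior_nTA <= 0 or sc.interior_nDIC <= 0:
        raise ValueError(
            "scenario implies non-positive interior TA/DIC; "
            "rates too large for the end member"
        )
    ss = np.random.SeedSequence(sc.seed)
    rng_sal, rng_ta, rng_dic = (np.random.default_rng(s) for s in ss.spawn(3))
    s_ref = sc.geometry.reference_salinity

    rows = []
    groups = [
        ("N", "bay_interior", sc.n_interior_sites,
         sc.interior_nTA, sc.interior_nDIC, sc.interior_temperature),
        ("OFF", "end_member", sc.n_offshore_sites,
         sc.end_member_nTA, sc.end_member_nDIC, sc.offshore_temperature),
    ]
    for prefix, role, n_sites, nta, ndic, temp in groups:
        for i in range(n_sites):
            sal = s_ref + (
                rng_sal.normal(0.0, sc.salinity_spread)
                if sc.salinity_spread > 0 else 0.0
            )
            for phase, sign in (("day", -1.0), ("night", +1.0)):
                nta_p = nta + sign * sc.diel_amplitude_TA
                ndic_p = ndic + sign * sc.diel_amplitude_DIC
                ta = nta_p * sal / s_ref
                dic = ndic_p * sal / s_ref
                if sc.noise_sd_TA > 0:
                    ta += rng_ta.normal(0.0, sc.noise_sd_TA)
                if sc.noise_sd_DIC > 0:
                    dic += rng_dic.normal(0.0, sc.noise_sd_DIC)
                rows.append(
                    {
                        "site_id": f"{prefix}{i + 1:02d}",
                        "phase": phase,
                        "salinity": sal,
                        "temperature_c": temp,
                        "ta_umol_kg": ta,
                        "dic_umol_kg": dic,
                        "station_role": role,
                    }
                )
    return pd.DataFrame(rows)


#: per-group (origin, transplant) true rates for the reciprocal design:
#: calcification mg CaCO3 cm-2 d-1; Pn, R umol O2 cm-2 h-1 (R negative).
#: Reference-origin corals lose calcification when moved to the high-CO2
#: bay; respiration is lowest (least negative) at the origin site.
DEFAULT_GROUP_RATES: dict[tuple[str, str], dict[str, float]] = {
    ("M1", "M1"): {"calcification": 1.40, "Pn": 0.95, "R": -0.40},
    ("M1", "N5"): {"calcification": 0.60, "Pn": 1.15, "R": -0.60},
    ("N5", "M1"): {"calcification": 1.05, "Pn": 0.90, "R": -0.55},
    ("N5", "N5"): {"calcification": 1.10, "Pn": 1.20, "R": -0.45},
}


def generate_transplant(
    true_rates_per_group: dict[tuple[str, str], dict[str, float]] | None = None,
    n_colonies: int = 12,
    *,
    n_incubated: int = 9,
    duration_days: float = 18.0,
    chamber_volume_ml: float = 400.0,
    seawater_density_g_cm3: float = 1.023,
    blank_drift_umol_l_h: float = 0.3,
    weight_noise_g: float = 0.0,
    o2_noise_umol_l: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nubbin and incubation tables for a reciprocal transplant with known
    true rates.

    One nubbin per colony per transplant site; buoyant weights follow from
    the prescribed calcification via the Archimedes conversion, and O2
    readings at 0/20/40 min are linear with the slope implied by the
    prescribed Pn (light) and R (dark) plus the shared blank drift.  The
    first ``n_incubated`` nubbins of each group get incubation series; a
    coral-free blank chamber is included per phase.  ``weight_noise_g`` and
    ``o2_noise_umol_l`` add Gaussian measurement noise; at zero the
    estimators invert the tables exactly (with blank correction on).
    """
    rates = DEFAULT_GROUP_RATES if true_rates_per_group is None else true_rates_per_group
    ss = np.random.SeedSequence(seed)
    rng_geom, rng_w, rng_o2 = (np.random.default_rng(s) for s in ss.spawn(3))

    nubbin_rows, inc_rows = [], []
    for (origin, site), r in sorted(rates.items()):
        for j in range(n_colonies):
            nid = f"{origin}_{site}_{j + 1:02d}"
            sa = rng_geom.uniform(8.0, 15.0)                  # cm2
            dry0 = rng_geom.uniform(8.0, 15.0)                # g
            v_coral = rng_geom.uniform(10.0, 20.0)            # ml
            dry1 = dry0 + r["calcification"] * sa * duration_days / 1000.0
            factor = 1.0 - seawater_density_g_cm3 / ARAGONITE_DENSITY
            w0, w1 = dry0 * factor, dry1 * factor
            if weight_noise_g > 0:
                w0 += rng_w.normal(0.0, weight_noise_g)
                w1 += rng_w.normal(0.0, weight_noise_g)
            nubbin_rows.append(
                {
                    "nubbin_id": nid,
                    "colony_id": f"{origin}_{j + 1:02d}",
                    "origin_site": origin,
                    "transplant_site": site,
                    "buoyant_weight_initial_g": w0,
                    "buoyant_weight_final_g": w1,
                    "duration_days": duration_days,
                    "surface_area_cm2": sa,
                    "seawater_density_g_cm3": seawater_density_g_cm3,
                }
            )
            if j < n_incubated:
                for phase, rate in (("light", r["Pn"]), ("dark", r["R"])):
                    slope = (
                        rate * sa / ((chamber_volume_ml - v_coral) / 1000.0)
                        + blank_drift_umol_l_h
                    )
                    o2_0 = 205.0 if phase == "light" else 215.0
                    for t in (0.0, 20.0, 40.0):
                        o2 = o2_0 + slope * t / 60.0
                        if o2_noise_umol_l > 0:
                            o2 += rng_o2.normal(0.0, o2_noise_umol_l)
                        inc_rows.append(
                            {
                                "nubbin_id": nid,
                                "phase": phase,
                                "chamber_volume_ml": chamber_volume_ml,
                                "coral_volume_ml": v_coral,
                                "time_min": t,
                                "o2_umol_l": o2,
                                "is_blank": False,
                            }
                        )
    # coral-free control chamber per phase, drifting at the blank rate
    for phase in ("light", "dark"):
        o2_0 = 205.0 if phase == "light" else 215.0
        for t in (0.0, 20.0, 40.0):
            o2 = o2_0 + blank_drift_umol_l_h * t / 60.0
            if o2_noise_umol_l > 0:
                o2 += rng_o2.normal(0.0, o2_noise_umol_l)
            inc_rows.append(
                {
                    "nubbin_id": f"blank_{phase}",
                    "phase": phase,
                    "chamber_volume_ml": chamber_volume_ml,
                    "coral_volume_ml": 0.0,
                    "time_min": t,
                    "o2_umol_l": o2,
                    "is_blank": True,
                }
            )
    return pd.DataFrame(nubbin_rows), pd.DataFrame(inc_rows)


def generate_point_counts(
    cover_by_site: dict[str, dict[str, float]],
    *,
    n_transects: int = 5,
    n_photos: int = 50,
    points_per_photo: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Annotation table with categories drawn per point from the
    prescribed site cover fractions (percent; normalized internally)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for site, cover in sorted(cover_by_site.items()):
        cats = sorted(cover)
        p = np.array([cover[c] for c in cats], dtype=float)
        if np.any(p < 0) or p.sum() <= 0:
            raise ValueError(f"invalid cover prescription for site {site}")
        p = p / p.sum()
        for t in range(1, n_transects + 1):
            for ph in range(1, n_photos + 1):
                draws = rng.choice(len(cats), size=points_per_photo, p=p)
                for k, ci in enumerate(draws, start=1):
                    rows.append(
                        {
                            "site_id": site,
                            "transect_id": f"{site}_T{t}",
                            "photo_id": f"{site}_T{t}_P{ph:03d}",
                            "point_index": k,
                            "category": cats[ci],
                        }
                    )
    return pd.DataFrame(rows)
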