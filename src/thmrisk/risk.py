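"""Dose and cancer-risk arithmetic for the three exposure routes.

Ingestion and dermal exposure are expressed as chronic daily intakes (CDI,
mg kg⁻¹ day⁻¹) multiplied by an oral cancer slope factor; inhalation is
expressed as a time-weighted exposure concentration (EC, µg/m³) multiplied by
an inhalation unit risk.  The heated-water adjustment raises the water
concentration seen by the dermal and inhalation routes (hot showers both
volatilize more and keep forming THM in the presence of residual chlorine);
drinking water is taken cold and needs no adjustment.

All operations accept scalars or equal-length numpy arrays and are
elementwise, which is what lets the Monte Carlo pipeline stay vectorized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .species import ROUTES, SPECIES
from .units import MINUTES_PER_HOUR, UG_TO_MG

__all__ = [
    "surface_area",
    "formation_rate",
    "heated_concentration",
    "cdi_ingestion",
    "cdi_dermal",
    "exposure_time",
    "exposure_concentration",
    "cancer_risk_oral",
    "cancer_risk_inhalation",
    "RiskTotals",
    "total_risk",
]


def _check_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError(f"{name} must be > 0")
    return arr


def surface_area(bw):
    """Body surface area (m²) from body weight (kg): (4·BW + 7)/(BW + 90)."""
    bw = _check_positive("bw", bw)
    return (4.0 * bw + 7.0) / (bw + 90.0)


def formation_rate(temp):
    """THM formation rate constant k (min⁻¹) at water temperature T (°C).

    k = 0.0011 · e^(0.0407·T); guarded to liquid-water temperatures.
    """
    temp = np.asarray(temp, dtype=float)
    if np.any((temp < 0) | (temp > 100)):
        raise ValueError("temperature must be within 0-100 °C")
    return 0.0011 * np.exp(0.0407 * temp)


def heated_concentration(cw, t, temp_hot, temp_cold):
    """THM concentration in heated water: Chw = Cw · e^((kh − kc)·t).

    ``kh`` and ``kc`` are the formation rates at the hot and cold water
    temperatures; ``t`` is the shower duration (min).  Chw >= Cw whenever the
    hot temperature is at least the cold one.
    """
    cw = np.asarray(cw, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    kh = formation_rate(temp_hot)
    kc = formation_rate(temp_cold)
    return cw * np.exp((kh - kc) * t)


def cdi_ingestion(cw, ir, ef, ed, bw, at):
    """Ingestion chronic daily intake (mg kg⁻¹ day⁻¹).

    CDI = Cw · IR · EF · ED · CF / (BW · AT) with Cw in µg/L, IR in L/day,
    EF in day/yr, ED in yr, BW in kg, AT in days and CF = 0.001 (µg → mg).
    """
    bw = _check_positive("bw", bw)
    at = _check_positive("at", at)
    cw = np.asarray(cw, dtype=float)
    return cw * np.asarray(ir, float) * np.asarray(ef, float) * np.asarray(ed, float) \
        * UG_TO_MG / (bw * at)


def cdi_dermal(chw, sa, pd_skin, t, f, ef, ed, bw, at):
    """Dermal chronic daily intake (mg kg⁻¹ day⁻¹).

    CDI = Chw · SA · Pd · t · F · EF · ED / (BW · AT) with Chw in µg/L, SA in
    m², Pd in m/min, t in min/event, F in events/day.  The implicit L→m³
    (×1000) and µg→mg (×0.001) conversions cancel, so the printed product
    applied to Chw in µg/L yields mg kg⁻¹ day⁻¹ directly.
    """
    bw = _check_positive("bw", bw)
    at = _check_positive("at", at)
    return (
        np.asarray(chw, float)
        * np.asarray(sa, float)
        * np.asarray(pd_skin, float)
        * np.asarray(t, float)
        * np.asarray(f, float)
        * np.asarray(ef, float)
        * np.asarray(ed, float)
        / (bw * at)
    )


def exposure_time(t, f):
    """Daily exposure time in the stall (h/day): ET = t · F / 60."""
    t = np.asarray(t, dtype=float)
    f = np.asarray(f, dtype=float)
    if np.any(t < 0) or np.any(f < 0):
        raise ValueError("t and f must be >= 0")
    return t * f / MINUTES_PER_HOUR


def exposure_concentration(cair, et, ef, ed, at_hours):
    """Time-weighted inhalation exposure concentration (µg/m³).

    EC = Cair · ET · EF · ED / AT with Cair in µg/m³, ET in h/day, EF in
    day/yr, ED in yr and the averaging time AT in **hours**.
    """
    at_hours = _check_positive("at_hours", at_hours)
    return (
        np.asarray(cair, float)
        * np.asarray(et, float)
        * np.asarray(ef, float)
        * np.asarray(ed, float)
        / at_hours
    )


def cancer_risk_oral(cdi, csf):
    """Incremental lifetime cancer risk from an oral-route dose: CR = CDI · CSF."""
    cdi = np.asarray(cdi, dtype=float)
    csf = np.asarray(csf, dtype=float)
    if np.any(cdi < 0) or np.any(csf < 0):
        raise ValueError("cdi and csf must be >= 0")
    return cdi * csf


def cancer_risk_inhalation(ec, iur):
    """Incremental lifetime cancer risk from inhalation: CR = EC · IUR."""
    ec = np.asarray(ec, dtype=float)
    iur = np.asarray(iur, dtype=float)
    if np.any(ec < 0) or np.any(iur < 0):
        raise ValueError("ec and iur must be >= 0")
    return ec * iur


@dataclass(frozen=True)
class RiskTotals:
    """Marginal sums of a complete species × route risk grid."""

    by_route: dict
    by_species: dict
    grand_total: object   # scalar or array, matching the grid cells


def total_risk(
    risks: Mapping[str, Mapping[str, object]],
    species: tuple[str, ...] = SPECIES,
    routes: tuple[str, ...] = ROUTES,
) -> RiskTotals:
    """Sum a per-route, per-species risk grid along both margins.

    ``risks[route][species]`` may hold scalars or aligned arrays.  The grid
    must be complete: a missing route or species cell is an error, because a
    silently partial total would understate the risk.
    """
    missing = [r for r in routes if r not in risks]
    if missing:
        raise KeyError(f"risk grid is missing route(s): {missing}")
    for route in routes:
        missing_sp = [sp for sp in species if sp not in risks[route]]
        if missing_sp:
            raise KeyError(f"route {route!r} is missing species: {missing_sp}")

    by_route = {
        route: sum(np.asarray(risks[route][sp], dtype=float) for sp in species)
        for route in routes
    }
    by_species = {
        sp: sum(np.asarray(risks[route][sp], dtype=float) for route in routes)
        for sp in species
    }
    grand = sum(by_route[route] for route in routes)
    return RiskTotals(by_route=by_route, by_species=by_species, grand_total=grand)
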