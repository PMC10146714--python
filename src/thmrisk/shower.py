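"""Shower-stall air concentration model.

A single shower event is a one-compartment mass balance

    dC/dt = a − b·C,   C(0) = 0

whose source and loss coefficients come from two-film volatilization of each
THM out of the spray (``a``) and the combined air exchange plus re-dissolution
(``b``).  The end-of-event concentration is the closed-form solution

    Ct = (1 − e^(−b·t)) · a / b

and the per-event exposure concentration is the time average approximated by
(C0 + Ct)/2.

For back-to-back events in a shared stall, the air left by one user becomes
the starting concentration for the next.  With no inter-event gap the
averaging recursion ``cair(k) = (cair(k−1) + Ct)/2`` from ``cair(0) = 0`` has
the closed form

    cair(n) = (2^n − 1)/2^n · Ct

which saturates at Ct — the second event sees a 50% higher exposure than the
first, the third 75%, never more than double.  This printed accumulation rule
is the default; an optional ``mode="ode"`` re-solves the mass balance with a
nonzero initial condition instead, for comparison studies.

All concentrations here are in µg/L, the natural unit of the mass balance
(volumes in L, flows in L/min); conversion to µg/m³ happens only at the
exposure-concentration boundary (see :mod:`thmrisk.units`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .species import SPECIES, TRANSPORT, SpeciesTransportConstants
from .units import UG_PER_L_TO_UG_PER_M3

__all__ = [
    "ShowerScenario",
    "AirState",
    "dimensionless_n",
    "volatilization_coefficients",
    "end_of_event_concentration",
    "successive_air_concentration",
    "event_series",
    "event_series_frame",
]


@dataclass(frozen=True)
class ShowerScenario:
    """Stall geometry and operating conditions for one (set of) events.

    Attributes
    ----------
    vs:
        Stall volume, L.
    qw:
        Water flow, L/min.
    qg:
        Ventilation air flow, L/min (0 = closed stall).
    t:
        Shower duration per event, min.
    n_events:
        Number of strictly back-to-back events.
    """

    vs: float
    qw: float
    qg: float
    t: float
    n_events: int = 1

    def __post_init__(self) -> None:
        if self.vs <= 0 or self.qw <= 0:
            raise ValueError("vs and qw must be > 0")
        if self.qg < 0:
            raise ValueError("qg must be >= 0")
        if self.t <= 0:
            raise ValueError("shower duration must be > 0")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


@dataclass(frozen=True)
class AirState:
    """Air concentrations around one event (all µg/L)."""

    event_index: int
    c0: float       # concentration when the user steps in
    ct: float       # end-of-event concentration
    cair: float     # event exposure concentration

    def __post_init__(self) -> None:
        if not 0 <= self.c0 <= self.cair <= self.ct + 1e-12:
            raise ValueError(
                f"inconsistent air state: c0={self.c0}, cair={self.cair}, ct={self.ct}"
            )


def dimensionless_n(kola, qw):
    """N = KoLA / Qw, the dimensionless overall mass-transfer coefficient."""
    if np.any(np.asarray(qw) <= 0):
        raise ValueError("qw must be > 0")
    return np.asarray(kola) / np.asarray(qw)


def volatilization_coefficients(
    scenario: ShowerScenario | None,
    constants: SpeciesTransportConstants,
    cw,
    *,
    vs=None,
    qw=None,
    qg=None,
):
    """Source and loss coefficients (a, b) of the event mass balance.

    ``b = (Qw/H · (1 − e^(−N)) + Qg) / Vs``  [min⁻¹]
    ``a = Qw · Cw · (1 − e^(−N)) / Vs``      [µg L⁻¹ min⁻¹]

    A :class:`ShowerScenario` supplies scalar stall conditions; the keyword
    arguments accept per-iteration arrays instead (either route, not both).
    """
    if scenario is not None:
        vs, qw, qg = scenario.vs, scenario.qw, scenario.qg
    vs = np.asarray(vs, dtype=float)
    qw = np.asarray(qw, dtype=float)
    qg = np.asarray(qg, dtype=float)
    cw = np.asarray(cw, dtype=float)
    if np.any(cw < 0):
        raise ValueError("cw must be >= 0")
    if constants.henry <= 0:
        raise ValueError("Henry's constant must be > 0")
    n = dimensionless_n(constants.kola, qw)
    stripped = -np.expm1(-n)          # 1 - e^{-N}
    b = ((qw / constants.henry) * stripped + qg) / vs
    a = qw * cw * stripped / vs
    return a, b


def end_of_event_concentration(a, b, t):
    """Closed-form solution of dC/dt = a − bC at time ``t`` from C(0)=0.

    ``Ct = (1 − e^(−b·t)) · a/b``; the ``b = 0`` cells return the ``a·t``
    limit (pure accumulation, no losses).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(b < 0):
        raise ValueError("b must be >= 0")
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        ct = -np.expm1(-b * t) * np.where(b > 0, a / np.where(b > 0, b, 1.0), 0.0)
    return np.where(b > 0, ct, a * t)


def successive_air_concentration(n: int, ct):
    """Exposure concentration at the n-th back-to-back event.

    Closed form ``(2^n − 1)/2^n · Ct`` of the averaging recursion
    ``cair(k) = (cair(k−1) + Ct)/2`` started from clean air.
    """
    if n < 1:
        raise ValueError(f"event index must be >= 1, got {n}")
    ct = np.asarray(ct, dtype=float)
    if np.any(ct < 0):
        raise ValueError("ct must be >= 0")
    factor = (2.0**n - 1.0) / 2.0**n
    return factor * ct


def event_series(
    scenario: ShowerScenario,
    cw: Mapping[str, float],
    transport: Mapping[str, SpeciesTransportConstants] | None = None,
    mode: str = "averaging",
    gap_min: float = 0.0,
) -> list[dict[str, AirState]]:
    """Per-event, per-species air states for a run of back-to-back events.

    Parameters
    ----------
    scenario:
        Stall conditions, including the number of events.
    cw:
        Water concentration per species, µg/L (heated-water values when the
        temperature adjustment applies).
    transport:
        Per-species constants; defaults to the shipped values.
    mode:
        ``"averaging"`` (default) applies the printed accumulation rule with a
        fixed per-event ``Ct``; ``"ode"`` re-solves the mass balance with the
        previous exposure concentration as initial condition.
    gap_min:
        Optional ventilation gap between events (min); the carried-over
        concentration decays by ``e^(−(Qg/Vs)·gap)``.  Default 0 (strictly
        back-to-back).

    Returns
    -------
    list of per-species dicts, one per event, in event order.
    """
    if mode not in ("averaging", "ode"):
        raise ValueError(f"mode must be 'averaging' or 'ode', got {mode!r}")
    if gap_min < 0:
        raise ValueError("gap_min must be >= 0")
    transport = dict(transport or TRANSPORT)
    decay = float(np.exp(-(scenario.qg / scenario.vs) * gap_min))

    coeffs = {}
    for sp in cw:
        a, b = volatilization_coefficients(scenario, transport[sp], cw[sp])
        coeffs[sp] = (float(a), float(b))

    series: list[dict[str, AirState]] = []
    prev_cair = {sp: 0.0 for sp in cw}
    for event in range(1, scenario.n_events + 1):
        states = {}
        for sp in cw:
            a, b = coeffs[sp]
            c0 = prev_cair[sp] * decay
            if mode == "averaging":
                ct = float(end_of_event_concentration(a, b, scenario.t))
                if gap_min == 0.0:
                    cair = float(successive_air_concentration(event, ct))
                else:
                    cair = 0.5 * (c0 + ct)
                ct_reported = ct
            else:
                # steady-state relaxation from the carried-over concentration
                cinf = a / b if b > 0 else np.inf
                if b > 0:
                    ct = float(cinf + (c0 - cinf) * np.exp(-b * scenario.t))
                else:
                    ct = c0 + a * scenario.t
                cair = 0.5 * (c0 + ct)
                ct_reported = ct
            states[sp] = AirState(event_index=event, c0=c0, ct=ct_reported, cair=cair)
            prev_cair[sp] = cair
        series.append(states)
    return series


def event_series_frame(
    scenario: ShowerScenario,
    cw: Mapping[str, float],
    **kwargs,
) -> pd.DataFrame:
    """Tidy per-event table with concentrations in both µg/L and µg/m³."""
    series = event_series(scenario, cw, **kwargs)
    rows = []
    for states in series:
        for sp in (s for s in SPECIES if s in states):
            st = states[sp]
            rows.append(
                {
                    "event": st.event_index,
                    "species": sp,
                    "c0_ugl": st.c0,
                    "ct_ugl": st.ct,
                    "cair_ugl": st.cair,
                    "c0_ugm3": st.c0 * UG_PER_L_TO_UG_PER_M3,
                    "ct_ugm3": st.ct * UG_PER_L_TO_UG_PER_M3,
                    "cair_ugm3": st.cair * UG_PER_L_TO_UG_PER_M3,
                }
            )
    return pd.DataFrame(rows)
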