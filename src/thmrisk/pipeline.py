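"""Monte Carlo orchestration, summaries, sensitivity scans and trend fits.

A run draws, per gender, one exposure-factor table and one four-species water
concentration table, pushes them through the three exposure routes, and pools
the two genders with equal weight (each gender contributes ``iterations``
draws).  Within an iteration the same person — the same parameter and
concentration draw — is used for all three routes, preserving realistic
covariation; route means are unaffected by this coupling.

Two population modes are supported:

* ``private``: only the first shower event matters for inhalation;
* ``shared``: back-to-back events S1..S10 (configurable) accumulate THM in
  the stall air, raising the inhalation term event by event while the oral
  routes stay fixed.

The duration and ventilation scans re-run the simulation on a grid with the
scanned input pinned (common random numbers across grid points) and fit
exponential trends to the per-event mean inhalation risk.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import risk as risk_ops
from .config import default_config
from .sampling import GENDERS, draw_parameters
from .shower import (
    end_of_event_concentration,
    successive_air_concentration,
    volatilization_coefficients,
)
from .species import SPECIES, SpeciesToxicity, SpeciesTransportConstants
from .units import HOURS_PER_DAY, L_PER_S_TO_L_PER_MIN, UG_PER_L_TO_UG_PER_M3
from .water import ConcentrationConfig, sample_concentrations

__all__ = [
    "RunConfig",
    "SimulationResult",
    "TrendFit",
    "simulate_draws",
    "summarize",
    "summary_frame",
    "table_frame",
    "run_private",
    "run_shared",
    "scan_duration",
    "scan_ventilation",
    "fit_trend",
]

_STAT_COLUMNS = ("mean", "sd", "min", "p10", "median", "p90", "max")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one Monte Carlo run."""

    iterations: int = 10_000
    seed: int = 0
    n_events: int = 10
    population: str = "private"          # "private" | "shared"
    config: Mapping | None = None        # merged package configuration
    couple_at_to_ed: bool = False
    accumulation: str = "averaging"      # "averaging" | "ode"
    fixed: Mapping[str, float] = field(default_factory=dict)
    concentrations: pd.DataFrame | None = None   # measured drop-in, µg/L

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 1 <= self.n_events <= 50:
            raise ValueError("n_events must be in [1, 50]")
        if self.population not in ("private", "shared"):
            raise ValueError("population must be 'private' or 'shared'")
        if self.accumulation not in ("averaging", "ode"):
            raise ValueError("accumulation must be 'averaging' or 'ode'")

    @property
    def events(self) -> tuple[int, ...]:
        if self.population == "private":
            return (1,)
        return tuple(range(1, self.n_events + 1))

    def resolved_config(self) -> Mapping:
        return self.config if self.config is not None else default_config()


@dataclass
class SimulationResult:
    """Pooled per-iteration draws of doses and risks.

    Array values have length ``2 × iterations`` (female draws first, then
    male).  ``cdi[route][species]`` holds oral doses, ``ec[event][species]``
    inhalation exposure concentrations, ``cr_oral[route][species]`` and
    ``cr_inhalation[event][species]`` the corresponding risks.
    """

    run: RunConfig
    gender: np.ndarray
    parameters: pd.DataFrame
    concentrations: pd.DataFrame
    cdi: dict
    cr_oral: dict
    ec: dict
    cr_inhalation: dict

    def oral_cr_total(self) -> np.ndarray:
        """Per-iteration ingestion + dermal risk summed over species."""
        return sum(
            self.cr_oral[route][sp] for route in ("ingestion", "dermal") for sp in SPECIES
        )

    def inhalation_cr_total(self, event: int) -> np.ndarray:
        return sum(self.cr_inhalation[event][sp] for sp in SPECIES)

    def grand_total(self, event: int) -> np.ndarray:
        """All-route risk when the receptor takes the ``event``-th shower."""
        return self.oral_cr_total() + self.inhalation_cr_total(event)

    def risk_grid(self, event: int) -> dict:
        """Complete species × route per-iteration risk grid for one event."""
        return {
            "ingestion": dict(self.cr_oral["ingestion"]),
            "dermal": dict(self.cr_oral["dermal"]),
            "inhalation": dict(self.cr_inhalation[event]),
        }

    def tidy_frame(self) -> pd.DataFrame:
        """Long-format draws: iteration, gender, species, route, event, dose, cr."""
        n = self.gender.size
        iteration = np.arange(n)
        blocks = []
        for route in ("ingestion", "dermal"):
            for sp in SPECIES:
                blocks.append(
                    pd.DataFrame(
                        {
                            "iteration": iteration,
                            "gender": self.gender,
                            "species": sp,
                            "route": route,
                            "event": 0,
                            "dose": self.cdi[route][sp],
                            "cr": self.cr_oral[route][sp],
                        }
                    )
                )
        for event in self.run.events:
            for sp in SPECIES:
                blocks.append(
                    pd.DataFrame(
                        {
                            "iteration": iteration,
                            "gender": self.gender,
                            "species": sp,
                            "route": "inhalation",
                            "event": event,
                            "dose": self.ec[event][sp],
                            "cr": self.cr_inhalation[event][sp],
                        }
                    )
                )
        return pd.concat(blocks, ignore_index=True)


def _transport_from_config(cfg: Mapping) -> dict[str, SpeciesTransportConstants]:
    constants = cfg["constants"]
    return {
        sp: SpeciesTransportConstants(
            henry=float(constants["henry"][sp]), kola=float(constants["kola"][sp])
        )
        for sp in SPECIES
    }


def _toxicity_from_config(cfg: Mapping) -> dict[str, SpeciesToxicity]:
    constants = cfg["constants"]
    return {
        sp: SpeciesToxicity(
            csf_oral=float(constants["csf_oral"][sp]), iur=float(constants["iur"][sp])
        )
        for sp in SPECIES
    }


def _concentration_rows(
    run: RunConfig, conc_cfg: ConcentrationConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    if run.concentrations is None:
        return sample_concentrations(conc_cfg, n, rng)
    table = run.concentrations[list(SPECIES)].to_numpy(dtype=float)
    # bootstrap measured rows up to the requested iteration count
    idx = rng.integers(0, table.shape[0], size=n)
    return pd.DataFrame(table[idx], columns=list(SPECIES))


def simulate_draws(run: RunConfig) -> SimulationResult:
    """Execute the full Monte Carlo for both genders and pool the draws."""
    cfg = run.resolved_config()
    transport = _transport_from_config(cfg)
    toxicity = _toxicity_from_config(cfg)
    conc_cfg = ConcentrationConfig.from_config(cfg)
    events = run.events

    gender_blocks = []
    seeds = np.random.SeedSequence(run.seed).spawn(len(GENDERS))
    for gender, seed in zip(GENDERS, seeds):
        rng = np.random.default_rng(seed)
        params = draw_parameters(
            cfg["parameters"],
            run.iterations,
            gender,
            rng,
            couple_at_to_ed=run.couple_at_to_ed,
            fixed=run.fixed,
        )
        conc = _concentration_rows(run, conc_cfg, run.iterations, rng)
        gender_blocks.append((gender, params, conc))

    parameters = pd.concat([b[1] for b in gender_blocks], ignore_index=True)
    concentrations = pd.concat([b[2] for b in gender_blocks], ignore_index=True)
    gender = parameters["gender"].to_numpy()

    p = {name: parameters[name].to_numpy() for name in parameters.columns if name != "gender"}
    sa = risk_ops.surface_area(p["bw"])
    et = risk_ops.exposure_time(p["t"], p["f"])
    at_hours = p["at"] * HOURS_PER_DAY

    cdi = {"ingestion": {}, "dermal": {}}
    cr_oral = {"ingestion": {}, "dermal": {}}
    ec: dict[int, dict[str, np.ndarray]] = {e: {} for e in events}
    cr_inh: dict[int, dict[str, np.ndarray]] = {e: {} for e in events}

    for sp in SPECIES:
        cw = concentrations[sp].to_numpy()
        chw = risk_ops.heated_concentration(cw, p["t"], p["t_hot"], p["t_cold"])

        dose_ing = risk_ops.cdi_ingestion(
            cw, p["ir"], p["ef_ing"], p["ed"], p["bw"], p["at"]
        )
        dose_der = risk_ops.cdi_dermal(
            chw, sa, p["pd"], p["t"], p["f"], p["ef_der"], p["ed"], p["bw"], p["at"]
        )
        cdi["ingestion"][sp] = dose_ing
        cdi["dermal"][sp] = dose_der
        cr_oral["ingestion"][sp] = risk_ops.cancer_risk_oral(
            dose_ing, toxicity[sp].csf_oral
        )
        cr_oral["dermal"][sp] = risk_ops.cancer_risk_oral(
            dose_der, toxicity[sp].csf_oral
        )

        a, b = volatilization_coefficients(
            None, transport[sp], chw, vs=p["vs"], qw=p["qw"], qg=p["qg"]
        )
        ct = end_of_event_concentration(a, b, p["t"])
        c0 = np.zeros_like(ct)
        for event in events:
            if run.accumulation == "averaging":
                cair_l = successive_air_concentration(event, ct)
            else:
                with np.errstate(divide="ignore", invalid="ignore"):
                    cinf = np.where(b > 0, a / np.where(b > 0, b, 1.0), np.inf)
                ct_ev = np.where(
                    b > 0,
                    cinf + (c0 - cinf) * np.exp(-b * p["t"]),
                    c0 + a * p["t"],
                )
                cair_l = 0.5 * (c0 + ct_ev)
                c0 = cair_l
            cair_m3 = cair_l * UG_PER_L_TO_UG_PER_M3
            ec_sp = risk_ops.exposure_concentration(
                cair_m3, et, p["ef_inh"], p["ed"], at_hours
            )
            ec[event][sp] = ec_sp
            cr_inh[event][sp] = risk_ops.cancer_risk_inhalation(
                ec_sp, toxicity[sp].iur
            )

    return SimulationResult(
        run=run,
        gender=gender,
        parameters=parameters,
        concentrations=concentrations,
        cdi=cdi,
        cr_oral=cr_oral,
        ec=ec,
        cr_inhalation=cr_inh,
    )


def summarize(draws) -> dict[str, float]:
    """Distributional summary of a draw vector.

    Percentiles use linear interpolation between order statistics (the numpy
    default); ``sd`` is the sample standard deviation (0 for a single draw).
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot summarize an empty draw vector")
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "p10": float(np.percentile(arr, 10)),
        "median": float(np.percentile(arr, 50)),
        "p90": float(np.percentile(arr, 90)),
        "max": float(arr.max()),
    }


def _summary_row(route, species, event, metric, draws) -> dict:
    row = {"route": route, "species": species, "event": event, "metric": metric}
    row.update(summarize(draws))
    return row


def summary_frame(result: SimulationResult) -> pd.DataFrame:
    """Per-route, per-species, per-event summary of doses and risks."""
    rows = []
    for route, dose_metric in (("ingestion", "cdi"), ("dermal", "cdi")):
        for sp in SPECIES:
            rows.append(_summary_row(route, sp, 0, dose_metric, result.cdi[route][sp]))
            rows.append(_summary_row(route, sp, 0, "cr", result.cr_oral[route][sp]))
        rows.append(
            _summary_row(
                route, "total", 0, "cr",
                sum(result.cr_oral[route][sp] for sp in SPECIES),
            )
        )
    for event in result.run.events:
        for sp in SPECIES:
            rows.append(_summary_row("inhalation", sp, event, "ec", result.ec[event][sp]))
            rows.append(
                _summary_row("inhalation", sp, event, "cr", result.cr_inhalation[event][sp])
            )
        rows.append(
            _summary_row("inhalation", "total", event, "cr", result.inhalation_cr_total(event))
        )
        rows.append(
            _summary_row("total", "total", event, "cr", result.grand_total(event))
        )
    frame = pd.DataFrame(rows)
    return frame[["route", "species", "event", "metric", *_STAT_COLUMNS]]


def table_frame(result: SimulationResult, scale: float = 1e6) -> pd.DataFrame:
    """Wide per-species mean-risk table (scaled, default ×10⁶).

    Columns: ingestion, dermal, one inhalation column per event, and one
    all-route total column per event; rows: species plus ``total``.
    """
    events = result.run.events
    rows = {}
    for sp in [*SPECIES, "total"]:
        if sp == "total":
            ing = sum(result.cr_oral["ingestion"][s] for s in SPECIES)
            der = sum(result.cr_oral["dermal"][s] for s in SPECIES)
            inh = {e: result.inhalation_cr_total(e) for e in events}
        else:
            ing = result.cr_oral["ingestion"][sp]
            der = result.cr_oral["dermal"][sp]
            inh = {e: result.cr_inhalation[e][sp] for e in events}
        row = {"ingestion": ing.mean() * scale, "dermal": der.mean() * scale}
        for e in events:
            row[f"inhalation_s{e}"] = inh[e].mean() * scale
        for e in events:
            row[f"total_s{e}"] = (ing.mean() + der.mean() + inh[e].mean()) * scale
        rows[sp] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "species"
    return frame


def run_private(run: RunConfig) -> pd.DataFrame:
    """Monte Carlo summary for private stalls (single shower event)."""
    if run.population != "private":
        run = dataclasses.replace(run, population="private")
    return summary_frame(simulate_draws(run))


def run_shared(run: RunConfig) -> pd.DataFrame:
    """Monte Carlo summary for shared stalls (per-event S1..Sn rows)."""
    if run.population != "shared":
        run = dataclasses.replace(run, population="shared")
    return summary_frame(simulate_draws(run))


@dataclass(frozen=True)
class TrendFit:
    """Least-squares trend on a linearized scale.

    ``form == "exponential"``: y = a · e^(b·x), fitted as ln y against x.
    ``form == "logarithmic"``: y = a · ln(x) + b, fitted as y against ln x.
    ``r2`` is the coefficient of determination on the linearized scale.
    """

    form: str
    a: float
    b: float
    r2: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        if self.form == "exponential":
            return self.a * np.exp(self.b * x)
        return self.a * np.log(x) + self.b


def fit_trend(x, y, form: str) -> TrendFit:
    """Fit an exponential or logarithmic trend by linearized least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 aligned (x, y) points")
    if form == "exponential":
        if np.any(y <= 0):
            raise ValueError("exponential form requires all y > 0")
        design_x, target = x, np.log(y)
        slope, intercept = np.polyfit(design_x, target, 1)
        a, b = float(np.exp(intercept)), float(slope)
    elif form == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic form requires all x > 0")
        design_x, target = np.log(x), y
        slope, intercept = np.polyfit(design_x, target, 1)
        a, b = float(slope), float(intercept)
    else:
        raise ValueError(f"unknown trend form {form!r}")
    fitted = slope * design_x + intercept
    ss_res = float(np.sum((target - fitted) ** 2))
    ss_tot = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return TrendFit(form=form, a=a, b=b, r2=float(r2))


def _scan(
    run: RunConfig,
    parameter: str,
    column: str,
    grid_values: Sequence[float],
    fixed_values: Sequence[float],
    events: Iterable[int],
) -> tuple[pd.DataFrame, dict[int, TrendFit]]:
    events = tuple(events)
    if not grid_values:
        raise ValueError("scan grid must not be empty")
    max_event = max(events)
    rows = []
    for grid_value, fixed_value in zip(grid_values, fixed_values):
        scan_run = dataclasses.replace(
            run,
            population="shared",
            n_events=max_event,
            fixed={**dict(run.fixed), parameter: fixed_value},
        )
        result = simulate_draws(scan_run)
        dermal_mean = float(
            sum(result.cr_oral["dermal"][sp] for sp in SPECIES).mean()
        )
        for event in events:
            rows.append(
                {
                    column: grid_value,
                    "event": event,
                    "mean_cr_inhalation": float(result.inhalation_cr_total(event).mean()),
                    "mean_cr_dermal": dermal_mean,
                }
            )
    grid = pd.DataFrame(rows)
    fits = {
        event: fit_trend(
            grid.loc[grid["event"] == event, column],
            grid.loc[grid["event"] == event, "mean_cr_inhalation"],
            "exponential",
        )
        for event in events
    }
    return grid, fits


def scan_duration(
    run: RunConfig,
    durations: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0),
    events: Iterable[int] = (1, 2, 3, 4, 5),
) -> tuple[pd.DataFrame, dict[int, TrendFit]]:
    """Mean dermal/inhalation risk across shower durations, with trend fits.

    The duration enters the event mass balance, the daily exposure time and
    the heating adjustment.  Every grid point reuses the same seed (common
    random numbers), so grid differences are purely the duration effect.
    """
    if any(d <= 0 for d in durations):
        raise ValueError("durations must be > 0")
    return _scan(run, "t", "duration_min", list(durations), list(durations), events)


def scan_ventilation(
    run: RunConfig,
    qg_ls_values: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0),
    events: Iterable[int] = (1, 2, 3, 4, 5),
) -> tuple[pd.DataFrame, dict[int, TrendFit]]:
    """Mean inhalation risk across ventilation rates given in L/s.

    Values are converted ×60 into the L/min units of the stall mass balance.
    The grid column keeps the L/s values as supplied.
    """
    if any(q < 0 for q in qg_ls_values):
        raise ValueError("ventilation rates must be >= 0")
    qg_lmin = [q * L_PER_S_TO_L_PER_MIN for q in qg_ls_values]
    return _scan(run, "qg", "qg_ls", list(qg_ls_values), qg_lmin, events)
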