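"""Seeded sampling of triangular-distributed exposure factors.

Every uncertain model input is described by a :class:`TriangularSpec`
(minimum, most-likely, maximum).  Draws are generated by inverse-CDF
transformation of a uniform stream from a ``numpy.random.Generator`` so that a
fixed seed reproduces bit-identical tables across platforms.  Parameters are
sampled mutually independently; the averaging time AT has its own triangular
specification by default, with an opt-in switch to couple it to the sampled
exposure duration (AT = ED × 365).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TriangularSpec",
    "PARAMETER_ORDER",
    "GENDERS",
    "sample_triangular",
    "triangular_cdf",
    "draw_parameters",
]

GENDERS: tuple[str, ...] = ("female", "male")

#: fixed sampling order — part of the determinism contract
PARAMETER_ORDER: tuple[str, ...] = (
    "ir",      # ingestion rate, L/day
    "pd",      # skin permeability, m/min
    "t",       # shower duration, min
    "vs",      # shower stall volume, L
    "qw",      # water flow, L/min
    "qg",      # ventilation air flow, L/min
    "r",       # breathing rate, m³/min (carried, unused by the EC equations)
    "f",       # shower frequency, events/day
    "ef_ing",  # exposure frequency, ingestion, day/yr
    "ef_der",  # exposure frequency, dermal, day/yr
    "ef_inh",  # exposure frequency, inhalation, day/yr
    "ed",      # exposure duration, yr (gender-specific)
    "bw",      # body weight, kg (gender-specific)
    "at",      # averaging time, days (gender-specific)
    "t_cold",  # cold water temperature, °C
    "t_hot",   # hot water temperature, °C
)


@dataclass(frozen=True)
class TriangularSpec:
    """A triangular distribution on [lower, upper] with mode ``mode``."""

    lower: float
    mode: float
    upper: float

    def validate(self, name: str = "parameter") -> None:
        if not (self.lower <= self.mode <= self.upper):
            raise ValueError(
                f"invalid triangular spec for {name!r}: "
                f"need lower <= mode <= upper, got "
                f"({self.lower}, {self.mode}, {self.upper})"
            )
        if not self.lower < self.upper:
            raise ValueError(
                f"invalid triangular spec for {name!r}: "
                f"need lower < upper, got ({self.lower}, {self.upper})"
            )

    @property
    def mean(self) -> float:
        return (self.lower + self.mode + self.upper) / 3.0


def triangular_cdf(x, spec: TriangularSpec):
    """Closed-form CDF of the triangular distribution (used as a test oracle)."""
    a, c, b = spec.lower, spec.mode, spec.upper
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    width = b - a
    left = (x > a) & (x < c)
    right = (x >= c) & (x < b)
    if c > a:
        out[left] = (x[left] - a) ** 2 / (width * (c - a))
    if b > c:
        out[right] = 1.0 - (b - x[right]) ** 2 / (width * (b - c))
    out[x >= b] = 1.0
    return out


def sample_triangular(
    spec: TriangularSpec,
    n: int,
    rng: np.random.Generator,
    name: str = "parameter",
) -> np.ndarray:
    """Draw ``n`` i.i.d. values by inverse-CDF transform of a uniform stream.

    Parameters
    ----------
    spec:
        Validated triangular specification.
    n:
        Number of draws, >= 1.
    rng:
        Seeded ``numpy.random.Generator``; the only source of randomness.
    name:
        Parameter name used in error messages.
    """
    spec.validate(name)
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    a, c, b = spec.lower, spec.mode, spec.upper
    u = rng.random(n)
    fc = (c - a) / (b - a)
    with np.errstate(invalid="ignore"):
        left = a + np.sqrt(u * (b - a) * (c - a))
        right = b - np.sqrt((1.0 - u) * (b - a) * (b - c))
    return np.where(u < fc, left, right)


def _spec_for(config: Mapping, name: str, gender: str) -> TriangularSpec | float:
    try:
        entry = config[name]
    except KeyError:
        raise KeyError(f"parameter table is missing {name!r}") from None
    if isinstance(entry, Mapping) and gender in entry:
        entry = entry[gender]
    if isinstance(entry, TriangularSpec):
        return entry
    if isinstance(entry, (int, float)):
        return float(entry)
    if isinstance(entry, Mapping):
        try:
            return TriangularSpec(
                float(entry["lower"]), float(entry["mode"]), float(entry["upper"])
            )
        except KeyError as exc:
            raise KeyError(
                f"parameter {name!r}: triangular entry needs lower/mode/upper "
                f"(missing {exc.args[0]!r})"
            ) from None
    raise TypeError(f"parameter {name!r}: unsupported spec {entry!r}")


def draw_parameters(
    config: Mapping,
    n_iter: int,
    gender: str,
    rng: np.random.Generator,
    couple_at_to_ed: bool = False,
    fixed: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Assemble an ``n_iter``-row table of independent per-iteration draws.

    Parameters
    ----------
    config:
        Mapping from parameter name to a :class:`TriangularSpec`, a
        ``{lower, mode, upper}`` mapping, a gender-keyed mapping of either, or
        a plain number (degenerate point mass).  Must cover every name in
        :data:`PARAMETER_ORDER`.
    n_iter:
        Number of Monte Carlo iterations.
    gender:
        ``"female"`` or ``"male"``; selects the gender-specific ED/BW/AT specs.
    rng:
        Seeded generator; parameters are consumed in :data:`PARAMETER_ORDER`.
    couple_at_to_ed:
        When True, the averaging time is computed per-draw as ED × 365 instead
        of being sampled from its own spec (whose uniform draw is still
        consumed, keeping the stream alignment identical between modes).
    fixed:
        Optional per-name constant overrides (used by the sensitivity scans).
        Overridden parameters do not consume random numbers.
    """
    if gender not in GENDERS:
        raise ValueError(f"gender must be one of {GENDERS}, got {gender!r}")
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(PARAMETER_ORDER)
    if unknown:
        raise KeyError(f"unknown fixed parameter(s): {sorted(unknown)}")

    columns: dict[str, np.ndarray] = {}
    for name in PARAMETER_ORDER:
        if name in fixed:
            columns[name] = np.full(n_iter, float(fixed[name]))
            continue
        spec = _spec_for(config, name, gender)
        if isinstance(spec, float):
            columns[name] = np.full(n_iter, spec)
        else:
            columns[name] = sample_triangular(spec, n_iter, rng, name=name)
    if couple_at_to_ed and "at" not in fixed:
        columns["at"] = columns["ed"] * 365.0
    frame = pd.DataFrame(columns, columns=list(PARAMETER_ORDER))
    frame.insert(0, "gender", gender)
    return frame
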