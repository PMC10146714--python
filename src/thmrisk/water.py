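"""Synthetic tap-water THM concentration generator.

The monitoring campaign this package emulates published only per-species
concentration ranges plus a total mean/sd, and reported that trichloromethane
followed a three-parameter (location-shifted) Weibull distribution while the
brominated species followed normal distributions.  This module generates
per-iteration four-species concentration vectors with exactly that structure:

* per-species parametric families (``weibull3`` or ``normal``),
* rejection-truncated to the published min–max ranges (rejection, not
  clamping, so the in-range density shape is preserved),
* species sampled independently, optionally tied together by a Gaussian
  copula when a cross-species correlation matrix is supplied,
* per-species means calibrated so the implied mean ingestion risks match the
  published values (:func:`calibrate_default_means`).

Concentration tables are plain :class:`pandas.DataFrame` objects with one row
per iteration and columns ``tcm, bdcm, dbcm, tbm`` in µg/L; a measured data
set in the same schema is a drop-in replacement for synthesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sampling import draw_parameters
from .species import REFERENCE_MEAN_INGESTION_CR, SPECIES, TOXICITY
from .units import UG_TO_MG

__all__ = [
    "SpeciesWaterSpec",
    "ConcentrationConfig",
    "sample_concentrations",
    "calibrate_default_means",
    "fit_species_params",
    "generate_chlorine_covariate",
    "read_concentrations",
    "write_concentrations",
]

_MIN_ACCEPTANCE = 0.01


@dataclass(frozen=True)
class SpeciesWaterSpec:
    """Distribution family + truncation range for one species (µg/L)."""

    family: str                      # "weibull3" | "normal"
    lower: float
    upper: float
    target_mean: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ("weibull3", "normal"):
            raise ValueError(f"unknown family {self.family!r}")
        if not self.lower < self.upper:
            raise ValueError("truncation range must satisfy lower < upper")

    def frozen_dist(self):
        if self.family == "weibull3":
            return stats.weibull_min(
                self.params["shape"], loc=self.params["loc"], scale=self.params["scale"]
            )
        return stats.norm(self.params["mu"], self.params["sigma"])

    def acceptance_probability(self) -> float:
        d = self.frozen_dist()
        return float(d.cdf(self.upper) - d.cdf(self.lower))


@dataclass(frozen=True)
class ConcentrationConfig:
    """Full four-species generator configuration."""

    species: Mapping[str, SpeciesWaterSpec]
    total_mean: float = 30.22
    total_sd: float = 14.45
    chlorine_range: tuple[float, float] = (0.0, 0.6)
    correlation: np.ndarray | None = None   # optional Gaussian-copula matrix

    def __post_init__(self) -> None:
        missing = [sp for sp in SPECIES if sp not in self.species]
        if missing:
            raise ValueError(f"missing species spec(s): {missing}")

    @classmethod
    def from_config(cls, cfg: Mapping) -> "ConcentrationConfig":
        """Build from the ``water:`` section of a package configuration."""
        water = cfg["water"] if "water" in cfg else cfg
        specs = {}
        for sp in SPECIES:
            entry = dict(water["species"][sp])
            family = entry.pop("family")
            lo, hi = entry.pop("range")
            target = entry.pop("target_mean")
            specs[sp] = SpeciesWaterSpec(
                family=family, lower=lo, upper=hi, target_mean=target, params=entry
            )
        return cls(
            species=specs,
            total_mean=float(water.get("total_mean", 30.22)),
            total_sd=float(water.get("total_sd", 14.45)),
            chlorine_range=tuple(water.get("chlorine_range", (0.0, 0.6))),
        )


def _raw_draw(spec: SpeciesWaterSpec, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of the untruncated family from uniforms ``u``."""
    if spec.family == "weibull3":
        c = spec.params["shape"]
        return spec.params["loc"] + spec.params["scale"] * (-np.log1p(-u)) ** (1.0 / c)
    return stats.norm.ppf(u, loc=spec.params["mu"], scale=spec.params["sigma"])


def sample_concentrations(
    config: ConcentrationConfig,
    n_iter: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generate ``n_iter`` four-species concentration rows (µg/L).

    Each species is drawn from its configured family and rejection-truncated
    to its range.  A configuration whose family places less than 1% of its
    mass inside the truncation range is rejected with a diagnostic before any
    sampling happens.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    for sp in SPECIES:
        acc = config.species[sp].acceptance_probability()
        if acc < _MIN_ACCEPTANCE:
            raise ValueError(
                f"species {sp!r}: truncation range [{config.species[sp].lower}, "
                f"{config.species[sp].upper}] captures only {acc:.2%} of the "
                f"{config.species[sp].family} mass; refit the family parameters"
            )

    if config.correlation is not None:
        return _sample_copula(config, n_iter, rng)

    columns = {}
    for sp in SPECIES:
        spec = config.species[sp]
        acc = spec.acceptance_probability()
        out = np.empty(n_iter)
        filled = 0
        while filled < n_iter:
            need = n_iter - filled
            batch = int(np.ceil(need / acc * 1.2)) + 16
            x = _raw_draw(spec, rng.random(batch))
            x = x[(x >= spec.lower) & (x <= spec.upper)]
            take = min(need, x.size)
            out[filled : filled + take] = x[:take]
            filled += take
        columns[sp] = out
    return pd.DataFrame(columns, columns=list(SPECIES))


def _sample_copula(
    config: ConcentrationConfig, n_iter: int, rng: np.random.Generator
) -> pd.DataFrame:
    """Gaussian-copula sampling with per-species truncated marginals."""
    corr = np.asarray(config.correlation, dtype=float)
    if corr.shape != (len(SPECIES), len(SPECIES)):
        raise ValueError("correlation matrix must be 4x4 in species order")
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_iter, len(SPECIES))) @ chol.T
    u = stats.norm.cdf(z)
    columns = {}
    for j, sp in enumerate(SPECIES):
        spec = config.species[sp]
        d = spec.frozen_dist()
        plo, phi = d.cdf(spec.lower), d.cdf(spec.upper)
        # truncation applied through the probability integral transform here:
        # the copula fixes ranks, so rejection would break the dependence
        columns[sp] = d.ppf(plo + u[:, j] * (phi - plo))
    return pd.DataFrame(columns, columns=list(SPECIES))


def _truncated_mean(dist, lo: float, hi: float) -> float:
    mass = dist.cdf(hi) - dist.cdf(lo)
    return dist.expect(lb=lo, ub=hi) / mass


def fit_species_params(
    target_means: Mapping[str, float],
    ranges: Mapping[str, tuple[float, float]] | None = None,
    weibull_shape: float = 1.1,
    normal_sigmas: Mapping[str, float] | None = None,
) -> dict[str, SpeciesWaterSpec]:
    """Solve family parameters so each truncated mean equals its target.

    TCM keeps a fixed Weibull shape (location pinned at the range minimum) and
    its scale is solved; the normal species keep a fixed sigma and their mu is
    solved.  Raises if a target mean is not attainable inside the range.
    """
    default_ranges = {
        "tcm": (1.7, 15.24),
        "bdcm": (3.55, 23.29),
        "dbcm": (4.84, 25.52),
        "tbm": (1.6, 6.57),
    }
    ranges = dict(ranges or default_ranges)
    sigmas = dict(normal_sigmas or {"bdcm": 8.0, "dbcm": 9.0, "tbm": 2.2})

    out: dict[str, SpeciesWaterSpec] = {}
    lo, hi = ranges["tcm"]
    target = target_means["tcm"]
    if not lo < target < hi:
        raise ValueError(f"tcm target mean {target} outside range [{lo}, {hi}]")

    def tcm_gap(scale: float) -> float:
        d = stats.weibull_min(weibull_shape, loc=lo, scale=scale)
        return _truncated_mean(d, lo, hi) - target

    scale = optimize.brentq(tcm_gap, 1e-3 * (hi - lo), 10 * (hi - lo))
    out["tcm"] = SpeciesWaterSpec(
        family="weibull3",
        lower=lo,
        upper=hi,
        target_mean=target,
        params={"shape": weibull_shape, "scale": scale, "loc": lo},
    )

    for sp in ("bdcm", "dbcm", "tbm"):
        lo, hi = ranges[sp]
        target = target_means[sp]
        if not lo < target < hi:
            raise ValueError(f"{sp} target mean {target} outside range [{lo}, {hi}]")
        sigma = sigmas[sp]

        def gap(mu: float) -> float:
            return _truncated_mean(stats.norm(mu, sigma), lo, hi) - target

        mu = optimize.brentq(gap, lo - 3 * sigma, hi + 3 * sigma)
        out[sp] = SpeciesWaterSpec(
            family="normal",
            lower=lo,
            upper=hi,
            target_mean=target,
            params={"mu": mu, "sigma": sigma},
        )
    return out


def calibrate_default_means(
    config: Mapping,
    n: int = 200_000,
    seed: int = 2023,
) -> dict[str, float]:
    """Back out per-species mean concentrations from published mean risks.

    The implied species mean is ``m_i = CR_i / (CSF_i × M)`` where ``CR_i`` is
    the published mean ingestion cancer risk of species *i* and ``M`` is the
    Monte Carlo mean of the ingestion dose multiplier
    ``IR × EF × ED × CF / (BW × AT)`` under the default exposure-factor table,
    averaged over both genders with equal weight.  The returned means are
    derived quantities, not measurements.
    """
    rng = np.random.default_rng(seed)
    multipliers = []
    for gender in ("female", "male"):
        draws = draw_parameters(config["parameters"], n, gender, rng)
        mult = (
            draws["ir"] * draws["ef_ing"] * draws["ed"] * UG_TO_MG
            / (draws["bw"] * draws["at"])
        )
        multipliers.append(float(mult.mean()))
    m = float(np.mean(multipliers))
    csf = {sp: TOXICITY[sp].csf_oral for sp in SPECIES}
    return {sp: REFERENCE_MEAN_INGESTION_CR[sp] / (csf[sp] * m) for sp in SPECIES}


def generate_chlorine_covariate(
    samples: pd.DataFrame,
    rng: np.random.Generator,
    target_r2: float = 0.63,
    chlorine_range: tuple[float, float] = (0.0, 0.6),
) -> np.ndarray:
    """Free-chlorine values (mg/L) linearly coupled to total THM.

    The covariate is linear in total THM plus Gaussian noise scaled so the
    squared correlation is approximately ``target_r2``, then clipped to the
    chlorine range.  At ``target_r2 == 1`` the output is exactly linear in
    total THM (up to clipping).  Optional feature; nothing else in the
    pipeline depends on it.
    """
    if not 0.0 < target_r2 <= 1.0:
        raise ValueError(f"target_r2 must be in (0, 1], got {target_r2}")
    total = samples[list(SPECIES)].sum(axis=1).to_numpy(dtype=float)
    lo, hi = chlorine_range
    center = 0.5 * (lo + hi)
    sd_total_target = (hi - lo) / 6.0   # keep ±3 sd inside the range pre-clip
    sd_thm = total.std()
    if sd_thm == 0:
        return np.full(total.shape, center)
    slope = sd_total_target * np.sqrt(target_r2) / sd_thm
    noise_sd = sd_total_target * np.sqrt(1.0 - target_r2)
    chlorine = center + slope * (total - total.mean())
    if noise_sd > 0:
        chlorine = chlorine + rng.normal(0.0, noise_sd, size=total.shape)
    return np.clip(chlorine, lo, hi)


def read_concentrations(path: str | Path) -> pd.DataFrame:
    """Read a concentration table (columns ``tcm,bdcm,dbcm,tbm`` in µg/L)."""
    frame = pd.read_csv(path)
    missing = [sp for sp in SPECIES if sp not in frame.columns]
    if missing:
        raise ValueError(f"concentration table is missing column(s): {missing}")
    if (frame[list(SPECIES)] < 0).any().any():
        raise ValueError("concentration table contains negative values")
    return frame[list(SPECIES)].astype(float)


def write_concentrations(frame: pd.DataFrame, path: str | Path) -> None:
    frame[list(SPECIES)].to_csv(path, index=False)
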