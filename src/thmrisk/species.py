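"""Trihalomethane species registry and per-species physical/toxicological constants.

The four regulated trihalomethanes (THM) are tracked throughout the package by
their lower-case abbreviations:

``tcm``
    trichloromethane (chloroform)
``bdcm``
    bromodichloromethane
``dbcm``
    dibromochloromethane
``tbm``
    tribromomethane (bromoform)

Transport constants (dimensionless Henry's constant at 40 °C and the overall
mass-transfer coefficient KoLA) drive the shower volatilization model; the
toxicity constants (oral cancer slope factor and inhalation unit risk) convert
doses into incremental lifetime cancer risks.  All defaults are point values
taken from regulatory compilations; they are treated as degenerate (non-random)
inputs by the sampling engine.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SPECIES",
    "ROUTES",
    "SpeciesTransportConstants",
    "SpeciesToxicity",
    "TRANSPORT",
    "TOXICITY",
    "REFERENCE_MEAN_INGESTION_CR",
]

#: canonical species ordering used by every table in the package
SPECIES: tuple[str, ...] = ("tcm", "bdcm", "dbcm", "tbm")

#: canonical exposure-route ordering
ROUTES: tuple[str, ...] = ("ingestion", "dermal", "inhalation")


@dataclass(frozen=True)
class SpeciesTransportConstants:
    """Volatilization constants for one THM species.

    Attributes
    ----------
    henry:
        Dimensionless Henry's constant at 40 °C (water/air partitioning).
    kola:
        Overall mass-transfer coefficient times interfacial area, L/min.
    """

    henry: float
    kola: float

    def __post_init__(self) -> None:
        if self.henry <= 0:
            raise ValueError(f"Henry's constant must be > 0, got {self.henry}")
        if self.kola < 0:
            raise ValueError(f"KoLA must be >= 0, got {self.kola}")


@dataclass(frozen=True)
class SpeciesToxicity:
    """Dose-response constants for one THM species.

    Attributes
    ----------
    csf_oral:
        Oral cancer slope factor, (mg kg⁻¹ day⁻¹)⁻¹.  Also applied to the
        dermal route in the absence of a dermal-specific slope factor.
    iur:
        Inhalation unit risk, (µg m⁻³)⁻¹.
    """

    csf_oral: float
    iur: float

    def __post_init__(self) -> None:
        if self.csf_oral < 0 or self.iur < 0:
            raise ValueError("toxicity constants must be non-negative")


#: Henry's constant (40 °C, dimensionless) and KoLA (L/min) per species
TRANSPORT: dict[str, SpeciesTransportConstants] = {
    "tcm": SpeciesTransportConstants(henry=0.25, kola=7.4),
    "bdcm": SpeciesTransportConstants(henry=0.124, kola=5.9),
    "dbcm": SpeciesTransportConstants(henry=0.0526, kola=4.6),
    "tbm": SpeciesTransportConstants(henry=0.0501, kola=3.7),
}

#: oral CSF ((mg kg⁻¹ day⁻¹)⁻¹) and IUR ((µg m⁻³)⁻¹) per species
TOXICITY: dict[str, SpeciesToxicity] = {
    "tcm": SpeciesToxicity(csf_oral=0.0061, iur=2.3e-5),
    "bdcm": SpeciesToxicity(csf_oral=0.062, iur=3.7e-5),
    "dbcm": SpeciesToxicity(csf_oral=0.084, iur=2.4e-5),
    "tbm": SpeciesToxicity(csf_oral=0.0079, iur=1.1e-6),
}

# Published mean per-species ingestion cancer risks for the reference
# monitoring campaign the synthetic water generator emulates.  These are
# calibration anchors only: the study never reported per-species water
# concentration means, so the default means of the generator are backed out
# from these risks (see water.calibrate_default_means).
REFERENCE_MEAN_INGESTION_CR: dict[str, float] = {
    "tcm": 0.96e-6,
    "bdcm": 17.13e-6,
    "dbcm": 29.80e-6,
    "tbm": 0.846e-6,
}
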