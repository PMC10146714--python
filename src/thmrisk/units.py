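"""Unit conversion constants.

Air concentrations are carried in micrograms per litre inside the shower
mass-balance model (its volumes and flows are in litres) and converted to
micrograms per cubic metre only at the exposure-concentration boundary.
The conversion factor is defined here and nowhere else.
"""

#: 1 µg/L = 1000 µg/m³
UG_PER_L_TO_UG_PER_M3: float = 1000.0

#: µg → mg, the CF factor of the ingestion dose equation
UG_TO_MG: float = 0.001

#: hours per day, used when converting the averaging time from days to hours
HOURS_PER_DAY: float = 24.0

#: minutes per hour, used when building the daily exposure time
MINUTES_PER_HOUR: float = 60.0

#: L/s → L/min, used by the ventilation scan
L_PER_S_TO_L_PER_MIN: float = 60.0
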