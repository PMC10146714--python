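# Default model inputs for the THM multi-pathway risk assessment.
#
# Triangular entries are {lower, mode, upper} in the units noted.  ED, BW and
# AT are gender-specific.  Constants (Henry, KoLA, CSF, IUR) are point values.
#
# The synthetic water generator section carries distribution parameters that
# were FITTED, not measured: the source monitoring campaign published only
# per-species concentration ranges and a total mean/sd, so the per-species
# target means are backed out from published mean ingestion risks
# (water.calibrate_default_means) and the family parameters are solved so the
# truncated mean of each family equals its target mean
# (water.fit_species_params).

parameters:
  ir:      {lower: 1.0, mode: 2.0, upper: 3.0}            # ingestion rate, L/day
  pd:      {lower: 2.67e-05, mode: 3.0e-05, upper: 3.5e-05}  # skin permeability, m/min
  t:       {lower: 5.0, mode: 10.0, upper: 15.0}          # shower duration, min
  vs:      {lower: 2000.0, mode: 3500.0, upper: 5000.0}   # stall volume, L
  qw:      {lower: 3.0, mode: 4.0, upper: 5.0}            # water flow, L/min
  qg:      {lower: 40.0, mode: 50.0, upper: 60.0}         # ventilation, L/min
  r:       {lower: 0.012, mode: 0.014, upper: 0.016}      # breathing rate, m3/min
  f:       {lower: 0.72, mode: 0.74, upper: 0.76}         # shower events/day
  ef_ing:  {lower: 330.0, mode: 350.0, upper: 365.0}      # day/yr
  ef_der:  {lower: 300.0, mode: 330.0, upper: 365.0}      # day/yr
  ef_inh:  {lower: 300.0, mode: 330.0, upper: 360.0}      # day/yr
  ed:                                                      # exposure duration, yr
    female: {lower: 67.0, mode: 72.0, upper: 77.0}
    male:   {lower: 65.0, mode: 70.0, upper: 75.0}
  bw:                                                      # body weight, kg
    female: {lower: 50.0, mode: 55.0, upper: 60.0}
    male:   {lower: 60.0, mode: 65.0, upper: 70.0}
  at:                                                      # averaging time, days
    female: {lower: 24455.0, mode: 26280.0, upper: 28105.0}
    male:   {lower: 23725.0, mode: 25550.0, upper: 27375.0}
  t_cold:  {lower: 10.0, mode: 15.0, upper: 20.0}          # °C
  t_hot:   {lower: 35.0, mode: 40.0, upper: 45.0}          # °C

constants:
  henry:    {tcm: 0.25,   bdcm: 0.124,  dbcm: 0.0526, tbm: 0.0501}   # dimensionless, 40 °C
  kola:     {tcm: 7.4,    bdcm: 5.9,    dbcm: 4.6,    tbm: 3.7}      # L/min
  csf_oral: {tcm: 0.0061, bdcm: 0.062,  dbcm: 0.084,  tbm: 0.0079}   # (mg/kg/day)^-1
  iur:      {tcm: 2.3e-05, bdcm: 3.7e-05, dbcm: 2.4e-05, tbm: 1.1e-06}  # (ug/m3)^-1

water:
  total_mean: 30.22   # ug/L, published mean of total THM
  total_sd: 14.45     # ug/L, published sd (not exactly attainable under
                      # independent truncated species; see package docs)
  chlorine_range: [0.0, 0.6]   # mg/L, free residual chlorine envelope
  species:
    tcm:
      family: weibull3
      range: [1.7, 15.24]        # ug/L, published min-max
      target_mean: 4.9021        # ug/L, derived (not measured)
      shape: 1.1
      scale: 3.474049            # fitted so truncated mean == target_mean
      loc: 1.7
    bdcm:
      family: normal
      range: [3.55, 23.29]
      target_mean: 8.6061        # derived (not measured)
      mu: -0.409333              # fitted so truncated mean == target_mean
      sigma: 8.0
    dbcm:
      family: normal
      range: [4.84, 25.52]
      target_mean: 11.0504       # derived (not measured)
      mu: 2.676150
      sigma: 9.0
    tbm:
      family: normal
      range: [1.6, 6.57]
      target_mean: 3.3357        # derived (not measured)
      mu: 1.863793
      sigma: 2.2
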