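# Default multi-route soil-exposure parameters for the two standard
# receptors, plus route-specific cancer slope factors.
#
# Units:
#   ir_ing  mg soil ingested per day
#   ir_inh  m^3 air inhaled per day
#   sa      cm^2 exposed skin
#   af      mg soil adhering per cm^2 skin
#   abs     dermal absorption fraction (dimensionless)
#   ef      days of exposure per year
#   ed      years of exposure
#   bw      kg body weight
#   at      averaging time in days (70 y x 365 d)
#   csf_*   (mg/kg/day)^-1 cancer slope factors
#   pef     m^3/kg particulate emission factor
#   rfd     mg/kg/day reference dose for the non-cancer hazard quotient
#   cf      unit conversion factor applied inside the daily-intake formula
receptors:
  adult:
    ir_ing: 100
    ir_inh: 20
    sa: 5700
    af: 0.07
    abs: 0.13
    ef: 365
    ed: 24
    bw: 60
    at: 25550
  child:
    ir_ing: 200
    ir_inh: 10
    sa: 2800
    af: 0.2
    abs: 0.13
    ef: 365
    ed: 6
    bw: 18
    at: 25550
slope_factors:
  csf_ing: 7.3
  csf_inh: 3.85
  csf_derm: 25
  pef: 1.36e9
  unit_factor: 1.0e6
noncancer:
  rfd: 2.0e-3
  cf: 1.0
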