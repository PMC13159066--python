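# Michaelis-Menten rate constants, cell densities, and solute diffusivities for
# the three regions of the Sprague-Dawley rat lumbar intervertebral disc, at the
# two dissolved-oxygen anchor levels (1% and 5% atmospheric partial pressure).
#
# Units:
#   vmax_*        nmol / million cells / h
#   km_*          mM
#   cell_density  million cells / mL tissue
#   d_*           m^2 / s
#   o2_conc_mM    dissolved-oxygen anchor concentration, mM
henry_constant_atm_per_M: 929.6
regions:
  AF:
    cell_density: 53.57
    d_glucose: 4.39e-10
    d_lactate: 5.80e-10
    d_oxygen: 1.16e-09
    levels:
      - o2_percent: 1
        o2_conc_mM: 0.011
        vmax_gcr_nocse: 77.37
        vmax_gcr_cse: 45.07
        km_gcr: 3.61
        vmax_lpr_nocse: 94.50
        vmax_lpr_cse: 66.01
        km_lpr: 1.94
      - o2_percent: 5
        o2_conc_mM: 0.054
        vmax_gcr_nocse: 131.72
        vmax_gcr_cse: 76.72
        km_gcr: 2.65
        vmax_lpr_nocse: 137.64
        vmax_lpr_cse: 96.14
        km_lpr: 1.04
  NP:
    cell_density: 35.71
    d_glucose: 6.47e-10
    d_lactate: 8.54e-10
    d_oxygen: 1.71e-09
    levels:
      - o2_percent: 1
        o2_conc_mM: 0.011
        vmax_gcr_nocse: 95.69
        vmax_gcr_cse: 53.37
        km_gcr: 1.37
        vmax_lpr_nocse: 118.19
        vmax_lpr_cse: 69.97
        km_lpr: 0.37
      - o2_percent: 5
        o2_conc_mM: 0.054
        vmax_gcr_nocse: 285.63
        vmax_gcr_cse: 159.31
        km_gcr: 4.12
        vmax_lpr_nocse: 257.04
        vmax_lpr_cse: 152.17
        km_lpr: 1.43
  CEP:
    cell_density: 78.57
    d_glucose: 5.18e-10
    d_lactate: 6.83e-10
    d_oxygen: 1.37e-09
    levels:
      - o2_percent: 1
        o2_conc_mM: 0.011
        vmax_gcr_nocse: 39.64
        vmax_gcr_cse: 25.36
        km_gcr: 2.13
        vmax_lpr_nocse: 41.93
        vmax_lpr_cse: 28.76
        km_lpr: 0.62
      - o2_percent: 5
        o2_conc_mM: 0.054
        vmax_gcr_nocse: 116.63
        vmax_gcr_cse: 74.59
        km_gcr: 11.10
        vmax_lpr_nocse: 126.27
        vmax_lpr_cse: 86.61
        km_lpr: 7.78
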