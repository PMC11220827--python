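name,value,unit
genistein_oral_noael,0.3,mg/kg/day
genistein_oral_loael,7,mg/kg/day
daidzein_invivo_pod,5,mg/kg/day
genistein_rat_cmax_total_mean,24.1,nM
genistein_rat_cmax_total_ci5,12.4,nM
genistein_rat_cmax_total_ci95,61.5,nM
genistein_rat_cmax_fu_mean,0.48,nM
genistein_rat_cmax_fu_ci5,0.38,nM
genistein_rat_cmax_fu_ci95,1.37,nM
daidzein_rat_cmax_total_mean,45.17,nM
daidzein_rat_cmax_total_ci5,17.14,nM
daidzein_rat_cmax_total_ci95,135.9,nM
daidzein_rat_cmax_fu_mean,1.33,nM
daidzein_rat_cmax_fu_ci5,0.72,nM
daidzein_rat_cmax_fu_ci95,2.61,nM
daidzein_dietary_plasma_high,3140,nM
daidzein_dermal_parent_absorbed_fraction,0.135,fraction
genistein_dermal_parent_absorbed_fraction,0.072,fraction
daidzein_dermal_bioavailable_fraction,0.25,fraction
genistein_dermal_bioavailable_fraction,0.40,fraction
sccs_default_dermal_penetration,0.5,fraction
sccs_oral_bioavailability,0.25,fraction
sccs_subcutaneous_bioavailability,1.0,fraction
sccs_mos_oral,96,unitless
sccs_mos_subcutaneous,385,unitless
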