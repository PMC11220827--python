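chemical_id,log_pow,boiling_point_C,melting_point_C,vapor_pressure_mmHg,molecular_weight,water_solubility_mg_mL,pka,density_g_cm3
genistein,3.04,555.5,301.5,1.33e-9,270.24,0.12,7.25;9.47,1.5
daidzein,3.3,512,323,3.46e-10,254.23,0.053,7.51,1.4
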