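assay_name,genistein_pct_inhibition_10uM,genistein_ic50_uM,daidzein_pct_inhibition_10uM,daidzein_ic50_uM,genistein_hit,daidzein_hit
Estrogen ERalpha (h) (agonist RL),101.07,0.14,100.24,0.308,True,True
ERbeta Human Estrogen NHR Binding (Agonist),104.33,0.00308,100.00,0.02472,True,True
EGFR Human RTK Kinase Enzyme activity,71.05,5.984,17.78,,True,False
MAO-A (antagonist RL),85.95,2.12,49.64,9.18,True,True
5-HT2A (h) (agonist RL),57.31,7.60,38.85,,True,False
5-HT2B (h) (agonist RL),91.89,0.682,44.11,,True,False
Adenosine A1 (h) (antagonist RL),53.51,9.12,19.92,,True,False
Adenosine A2A (h) (agonist RL),52.21,10.0,20.50,,True,False
COX1 (h),70.76,7.69,44.74,,True,False
COX2 (h),53.81,13.6,21.63,,True,False
PDE4D2 (h) (phosphodiesterase 4D),87.03,0.738,0.04,,True,False
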