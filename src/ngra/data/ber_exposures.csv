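scenario,exposure_metric,bound,exposure_value_nM
body lotion 0.1%,cmax_total_mean,,5.95
body lotion 0.1%,cmax_total_ci,lower,3.37
body lotion 0.1%,cmax_total_ci,upper,9.89
body lotion 0.1%,cmax_fu_mean,,0.3
body lotion 0.1%,cmax_fu_ci,lower,0.18
body lotion 0.1%,cmax_fu_ci,upper,0.50
body lotion 0.02%,cmax_total_mean,,1.18
body lotion 0.02%,cmax_total_ci,lower,0.68
body lotion 0.02%,cmax_total_ci,upper,1.96
body lotion 0.02%,cmax_fu_mean,,0.06
body lotion 0.02%,cmax_fu_ci,lower,0.04
body lotion 0.02%,cmax_fu_ci,upper,0.10
dietary intake,cmax_total_mean,,3140
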