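# Calibrated human dermal configuration for the target chemical (daidzein).
# Regression anchors: 0.5 ug/cm2 once daily over 15,670 cm2 (60 kg) x 7 days
# -> mean Cmax,total 10 nM (so reverse dosimetry of the 10 nM safe internal
# concentration returns ~0.5 ug/cm2, i.e. a 0.1% body lotion), and a 3-fold
# skin first-pass effect on parent Cmax (k_met_skin and hepatic_clint fitted
# jointly).  fu = 0.3/5.95 = 0.0504 from the reported unbound/total pair.
# Dermal absorbed fraction 0.25 per the measured skin penetration data.
name: daidzein-human-dermal
body_weight: 60.0
molecular_weight: 254.23
fu_plasma: 0.0504
compartments:
  - {name: plasma, volume: 0.0429, blood_flow: 0.0, tissue_plasma_partition: 1.0}
  - {name: gut, volume: 0.0171, blood_flow: 1.1, tissue_plasma_partition: 3.0}
  - {name: liver, volume: 0.0257, blood_flow: 1.45, tissue_plasma_partition: 4.0}
  - {name: kidney, volume: 0.0044, blood_flow: 1.24, tissue_plasma_partition: 3.0}
  - {name: skin, volume: 0.0371, blood_flow: 0.30, tissue_plasma_partition: 2.5}
  - {name: rest, volume: 0.75, blood_flow: 1.50, tissue_plasma_partition: 1.5}
hepatic_clint: 4.7664449
ka_oral: 0.8
f_abs_oral: 0.5
f_abs_dermal: 0.25
k_perm_skin: 0.05
k_met_skin: 0.1617544
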