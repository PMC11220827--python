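# Calibrated rat oral configuration for the source chemical (genistein).
# Regression anchor: 0.3 mg/kg/day once daily x 7 days -> mean Cmax,total
# 24.1 nM; fu chosen so Cmax,fu = 0.48 nM at that Cmax (0.48/24.1 = 0.0199).
# Physiological volumes/flows are standard rat values; partitions are
# plausible for a moderately lipophilic isoflavone; hepatic intrinsic
# clearance is the fitted free parameter.  This is a calibration fixture,
# not a validated in vivo model.
name: genistein-rat-oral
body_weight: 0.25
molecular_weight: 270.24
fu_plasma: 0.0199
compartments:
  - {name: plasma, volume: 0.0312, blood_flow: 0.0, tissue_plasma_partition: 1.0}
  - {name: gut, volume: 0.027, blood_flow: 2.9, tissue_plasma_partition: 3.0}
  - {name: liver, volume: 0.037, blood_flow: 4.7, tissue_plasma_partition: 4.0}
  - {name: kidney, volume: 0.0073, blood_flow: 3.7, tissue_plasma_partition: 3.0}
  - {name: skin, volume: 0.19, blood_flow: 1.3, tissue_plasma_partition: 2.5}
  - {name: rest, volume: 0.62, blood_flow: 13.0, tissue_plasma_partition: 1.5}
hepatic_clint: 478.4305424
ka_oral: 0.8
f_abs_oral: 0.5
f_abs_dermal: 1.0
k_perm_skin: 0.05
k_met_skin: 0.0
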