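data_type,use,assumptions,confidence
ADME properties,RA,Skin penetration and metabolism assay provides good quality data for refining the PBPK model,high
CALUX assays / ER activity,RA,Assay provides good quality data on ER binding and activation for target and source chemicals with a potency trend against the positive control,high
PBPK,RA,Model estimates internal exposure of the target chemical for the intended consumer use scenario; dermal module calibrated with measured skin absorption,high
Consumer exposure (applied dose),RA,Use in a body lotion is a reasonable worst-case leave-on scenario,moderate
Molecular docking / ER activity,WOE,Docking characterizes binding probability of parent and metabolites to nuclear receptors,moderate
ToxCast / potency,WOE,ToxCast informs on mode of action and relative potency,moderate
Cell stress,WOE,Nontargeted panel indicates nonspecific toxicity leading to cell stress,moderate
Pharmacology profiling,WOE,Indicates possible targets of interest and increases biological coverage; binding does not directly translate to bioactivity potency,moderate
Toxicogenomics,WOE,Informs on gene changes and supports identification of specific biological activity,moderate
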