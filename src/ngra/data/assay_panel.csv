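chemical_id,assay_id,endpoint_class,measure,value_nM,sd,s9,direction
genistein,calux_er_alpha,functional_transactivation,LOEC,5.2,2.1,plus,agonist
genistein,calux_er_alpha,functional_transactivation,LOEC,6.5,2.1,minus,agonist
daidzein,calux_er_alpha,functional_transactivation,LOEC,100,0.0,plus,agonist
daidzein,calux_er_alpha,functional_transactivation,LOEC,110,18,minus,agonist
genistein,ttr_binding,enzyme_inhibition,LOEC,210,67,minus,inhibition
daidzein,ttr_binding,enzyme_inhibition,LOEC,1000,0.0,minus,inhibition
genistein,htpo_inhibition,enzyme_inhibition,LOEC,19000,8900,minus,inhibition
daidzein,htpo_inhibition,enzyme_inhibition,LOEC,28000,13000,minus,inhibition
genistein,h295r_androgen_synthesis,steroidogenesis,LOEC,3200,0.0,minus,inhibition
daidzein,h295r_androgen_synthesis,steroidogenesis,LOEC,2100,1500,minus,inhibition
genistein,cell_stress_mmp,cell_stress,LOEC,11600,,n/a,down
daidzein,cell_stress_mmp,cell_stress,LOEC,10800,,n/a,down
genistein,pharmacology_er_alpha,receptor_binding,LOEC,44,,n/a,agonist
daidzein,pharmacology_er_alpha,receptor_binding,LOEC,35.2,,n/a,agonist
genistein,pharmacology_er_beta,receptor_binding,LOEC,0.52,,n/a,agonist
daidzein,pharmacology_er_beta,receptor_binding,LOEC,3.2,,n/a,agonist
genistein,transcriptomics_mcf7,transcriptomic_pathway,BMD_median,6.5,,n/a,up
daidzein,transcriptomics_mcf7,transcriptomic_pathway,BMD_median,38,,n/a,down
genistein,transcriptomics_hepg2,transcriptomic_pathway,BMD_median,15700,,n/a,down
daidzein,transcriptomics_hepg2,transcriptomic_pathway,BMD_median,16200,,n/a,up
genistein,transcriptomics_heparg,transcriptomic_pathway,BMD_median,40,,n/a,up
daidzein,transcriptomics_heparg,transcriptomic_pathway,BMD_median,33100,,n/a,down
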