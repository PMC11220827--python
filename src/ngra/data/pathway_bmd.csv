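chemical_id,cell_type,min_genes_filter,lowest_median_bmd_uM,pathway,direction,estrogen_bmd_uM,estrogen_pathway
daidzein,MCF-7,3,0.038,Positive regulation of insulin-like growth factor receptor signaling pathway,down,21.3,response to estrogen (down)
daidzein,MCF-7,5,0.084,Epidermal growth factor receptor signaling pathway,down,,
daidzein,HepG2,3,16.2,C21-steroid hormone metabolic process,up,,
daidzein,HepG2,5,30.0,Steroid biosynthetic process,up,,
daidzein,HepaRG,3,33.1,Arachidonic acid monooxygenase activity,down,,
daidzein,HepaRG,5,39.3,Oxidoreductase activity,down,,
genistein,MCF-7,3,0.0065,L-leucine transmembrane transporter activity,up,60.1,estrogen 2-hydroxylase activity (down)
genistein,MCF-7,5,0.051,Negative regulation of Notch signaling pathway,down,,
genistein,HepG2,3,,All deregulated pathways had more than 5 genes,,53.8,estrogen-dependent gene expression (down)
genistein,HepG2,5,15.7,Regulation of glomerular mesangial cell proliferation,down,,
genistein,HepaRG,3,0.040,Regulation of intracellular sterol transport,up,0.11,estrogen-dependent gene expression (up)
genistein,HepaRG,5,0.051,Translation initiation complex formation,up,,
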