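chemical_id,cell_line,well_format,nominal_uM,conc_0h_uM,conc_24h_uM
genistein,HepG2,48-well,1.3,1.33,1.26
genistein,HepG2,96-well,1.3,1.11,1.41
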