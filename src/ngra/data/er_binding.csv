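chemical_id,receptor,ic50_nM,ki_nM,loec_nM
genistein,ERalpha,140,40,44
genistein,ERbeta,3.1,0.64,0.52
daidzein,ERalpha,308,87.9,35.2
daidzein,ERbeta,24.7,5.1,3.2
diethylstilbestrol,ERalpha,,,
diethylstilbestrol,ERbeta,1.18,0.24,
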