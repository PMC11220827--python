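{
  "assay_panel.csv": "52ff65f97d2ec8d92de884800c92224570dff5eb2629f77ddcca5665846fdb3a",
  "ber_exposures.csv": "1c96474e3288cac41fd379248d7c53ddea0f34e3a8cdf6048e0f9c695267836a",
  "er_binding.csv": "748aa0266dcd6ed04bdc0183ccfe208f8a421c7af3b585201b479590c8c46b3f",
  "insilico_alerts.csv": "aa518b4874e90ea4ff91d9903a9e57c3d6632330a2fb0a15487553e74a12c630",
  "invivo_anchors.csv": "b0a3781e8889ec6c7163cb77ffbea8ce06cf3c3409bc3fa4b3b1a4175f367c97",
  "pathway_bmd.csv": "e5d263e3baf4227e26ed82e8612d2008394e3284e984e17e85c63f238f618adc",
  "pbpk_daidzein_human_dermal.yaml": "36910e5085608b343dd6240fe702d10ecdb7f7d9e3a32233778afb2c8aade563",
  "pbpk_daidzein_rat_oral.yaml": "3e84334139a7b07b1c9aee934019b65c3458cb13fdf26113a34beb3189520f0d",
  "pbpk_genistein_rat_oral.yaml": "b7769113676942201f7d2926d3575bf21524f18a288dbda332f19d4ee72f6f8a",
  "pharmacology_screen.csv": "8550fec53f866f158f59464118064c6581997d7d6b0858fb648ad58b6a298543",
  "physchem.csv": "29277a45adbd7d092c4b69d446683c9885b6c80b6dc59c9fe66695ac433bebba",
  "stability_controls.csv": "d5a49748cd1db64c0b3c4addeb3ca332a36207c0748d619b687115c94a521497",
  "uncertainty.csv": "78e1ddf457eb8cc444874e01c318510c1b40f7465b5a70a9969cb7382cd96296"
}
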