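wavelength_nm,eps_water_mm-1,eps_lipid_mm-1,source
970,0.0450,0.0050,"water: Hale/Querry-Kou pure-water absorption, digitized; lipid: van Veen soybean-oil absorption, digitized"
1050,0.0150,0.0045,"water: Hale/Querry-Kou pure-water absorption, digitized; lipid: van Veen soybean-oil absorption, digitized"
1200,0.1040,0.0480,"water: Hale/Querry-Kou pure-water absorption, digitized; lipid: van Veen soybean-oil absorption, digitized"
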