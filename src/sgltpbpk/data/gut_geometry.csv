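compartment,transit_fraction,luminal_volume_ml,radius_cm
stomach,,46,10.0
duodenum,0.08,42,1.6
jejunum1,0.29,154,1.5
jejunum2,0.23,122,1.34
ileum1,0.18,94,1.18
ileum2,0.13,71,1.01
ileum3,0.09,49,0.85
caecum,,47,3.5
ascending_colon,,50,2.5
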