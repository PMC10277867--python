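tissue,volume_l,blood_flow_l_h
lung,0.5,336.0
heart,0.33,13.44
brain,1.45,40.32
muscle,28.0,57.12
adipose,15.0,16.8
skin,3.3,16.8
rest,8.5,31.92
spleen,0.15,10.08
gut_tissue,1.65,62.16
liver,1.8,21.84
kidney,0.31,63.84
reproductive,0.5,1.68
arterial,1.7,336.0
venous,3.9,336.0
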