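tissue,f_ew,f_iw,f_nl,f_np,albumin_ratio
adipose,0.135,0.017,0.79,0.002,0.049
rest,0.1,0.346,0.074,0.0011,0.1
brain,0.162,0.62,0.051,0.0565,0.048
gut_tissue,0.282,0.475,0.0487,0.0163,0.158
heart,0.32,0.456,0.0115,0.0166,0.157
kidney,0.273,0.483,0.0207,0.0162,0.13
liver,0.161,0.573,0.0348,0.0252,0.086
lung,0.336,0.446,0.003,0.009,0.212
muscle,0.118,0.63,0.0238,0.0072,0.064
skin,0.382,0.291,0.0284,0.0111,0.277
spleen,0.207,0.579,0.0201,0.0198,0.097
reproductive,0.141,0.379,0.0019,0.0066,0.041
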