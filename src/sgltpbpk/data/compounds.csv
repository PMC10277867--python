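name,molecular_weight,log_p,solubility,solubility_unit,peff,fup,rbp,cl_total,cl_hepatic,ki_sglt1,ki_sglt2
ertugliflozin,436.8,2.5,0.163,mg/mL,4.1,0.064,0.66,0.14,0.13,1888.66,0.88
empagliflozin,450.9,2.31,0.13,mg/mL,1.08,0.138,0.66,0.15,0.09,797.61,0.64
henagliflozin,454.1,2.72,0.182,mg/mL,6.7,0.05,0.55,0.11,0.09,4184.52,2.38
sotagliflozin,424.9,4.09,0.0136,mg/mL,1.72,0.027,0.6,0.35,0.33,7.02,1.41
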