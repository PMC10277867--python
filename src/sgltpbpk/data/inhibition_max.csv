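site,ertugliflozin_5,ertugliflozin_10,empagliflozin_10,empagliflozin_25,henagliflozin_5,henagliflozin_10,sotagliflozin_200,sotagliflozin_400
duodenum,0.14,0.43,2.33,3.90,0.07,0.11,89.54,94.47
jejunum1,0.09,0.26,1.74,3.22,0.04,0.07,81.41,89.75
S3,0.09,0.26,0.89,1.91,0.04,0.08,6.66,13.05
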