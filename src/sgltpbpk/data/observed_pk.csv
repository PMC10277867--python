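compound,dose_mg,auc,cmax,tmax,population_tag,auc_pred_ref,cmax_pred_ref,tmax_pred_ref
ertugliflozin,15,1291.7,266.17,1.0,non-Asian,1238.5,263.08,1.0
ertugliflozin,1,68.09,17.9,1.0,Asian,75.4,18.82,1.0
ertugliflozin,5,433.79,79.7,1.02,Asian,393.82,95.5,1.04
ertugliflozin,25,2151.4,432.0,1.25,Asian,2485.6,437.61,1.16
empagliflozin,1,129.01,14.63,1.25,Asian,141.73,16.19,1.25
empagliflozin,10,1286.5,148.83,1.5,Asian,1493.5,147.55,1.3
empagliflozin,25,2843.7,284.5,2.0,Asian,2919.5,317.5,1.78
empagliflozin,100,10590,1192.1,2.5,Asian,9507.7,1201.4,2.12
henagliflozin,2.5,408,54.8,1.5,Asian,395.1,52.1,0.96
henagliflozin,5,796.69,117.37,1.5,Asian,766.09,106.92,0.96
henagliflozin,10,1415.6,161.7,1.75,Asian,1413.4,205.1,1.16
henagliflozin,25,3384.1,406.0,2.0,Asian,3642,457.07,1.1
henagliflozin,50,7671.8,941.7,1.5,Asian,7449.5,964.07,1.1
henagliflozin,100,13440,1460.0,2.0,Asian,13930,1732.5,1.6
henagliflozin,200,28480,3140.5,1.5,Asian,28630,3305.1,1.68
sotagliflozin,200,631.14,90.9,1.0,Asian,475.36,115.82,0.72
sotagliflozin,400,1129.8,151.0,1.0,Asian,928.08,195.54,0.72
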