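condition,variable,time_h,value,sd,units
control,glucose,2,7.8,0.5,mM
control,insulin,1,21.1,0.8,ug/L
control,insulin,12,22.2,0.3,ug/L
control,insulin,24,22.6,0.1,ug/L
pa,insulin,1,22.3,0.9,ug/L
pa,insulin,12,26.6,0.4,ug/L
pa,insulin,24,27.1,0.5,ug/L
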