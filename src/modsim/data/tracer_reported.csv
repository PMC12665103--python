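species,metric,compartment,source,time_min,value,sd,units
dextran_4k,percent_transferred,downstream,POC,180,58.4,7.6,%
dextran_4k,percent_transferred_noflow,downstream,POC,180,20.4,3.1,%
dextran_4k,fold_enhancement,LOC,POC,180,2.1,0.1,fold
glucose,fold_enhancement,POC,LOOP,180,1.9,0.1,fold
dextran_70k,percent_transferred,downstream,LOC,1440,70.6,12.4,%
dextran_70k,percent_transferred_noflow,downstream,LOC,1440,15.9,8.1,%
dextran_70k,fold_enhancement,POC,LOC,1440,9.1,0.3,fold
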