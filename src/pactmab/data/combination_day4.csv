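regimen,pac_dose,tmab_dose,mean_confluence,ci_lo,ci_hi
paclitaxel_first,25,25,0.33,0.31,0.35
paclitaxel_first,100,25,0.27,0.26,0.28
simultaneous,25,25,0.24,0.23,0.25
simultaneous,100,25,0.19,0.17,0.21
trastuzumab_first,25,25,0.19,0.18,0.20
trastuzumab_first,100,25,0.18,0.15,0.21
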