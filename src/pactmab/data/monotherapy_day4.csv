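drug,dose,mean_confluence,ci_lo,ci_hi
paclitaxel,10,0.45,0.41,0.49
paclitaxel,25,0.46,0.43,0.49
paclitaxel,50,0.38,0.35,0.40
paclitaxel,100,0.33,0.32,0.34
paclitaxel,250,0.30,0.27,0.33
paclitaxel,500,0.25,0.21,0.29
trastuzumab,10,0.43,0.42,0.45
trastuzumab,25,0.38,0.36,0.40
trastuzumab,50,0.24,0.21,0.27
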