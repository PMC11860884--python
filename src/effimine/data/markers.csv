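name,normal_low,normal_high,pre_median,pre_q1,pre_q3,direction,units
FBG,2.0,4.0,4.80,4.27,5.37,high-is-bad,g/L
PLT,125.0,350.0,279.0,216.0,363.0,high-is-bad,1e9/L
ESR,2.0,12.0,58.0,38.0,80.0,high-is-bad,mm/h
Hs-CRP,0.0,1.0,36.0,16.0,66.0,high-is-bad,mg/L
IgA,0.7,4.0,2.59,1.99,3.39,high-is-bad,g/L
IgG,7.0,16.0,12.8,10.2,15.9,high-is-bad,g/L
IgM,0.4,2.5,1.25,0.91,1.64,high-is-bad,g/L
RF,0.0,14.0,130.0,48.0,306.0,high-is-bad,U/mL
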