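salt,temperature_c,aw
KOH,30,0.0738
KOH,40,0.0626
KOH,50,0.0572
MgCl2.6H2O,30,0.3238
MgCl2.6H2O,40,0.3159
MgCl2.6H2O,50,0.3054
K2CO3,30,0.4317
K2CO3,40,0.423
K2CO3,50,0.4091
NaNO3,30,0.7275
NaNO3,40,0.71
NaNO3,50,0.6904
KCl,30,0.8362
KCl,40,0.8232
KCl,50,0.812
BaCl2.2H2O,30,0.898
BaCl2.2H2O,40,0.891
BaCl2.2H2O,50,0.8823
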