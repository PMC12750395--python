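name,formula,exact_mass,nominal_mass,pb_class_hint,enabled
malonylation,C3H2O3,86.0004,86,PxB,1
hydrogenation,H2,2.0157,2,PleB,1
dehydrogenation,-H2,-2.0157,-2,PrB,1
oxygenation,O,15.9949,16,other,1
glycosylation,C6H10O5,162.0528,162,other,0
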