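name,pb_class,neutral_mass,formula,source
Ep-PxB-6,PxB,642.2681,,from [M+H]+ m/z 643.2754
Sao-PxB,PxB,728.2685,,Ep-PxB-6 + malonyl (C3H2O3)
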