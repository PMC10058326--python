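compound,total_smd_energy_kcalmol,fmax_pn
10,337.71,2387.26
11,285.87,1523.115
12,324.15,2178.367
13,349.20,1707.508
14,261.82,1494.272
15,251.42,1565.923
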