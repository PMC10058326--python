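compound,ki_nm,dg_from_ki,dg_autodock,dg_vina,dg_mmpbsa,dg_mmgbsa
1,160.1,-9.26,-8.36,-8.27,-6.63,-8.66
2,22,-10.44,-8.57,-6.96,-10.04,-13.45
3,60,-9.84,-6.91,-6.24,-4.40,-10.79
4,136,-9.36,-8.38,-8.01,-8.39,-10.40
5,2.16,-11.81,-7.43,-8.21,-14.21,-14.25
6,1.85,-11.90,-6.74,-7.61,-15.22,-15.15
7,0.76,-12.43,-6.57,-7.17,-14.66,-14.47
8,0.40,-12.81,-6.62,-8.22,-12.51,-12.79
9,0.21,-13.19,-7.52,-8.08,-11.72,-12.12
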