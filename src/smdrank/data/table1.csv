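compound,exp_pki,autodock_pki,vina_pki,mmpbsa_pki,mmgbsa_pki,total_smd_energy_kcalmol,fmax_pn
1,6.79,6.13,6.07,4.87,6.35,607.57,3107.35
2,7.66,6.29,5.10,7.36,9.87,743.43,3696.76
3,7.22,5.07,4.58,3.23,7.92,579.64,3444.44
4,6.87,6.15,5.87,6.15,7.63,575.78,3167.07
5,8.67,5.45,6.02,10.43,10.45,353.09,3619.763
6,8.73,4.94,5.58,11.16,11.11,490.62,3671.292
7,9.12,4.82,5.26,10.75,10.62,477.53,3500.413
8,9.40,4.85,6.03,9.18,9.38,585.43,3594.054
9,9.68,5.51,5.93,8.60,8.89,503.11,3596.79
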