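# Comparison set (Baughman et al.), saturable kinetics, interior-point fit.
phi_star_1: 8.85e-4
phi_star_2: 1.12e+6
phi_star_3: 1.1e+5
phi_star_4: 1.97e-2
phi_star_5: 4.95
phi_star_6: 1.34e+5
phi_star_7: 1.36e+3
phi_star_8: 1.0e-5
phi_star_9: 1.83e+4
ks_1_1: 1.63e+5
ks_1_2: 1.08e+4
ks_1_3: 1.44e+4
ks_3_2: 9.64e+2
ks_3_3: 1.04e+3
ks_3_4: 5.42e-2
ks_2_6: 3.03e+3
ks_2_7: 6.39e+3
ks_2_8: 3.73e-1
ks_2_9: 3.23e+5
ks_4_5: 7.42e+3
ks_5_6: 4.45e+3
mu: 3.22e-2
kd: 4.99e-2
kinetics_mode: saturable
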