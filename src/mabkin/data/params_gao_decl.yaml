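# Comparison set (Gao et al.), decline-phase block (simplified kinetics).
phi_star_1: -0.0033
phi_star_2: 0.0058
phi_star_3: -0.0014
phi_star_4: 0.0057
phi_star_5: 0.0056
phi_star_6: 0.0029
phi_star_7: 0.0573
phi_star_8: 0.0077
phi_star_9: 0.0113
ks_1_1: 0.01
ks_1_2: 0.01
ks_1_3: 0.01
ks_3_2: 0.001
ks_3_3: 0.001
ks_3_4: 0.001
ks_2_6: 0.01
ks_2_7: 0.01
ks_2_8: 0.01
ks_2_9: 0.01
ks_4_5: 0.001
ks_5_6: 0.001
mu: 0.0399
kd: 0.06
kinetics_mode: simplified
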