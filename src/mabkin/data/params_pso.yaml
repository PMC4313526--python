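# Kinetic parameters estimated by the multistep PSO approach (saturable kinetics).
# phi_star_* in pmol/(cell h); ks_* in mM; mu in 1/h; kd per (1e6 cells/mL) per h.
phi_star_1: 8.443e-4
phi_star_2: 2.481e+6
phi_star_3: 3.968e+5
phi_star_4: 1.090e+2
phi_star_5: 7.283
phi_star_6: 3.337e+5
phi_star_7: 3.977e+3
phi_star_8: 6.697e-6
phi_star_9: 3.261e+4
ks_1_1: 8.989e+5
ks_1_2: 6.495e+4
ks_1_3: 3.723e+4
ks_3_2: 7.076e+2
ks_3_3: 2.782e+3
ks_3_4: 0.019
ks_2_6: 2.719e+4
ks_2_7: 9.324e+3
ks_2_8: 0.537
ks_2_9: 6.683e+5
ks_4_5: 1.920e+3
ks_5_6: 4.488e+4
mu: 0.043
kd: 0.067
kinetics_mode: saturable
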