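time_h,GLC,GLC_sd,GLN,GLN_sd,ASN,ASN_sd,ASP,ASP_sd,LAC,LAC_sd,ALA,ALA_sd,PRO,PRO_sd,MAb,MAb_sd,BM,BM_sd,X,X_sd,Xd,Xd_sd
0,3.59,0.04,2.85,0.04,0.46,0.00,0.27,0.02,0.51,0.01,0.33,0.03,0.30,0.01,0.34,0.12,2.01,0.20,0.09,0.01,0.02,0.01
28,2.59,0.09,1.27,0.30,0.39,0.02,0.18,0.02,1.33,0.06,0.72,0.11,0.27,0.02,1.02,0.06,11.61,0.46,0.58,0.02,0.05,0.01
54,1.88,0.15,0.42,0.31,0.35,0.02,0.10,0.04,1.66,0.19,1.15,0.17,0.42,0.04,1.58,0.16,16.51,0.85,0.79,0.05,0.11,0.01
76,1.77,0.05,0.11,0.10,0.32,0.03,0.07,0.04,1.74,0.01,1.32,0.12,0.53,0.02,2.31,0.24,17.98,0.84,0.72,0.01,0.25,0.05
101,1.70,0.03,0.00,0.00,0.28,0.02,0.04,0.04,1.71,0.01,1.46,0.07,0.56,0.02,2.66,0.41,19.41,2.21,0.47,0.06,0.58,0.05
124,1.67,0.04,0.00,0.00,0.25,0.02,0.03,0.04,1.72,0.01,1.48,0.07,0.60,0.01,3.09,0.60,18.67,2.49,0.17,0.03,0.85,0.12
147,1.68,0.05,0.00,0.00,0.22,0.02,0.03,0.04,1.73,0.05,1.51,0.08,0.60,0.01,3.41,0.75,17.97,1.33,0.06,0.02,0.91,0.07
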