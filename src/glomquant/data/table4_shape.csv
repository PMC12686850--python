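# Per-dataset quartiles of aspect-length ratios and sphericity,
# transcribed from the published study (paper-derived reference values,
# not outputs of this package). Group rows are recomputed by the
# statistics layer, not stored.
dataset,age_group,q1_alr_xz,median_alr_xz,q3_alr_xz,q1_alr_yz,median_alr_yz,q3_alr_yz,q1_sphericity,median_sphericity,q3_sphericity
SR1-1692,PD14,1.83,2.11,2.46,1.16,1.27,1.39,0.59,0.62,0.66
AC1547,PD14,1.86,2.13,2.50,1.16,1.26,1.39,0.59,0.62,0.66
A2661-R,PD14,1.97,2.31,2.74,1.16,1.28,1.42,0.59,0.63,0.67
A2661-L,PD14,2.02,2.39,2.80,1.17,1.27,1.42,0.57,0.61,0.65
F-1768,PD21,1.60,1.82,2.08,1.14,1.23,1.35,0.60,0.64,0.67
8067-R,PD21,1.98,2.37,2.85,1.16,1.26,1.37,0.54,0.58,0.61
8066-R,PD21,1.76,2.14,2.61,1.15,1.24,1.36,0.58,0.62,0.65
8066-L,PD21,1.94,2.34,2.78,1.16,1.25,1.38,0.50,0.53,0.57
8034-L,PD56,2.00,2.44,2.99,1.19,1.32,1.48,0.51,0.54,0.59
8036-L,PD56,2.02,2.46,3.00,1.18,1.30,1.44,0.52,0.56,0.59
8035-L,PD56,2.04,2.52,3.10,1.18,1.30,1.43,0.52,0.56,0.59
8034-R,PD56,2.10,2.54,3.03,1.16,1.27,1.41,0.56,0.60,0.63
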