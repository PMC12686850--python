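# Per-dataset glomerular counts and sizes for 12 mouse olfactory bulbs,
# transcribed from the published study (paper-derived reference values,
# not outputs of this package). Group rows (medians of medians) are
# recomputed by the statistics layer, not stored.
dataset,age_group,n_glomeruli,total_volume_mm3,median_volume_um3,median_effective_diameter_um
SR1-1692,PD14,2686,0.671,210177,73.77
AC1547,PD14,2775,0.549,167843,68.44
A2661-R,PD14,2798,0.423,129866,62.83
A2661-L,PD14,2804,0.480,146564,65.41
F-1768,PD21,2473,0.548,194988,71.95
8067-R,PD21,2560,0.591,199784,72.53
8066-R,PD21,2788,0.524,158728,67.18
8066-L,PD21,2792,0.660,210616,73.82
8034-L,PD56,2828,0.973,272504,80.44
8036-L,PD56,2845,0.729,219530,74.85
8035-L,PD56,2857,0.838,262119,79.40
8034-R,PD56,2931,0.771,226890,75.67
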